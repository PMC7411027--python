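import numpy as np
import pandas as pd
import pytest

from sibprs import SimConfig, simulate_cohort
from sibprs.datatypes import Pedigree, PhenotypeTable
from sibprs.train import ScoreTable


@pytest.fixture(scope="session")
def small_binary_cohort():
    """Confound-free disease cohort, small enough for unit tests."""
    cfg = SimConfig(
        n_families=300, n_unrelated=3000, n_variants=600, n_causal=40,
        h2=0.5, prevalence=0.2, seed=101, trait_kind="binary",
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_quant_cohort():
    cfg = SimConfig(
        n_families=300, n_unrelated=3000, n_variants=600, n_causal=40,
        h2=0.5, seed=102, trait_kind="quantitative",
    )
    return simulate_cohort(cfg)


def make_scores(ids, values) -> ScoreTable:
    """ScoreTable from a vector (one predictor) or matrix (n x m)."""
    arr = np.asarray(values, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    m = arr.shape[1]
    return ScoreTable(np.asarray(ids, dtype=object), arr, True, np.zeros(m), np.ones(m))


def make_pedigree(sibships, singletons=()) -> Pedigree:
    """Pedigree from a list of sibling-id tuples plus singleton ids."""
    rows = []
    fam = 0
    for sibs in sibships:
        f = f"FAM{fam}"
        rows.append((f"{f}_P1", f, "0", "0", 1, "founder"))
        rows.append((f"{f}_P2", f, "0", "0", 2, "founder"))
        for s in sibs:
            rows.append((s, f, f"{f}_P1", f"{f}_P2", 1, "offspring"))
        fam += 1
    for s in singletons:
        f = f"FAM{fam}"
        rows.append((f"{f}_P1", f, "0", "0", 1, "founder"))
        rows.append((f"{f}_P2", f, "0", "0", 2, "founder"))
        rows.append((s, f, f"{f}_P1", f"{f}_P2", 2, "offspring"))
        fam += 1
    return Pedigree(pd.DataFrame(rows, columns=Pedigree.COLUMNS))


def make_phen(ids, values, kind="quantitative", trait="t") -> PhenotypeTable:
    return PhenotypeTable(
        pd.Series(np.asarray(values, dtype=float), index=np.asarray(ids, dtype=object)),
        trait, kind,
    )
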