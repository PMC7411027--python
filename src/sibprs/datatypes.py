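"""Core containers for family-structured genotype/phenotype cohorts.

The in-memory model mirrors what a PLINK-style workflow would carry around:
a dense dosage matrix with sample/variant metadata, a pedigree table, and a
long-format phenotype table.  All downstream statistics operate on these.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "TruthModel",
    "GenotypeMatrix",
    "Pedigree",
    "PhenotypeTable",
]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the family-structured cohort simulator.

    Defaults describe the reference study condition used throughout the
    analysis scripts: 20k unrelated training individuals, 2k sibling pairs,
    10k unlinked biallelic SNPs of which 100 are causal, heritability 0.5,
    and (for disease traits) a liability-threshold prevalence of 10%.
    Confounds (shared family environment ``c2``, parental genetic nurture
    ``w_nurture``, two-subpopulation drift ``fst`` with an environmental
    offset ``env_offset``) are off by default.
    """

    n_families: int = 2000
    n_sibs_per_family: int = 2
    n_unrelated: int = 20_000
    n_variants: int = 10_000
    maf_low: float = 0.05
    maf_high: float = 0.5
    n_causal: int = 100
    h2: float = 0.5
    c2: float = 0.0
    w_nurture: float = 0.0
    fst: float = 0.0
    env_offset: float = 0.0
    prevalence: float = 0.1
    trait: str = "trait"
    trait_kind: str = "binary"  # "binary" | "quantitative"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_families < 0 or self.n_unrelated < 0:
            raise ValueError("family/unrelated counts must be non-negative")
        if self.n_families + self.n_unrelated <= 0:
            raise ValueError("cohort is empty")
        if self.n_families > 0 and self.n_sibs_per_family < 2:
            raise ValueError("n_sibs_per_family must be >= 2")
        if self.n_variants <= 0:
            raise ValueError("n_variants must be positive")
        if not (0.0 < self.maf_low <= self.maf_high <= 0.5):
            raise ValueError("require 0 < maf_low <= maf_high <= 0.5")
        if not (0 <= self.n_causal <= self.n_variants):
            raise ValueError("n_causal must lie in [0, n_variants]")
        if not (0.0 <= self.h2 <= 1.0) or not (0.0 <= self.c2 <= 1.0):
            raise ValueError("h2 and c2 must lie in [0, 1]")
        if self.h2 + self.c2 > 1.0 + 1e-12:
            raise ValueError("h2 + c2 must not exceed 1")
        if self.w_nurture < 0:
            raise ValueError("w_nurture must be >= 0")
        if not (0.0 <= self.fst < 1.0):
            raise ValueError("fst must lie in [0, 1)")
        if not (0.0 < self.prevalence < 1.0):
            raise ValueError("prevalence must lie in (0, 1)")
        if self.trait_kind not in ("binary", "quantitative"):
            raise ValueError("trait_kind must be 'binary' or 'quantitative'")


@dataclass
class TruthModel:
    """Ground truth recorded by the simulator for parameter-recovery tests.

    ``causal_effects`` are per standardized allele (cohort-standardized
    dosage scale).  ``genetic_values`` / ``parental_mean_gv`` are indexed by
    offspring individual id and already scaled so var(gv) == h2.
    """

    causal_effects: np.ndarray
    variance_components: dict
    liability_threshold: Optional[float]
    subpop_assignment: pd.Series  # family_id -> 0/1
    genetic_values: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    parental_mean_gv: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))

    @property
    def n_causal(self) -> int:
        return int(np.count_nonzero(self.causal_effects))


class GenotypeMatrix:
    """Dense individuals x variants dosage matrix with metadata.

    Dosages count copies of allele1 (the "counted" allele, written as ALT
    in VCF / allele-1 in BIM).  Hard calls are {0,1,2}; fractional values
    may appear after mean imputation of missing entries at load time.
    """

    def __init__(
        self,
        sample_ids,
        variant_ids,
        dosages: np.ndarray,
        variant_meta: Optional[pd.DataFrame] = None,
        validate: bool = True,
    ):
        self.sample_ids = np.asarray(sample_ids, dtype=object)
        self.variant_ids = np.asarray(variant_ids, dtype=object)
        self.dosages = dosages
        if variant_meta is None:
            freq = dosages.mean(axis=0) / 2.0 if len(dosages) else np.zeros(len(self.variant_ids))
            variant_meta = pd.DataFrame(
                {"freq": freq, "allele1": "A", "allele2": "G"}, index=self.variant_ids
            )
        self.variant_meta = variant_meta
        self._sample_index = pd.Index(self.sample_ids)
        self._variant_index = pd.Index(self.variant_ids)
        if validate:
            self._check()

    def _check(self) -> None:
        n, p = self.dosages.shape
        if n != len(self.sample_ids) or p != len(self.variant_ids):
            raise ValueError("dosage matrix shape does not match id lists")
        if self._sample_index.has_duplicates or self._variant_index.has_duplicates:
            raise ValueError("sample and variant ids must be unique")
        if n and p:
            lo = self.dosages.min()
            hi = self.dosages.max()
            if not (np.isfinite(lo) and np.isfinite(hi)):
                raise ValueError("dosages contain non-finite entries")
            if lo < 0 or hi > 2:
                raise ValueError("dosages must lie in [0, 2]")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    def sample_indexer(self, ids) -> np.ndarray:
        idx = self._sample_index.get_indexer(np.asarray(ids, dtype=object))
        if (idx < 0).any():
            missing = np.asarray(ids, dtype=object)[idx < 0][:5]
            raise KeyError(f"unknown sample ids (first few): {list(missing)}")
        return idx

    def variant_indexer(self, ids) -> np.ndarray:
        idx = self._variant_index.get_indexer(np.asarray(ids, dtype=object))
        if (idx < 0).any():
            missing = np.asarray(ids, dtype=object)[idx < 0][:5]
            raise KeyError(f"unknown variant ids (first few): {list(missing)}")
        return idx

    def dosages_for(self, sample_ids=None, variant_ids=None) -> np.ndarray:
        out = self.dosages
        if sample_ids is not None:
            out = out[self.sample_indexer(sample_ids), :]
        if variant_ids is not None:
            out = out[:, self.variant_indexer(variant_ids)]
        return out


class Pedigree:
    """Family structure: one record per individual, FAM-style.

    ``generation`` is 'founder' for parents and 'offspring' for analysis
    individuals.  Full siblings share both ``father_id`` and ``mother_id``.
    """

    COLUMNS = ["individual_id", "family_id", "father_id", "mother_id", "sex", "generation"]

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in table.columns]
        if missing:
            raise ValueError(f"pedigree table missing columns: {missing}")
        if table["individual_id"].duplicated().any():
            raise ValueError("duplicate individual ids in pedigree")
        self.table = table.reset_index(drop=True)
        self._by_id = self.table.set_index("individual_id")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def offspring(self) -> pd.DataFrame:
        return self.table[self.table["generation"] == "offspring"]

    def family_of(self, ids) -> pd.Series:
        return self._by_id.loc[np.asarray(ids, dtype=object), "family_id"]

    def sibships(self) -> list:
        """Offspring id arrays grouped by (father, mother), size >= 2."""
        off = self.offspring
        groups = off.groupby(["father_id", "mother_id"], sort=True)["individual_id"]
        return [np.sort(g.to_numpy()) for _, g in groups if len(g) >= 2]

    def sib_ids(self) -> np.ndarray:
        """Ids of all offspring that have at least one full sibling."""
        ships = self.sibships()
        if not ships:
            return np.array([], dtype=object)
        return np.concatenate(ships)

    def singleton_ids(self) -> np.ndarray:
        """Offspring without any full sibling (the non-sibling pool)."""
        sibs = set(self.sib_ids())
        off = self.offspring["individual_id"].to_numpy()
        return np.array([i for i in off if i not in sibs], dtype=object)


class PhenotypeTable:
    """Per-individual phenotype values for one trait.

    Binary traits take values in {0, 1}; quantitative traits are stored
    z-scored with the reference mean/SD retained for back-conversion.
    """

    def __init__(
        self,
        values: pd.Series,
        trait: str,
        kind: str,
        z_scored: bool = False,
        ref_mean: float = 0.0,
        ref_sd: float = 1.0,
    ):
        if kind not in ("binary", "quantitative"):
            raise ValueError("kind must be 'binary' or 'quantitative'")
        values = values.astype(float)
        if kind == "binary":
            bad = ~values.isin([0.0, 1.0])
            if bad.any():
                raise ValueError("binary phenotype values must be 0 or 1")
        self.values = values
        self.trait = trait
        self.kind = kind
        self.z_scored = z_scored
        self.ref_mean = float(ref_mean)
        self.ref_sd = float(ref_sd)

    def values_for(self, ids) -> np.ndarray:
        return self.values.loc[np.asarray(ids, dtype=object)].to_numpy()

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "individual_id": self.values.index,
                "trait": self.trait,
                "value": self.values.to_numpy(),
            }
        )
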