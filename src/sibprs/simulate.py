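"""Family-structured genotype/phenotype simulator.

Generates cohorts with the statistical structure a between-sibling
validation design is built to probe: full-sibling pairs (expected per-locus
IBD 0.5), unrelated training individuals, additive causal effects under a
liability-threshold or quantitative model, and three optional confounds —

* shared family environment (variance fraction ``c2``, identical for sibs),
* parental genetic nurture (``w_nurture`` times the mean parental genetic
  value enters the offspring phenotype through the environment), and
* two-subpopulation stratification (Balding–Nichols allele-frequency drift
  at ``fst`` plus an environmental offset ``env_offset`` for subpopulation B).

Loci are unlinked: transmission is independent per variant, so sibling
genotype correlation equals the expected kinship without genome-wide
sharing variance.  Founders (parents) are generated, used for transmission
and nurture, and excluded from the analysis cohort.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GenotypeMatrix, Pedigree, PhenotypeTable, SimConfig, TruthModel

__all__ = [
    "split_streams",
    "draw_founders",
    "transmit",
    "genetic_value",
    "assign_quantitative",
    "assign_case_control",
    "simulate_cohort",
    "Cohort",
]

_FAMILY_CHUNK = 2048  # families generated per block; fixed so seeds reproduce


def split_streams(seed: int) -> dict:
    """Split a master seed into named independent substreams."""
    names = ("frequencies", "effects", "founders", "transmission", "environment")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _ancestral_frequencies(config: SimConfig, rng) -> np.ndarray:
    return rng.uniform(config.maf_low, config.maf_high, size=config.n_variants)


def _subpop_frequencies(anc: np.ndarray, fst: float, rng) -> np.ndarray:
    """Per-subpopulation allele frequencies, shape (2, n_variants).

    With drift, each subpopulation draws from the Balding–Nichols
    distribution Beta(f(1-F)/F, (1-f)(1-F)/F), which has mean f and
    variance F*f*(1-f).
    """
    if fst == 0.0:
        return np.vstack([anc, anc])
    a = anc * (1.0 - fst) / fst
    b = (1.0 - anc) * (1.0 - fst) / fst
    out = np.vstack([rng.beta(a, b), rng.beta(a, b)])
    # guard against numerically degenerate draws
    return np.clip(out, 1e-6, 1.0 - 1e-6)


def draw_founders(config: SimConfig, rng, n_pairs: int | None = None, subpop: np.ndarray | None = None):
    """Draw founder parent pairs: haplotypes, pedigree rows, subpop labels.

    Returns ``(haplotypes, pedigree_rows, subpop, freqs)`` where
    ``haplotypes`` has shape (n_pairs, 2 parents, 2 haplotypes, n_variants)
    and ``freqs`` holds the two subpopulation frequency vectors.  Mating is
    random within subpopulation (each pair is drawn inside one label).
    """
    if n_pairs is None:
        n_pairs = config.n_families + config.n_unrelated
    anc = _ancestral_frequencies(config, rng)
    freqs = _subpop_frequencies(anc, config.fst, rng)
    if subpop is None:
        subpop = np.arange(n_pairs) % 2
    haps = _founder_haplotypes(freqs, subpop, config.n_variants, rng)
    rows = []
    for i in range(n_pairs):
        fam = f"F{i:06d}"
        rows.append((f"{fam}_P1", fam, "0", "0", 1, "founder"))
        rows.append((f"{fam}_P2", fam, "0", "0", 2, "founder"))
    ped = pd.DataFrame(rows, columns=Pedigree.COLUMNS)
    return haps, ped, subpop, freqs


def _founder_haplotypes(freqs: np.ndarray, subpop: np.ndarray, n_variants: int, rng) -> np.ndarray:
    """Bernoulli haplotypes, shape (n_pairs, 2, 2, n_variants) uint8."""
    n_pairs = len(subpop)
    p = freqs[subpop]  # (n_pairs, n_variants)
    u = rng.random(size=(n_pairs, 2, 2, n_variants))
    return (u < p[:, None, None, :]).astype(np.uint8)


def transmit(father_haps: np.ndarray, mother_haps: np.ndarray, n_offspring: int, rng) -> np.ndarray:
    """Mendelian transmission, independent per variant (unlinked loci).

    ``father_haps``/``mother_haps`` have shape (n_families, 2, n_variants).
    Each offspring inherits one uniformly chosen haplotype allele from each
    parent per variant; returns dosages (n_families, n_offspring, n_variants).
    """
    father_haps = np.asarray(father_haps)
    mother_haps = np.asarray(mother_haps)
    if father_haps.shape != mother_haps.shape:
        raise ValueError("parent haplotype arrays must have matching shapes")
    nf, two, p = father_haps.shape
    if two != 2:
        raise ValueError("each parent must carry exactly two haplotypes")
    fam_idx = np.arange(nf)[:, None, None]
    var_idx = np.arange(p)[None, None, :]
    pick_f = rng.integers(0, 2, size=(nf, n_offspring, p), dtype=np.uint8)
    pick_m = rng.integers(0, 2, size=(nf, n_offspring, p), dtype=np.uint8)
    dose = father_haps[fam_idx, pick_f, var_idx] + mother_haps[fam_idx, pick_m, var_idx]
    return dose.astype(np.uint8)


def genetic_value(
    dosages: np.ndarray,
    effects: np.ndarray,
    means: np.ndarray | None = None,
    sds: np.ndarray | None = None,
) -> np.ndarray:
    """Additive genetic value: standardized dosages dotted with effects.

    ``effects`` is full-length (one entry per variant, mostly zero); only
    nonzero columns are touched.  ``means``/``sds`` default to the cohort
    statistics of ``dosages`` and define the standardization reference.
    """
    effects = np.asarray(effects, dtype=float)
    if effects.shape[0] != dosages.shape[1]:
        raise ValueError("effect vector length must equal number of variants")
    nz = np.flatnonzero(effects)
    if nz.size == 0:
        return np.zeros(dosages.shape[0])
    d = dosages[:, nz].astype(float)
    mu = d.mean(axis=0) if means is None else np.asarray(means, dtype=float)[nz]
    sd = d.std(axis=0) if sds is None else np.asarray(sds, dtype=float)[nz]
    if np.any(sd == 0):
        raise ValueError("monomorphic variant among causal loci; cannot standardize")
    return (d - mu) / sd @ effects[nz]


def _compose_liability(
    gv: np.ndarray,
    family_codes: np.ndarray,
    n_families: int,
    parental_gv: np.ndarray,
    subpop_b: np.ndarray,
    config: SimConfig,
    rng,
) -> np.ndarray:
    """Raw phenotype/liability before z-scoring.

    y = gv + shared family environment (var c2) + w * mean parental gv
        + env_offset * 1[subpop B] + residual sized so that the total
        variance is 1 when all confounds are off.
    """
    var_resid = 1.0 - config.h2 - config.c2
    fam_env = rng.normal(0.0, np.sqrt(config.c2), size=n_families) if config.c2 > 0 else np.zeros(n_families)
    resid = rng.normal(0.0, np.sqrt(var_resid), size=len(gv)) if var_resid > 0 else np.zeros(len(gv))
    y = gv + fam_env[family_codes] + config.w_nurture * parental_gv + resid
    if config.env_offset != 0.0:
        y = y + config.env_offset * subpop_b
    return y


def assign_quantitative(
    gv: np.ndarray,
    family_codes: np.ndarray,
    n_families: int,
    parental_gv: np.ndarray,
    subpop_b: np.ndarray,
    config: SimConfig,
    rng,
    ids=None,
) -> PhenotypeTable:
    """Quantitative trait: composed liability, z-scored on the whole cohort."""
    y = _compose_liability(gv, family_codes, n_families, parental_gv, subpop_b, config, rng)
    mu, sd = float(np.mean(y)), float(np.std(y))
    z = (y - mu) / sd if sd > 0 else y - mu
    idx = pd.Index(ids if ids is not None else np.arange(len(y)))
    return PhenotypeTable(
        pd.Series(z, index=idx), config.trait, "quantitative",
        z_scored=True, ref_mean=mu, ref_sd=sd,
    )


def assign_case_control(liability: np.ndarray, prevalence: float, ids=None, trait: str = "trait"):
    """Threshold a standard-normal-scale liability at the (1-K) quantile.

    Returns ``(PhenotypeTable, threshold)``; case (1) iff liability exceeds
    the threshold, so realized prevalence is ~K when the liability is
    standard normal at cohort level.
    """
    if not (0.0 < prevalence < 1.0):
        raise ValueError("prevalence must lie in (0, 1)")
    thr = float(stats.norm.ppf(1.0 - prevalence))
    status = (np.asarray(liability) > thr).astype(float)
    idx = pd.Index(ids if ids is not None else np.arange(len(status)))
    table = PhenotypeTable(pd.Series(status, index=idx), trait, "binary")
    return table, thr


@dataclass
class Cohort:
    genotypes: GenotypeMatrix
    pedigree: Pedigree
    phenotypes: PhenotypeTable
    truth: TruthModel
    config: SimConfig


def simulate_cohort(config: SimConfig) -> Cohort:
    """Simulate a full cohort: genotypes, pedigree, phenotypes, truth.

    Families are laid out as ``n_unrelated`` single-child families followed
    by ``n_families`` sibships of ``n_sibs_per_family``; only offspring
    enter the analysis cohort.  Deterministic given ``config.seed``.
    """
    streams = split_streams(config.seed)
    anc = _ancestral_frequencies(config, streams["frequencies"])
    freqs = _subpop_frequencies(anc, config.fst, streams["frequencies"])

    causal_idx = np.sort(
        streams["effects"].choice(config.n_variants, size=config.n_causal, replace=False)
    )
    raw_eff = streams["effects"].normal(size=config.n_causal)

    n_single = config.n_unrelated
    n_sib_fams = config.n_families
    s = config.n_sibs_per_family if n_sib_fams else 0
    total_fams = n_single + n_sib_fams
    subpop = np.arange(total_fams) % 2
    n_children = n_single + n_sib_fams * s

    child_dose = np.empty((n_children, config.n_variants), dtype=np.uint8)
    parent_causal = np.empty((total_fams, 2, config.n_causal), dtype=np.uint8)

    rng_f = streams["founders"]
    rng_t = streams["transmission"]

    def _generate(fam_lo, fam_hi, n_off, child_offset):
        """Generate one block of families; returns rows written."""
        for lo in range(fam_lo, fam_hi, _FAMILY_CHUNK):
            hi = min(lo + _FAMILY_CHUNK, fam_hi)
            haps = _founder_haplotypes(freqs, subpop[lo:hi], config.n_variants, rng_f)
            dose = transmit(haps[:, 0], haps[:, 1], n_off, rng_t)
            n_rows = (hi - lo) * n_off
            start = child_offset + (lo - fam_lo) * n_off
            child_dose[start : start + n_rows] = dose.reshape(n_rows, -1)
            parent_causal[lo:hi] = haps[:, :, 0, causal_idx] + haps[:, :, 1, causal_idx]
        return (fam_hi - fam_lo) * n_off

    written = 0
    if n_single:
        written += _generate(0, n_single, 1, 0)
    if n_sib_fams:
        written += _generate(n_single, total_fams, s, written)
    assert written == n_children

    # ids and pedigree
    fam_ids = np.array([f"F{i:06d}" for i in range(total_fams)], dtype=object)
    child_ids, child_fam_codes, ped_rows = [], [], []
    for i in range(total_fams):
        fam = fam_ids[i]
        ped_rows.append((f"{fam}_P1", fam, "0", "0", 1, "founder"))
        ped_rows.append((f"{fam}_P2", fam, "0", "0", 2, "founder"))
        n_off = 1 if i < n_single else s
        for j in range(n_off):
            cid = f"{fam}_S{j + 1}"
            ped_rows.append((cid, fam, f"{fam}_P1", f"{fam}_P2", 1 + (j % 2), "offspring"))
            child_ids.append(cid)
            child_fam_codes.append(i)
    child_ids = np.array(child_ids, dtype=object)
    child_fam_codes = np.array(child_fam_codes)
    pedigree = Pedigree(pd.DataFrame(ped_rows, columns=Pedigree.COLUMNS))

    # genetic values on the child standardization reference
    mu_c = child_dose[:, causal_idx].astype(float).mean(axis=0) if config.n_causal else np.zeros(0)
    sd_c = child_dose[:, causal_idx].astype(float).std(axis=0) if config.n_causal else np.zeros(0)
    if config.n_causal and np.any(sd_c == 0):
        raise ValueError(
            "monomorphic causal variant; increase cohort size or maf_low"
        )
    effects = np.zeros(config.n_variants)
    if config.n_causal and config.h2 > 0:
        gv_raw = (child_dose[:, causal_idx] - mu_c) / sd_c @ raw_eff
        scale = np.sqrt(config.h2) / np.std(gv_raw)
        effects[causal_idx] = raw_eff * scale
        gv = gv_raw * scale
        pc = parent_causal.astype(float)
        par_gv = ((pc - mu_c) / sd_c) @ raw_eff * scale  # (total_fams, 2)
        parental_mean_gv = par_gv.mean(axis=1)[child_fam_codes]
    else:
        gv = np.zeros(n_children)
        parental_mean_gv = np.zeros(n_children)

    subpop_b = subpop[child_fam_codes].astype(float)
    rng_e = streams["environment"]
    liability_threshold = None
    if config.trait_kind == "quantitative":
        phen = assign_quantitative(
            gv, child_fam_codes, total_fams, parental_mean_gv, subpop_b, config, rng_e, ids=child_ids
        )
    else:
        liab = _compose_liability(
            gv, child_fam_codes, total_fams, parental_mean_gv, subpop_b, config, rng_e
        )
        liab = (liab - liab.mean()) / liab.std()
        phen, liability_threshold = assign_case_control(
            liab, config.prevalence, ids=child_ids, trait=config.trait
        )

    variant_ids = np.array([f"v{j:06d}" for j in range(config.n_variants)], dtype=object)
    meta = pd.DataFrame(
        {
            "freq": child_dose.mean(axis=0) / 2.0,
            "allele1": "A",
            "allele2": "G",
            "ancestral_freq": anc,
        },
        index=variant_ids,
    )
    gm = GenotypeMatrix(child_ids, variant_ids, child_dose, meta)

    truth = TruthModel(
        causal_effects=effects,
        variance_components={
            "h2": config.h2,
            "c2": config.c2,
            "nurture_var": config.w_nurture**2 * float(np.var(parental_mean_gv)),
            "stratification_var": config.env_offset**2 * float(np.var(subpop_b)),
        },
        liability_threshold=liability_threshold,
        subpop_assignment=pd.Series(subpop, index=fam_ids),
        genetic_values=pd.Series(gv, index=child_ids),
        parental_mean_gv=pd.Series(parental_mean_gv, index=child_ids),
    )
    return Cohort(gm, pedigree, phen, truth, config)
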