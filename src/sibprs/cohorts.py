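"""Evaluation-cohort construction: sibling pairs, randomized baselines,
affected-sibling-pair (ASP) restrictions, high-risk/normal-risk subsets,
and sibling trios.

Pair sets are plain DataFrames with columns ``id_a``, ``id_b``,
``family_a``, ``family_b`` and ``kind`` ('sibling' | 'random'), plus
annotation columns added by the filters below.
"""
from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd

from .datatypes import Pedigree

__all__ = [
    "extract_sib_pairs",
    "single_case_pairs",
    "random_pairs",
    "asp_restrict",
    "highrisk_normal_pairs",
    "extract_trios",
]

PAIR_COLUMNS = ["id_a", "id_b", "family_a", "family_b", "kind"]


def extract_sib_pairs(pedigree: Pedigree, one_pair_per_family: bool = False) -> pd.DataFrame:
    """All unordered full-sibling pairs; a sibship of s yields s(s-1)/2.

    ``one_pair_per_family`` keeps only the first (lexicographic) pair per
    sibship, the conservative choice when error bars must assume
    independent pairs.
    """
    rows = []
    for sibs in pedigree.sibships():
        fam = pedigree.family_of([sibs[0]]).iloc[0]
        pairs = combinations(sibs, 2)
        if one_pair_per_family:
            pairs = [next(iter(pairs))]
        for a, b in pairs:
            rows.append((a, b, fam, fam, "sibling"))
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)


def single_case_pairs(pairs: pd.DataFrame, status: pd.Series) -> pd.DataFrame:
    """Keep only status-discordant pairs, annotated with case/control ids.

    Pairs with a missing status on either side are dropped (count recorded
    in ``.attrs['n_dropped_missing']``).  Idempotent.
    """
    if pairs.empty:
        out = pairs.copy()
        out["case_id"] = pd.Series(dtype=object)
        out["control_id"] = pd.Series(dtype=object)
        return out
    sa = status.reindex(pairs["id_a"]).to_numpy()
    sb = status.reindex(pairs["id_b"]).to_numpy()
    missing = np.isnan(sa) | np.isnan(sb)
    keep = ~missing & (sa != sb)
    out = pairs.loc[keep].copy()
    out["case_id"] = np.where(sa[keep] == 1, out["id_a"], out["id_b"])
    out["control_id"] = np.where(sa[keep] == 1, out["id_b"], out["id_a"])
    out.attrs["n_dropped_missing"] = int(missing.sum())
    return out.reset_index(drop=True)


def random_pairs(
    individuals,
    status: pd.Series,
    n_pairs: int,
    rng,
    family_of: pd.Series,
    max_attempts: int = 200,
) -> pd.DataFrame:
    """Random non-sibling case–control pairs, exactly one case per pair.

    Individuals are drawn without replacement within the draw; members of a
    pair always come from different families.  Raises if no valid pairing
    of the requested size exists.
    """
    ids = np.asarray(individuals, dtype=object)
    st = status.reindex(ids)
    cases = ids[(st == 1).to_numpy()]
    ctrls = ids[(st == 0).to_numpy()]
    if n_pairs > min(len(cases), len(ctrls)):
        raise ValueError(
            f"requested {n_pairs} pairs but only {len(cases)} cases / {len(ctrls)} controls"
        )
    pick_cases = rng.choice(cases, size=n_pairs, replace=False)
    pick_ctrls = rng.choice(ctrls, size=n_pairs, replace=False)
    fam = family_of
    fc = fam.reindex(pick_cases).to_numpy()
    for _ in range(max_attempts):
        fk = fam.reindex(pick_ctrls).to_numpy()
        bad = np.flatnonzero(fc == fk)
        if bad.size == 0:
            break
        # re-shuffle the controls of the offending pairs together with a
        # random slice of good ones so a fix always exists when feasible
        n_extra = min(len(pick_ctrls) - bad.size, bad.size + 8)
        good = np.setdiff1d(np.arange(n_pairs), bad)
        mix = np.concatenate([bad, rng.choice(good, size=n_extra, replace=False)]) if n_extra else bad
        pick_ctrls[mix] = rng.permutation(pick_ctrls[mix])
    else:
        raise ValueError("could not construct cross-family random pairs")
    out = pd.DataFrame(
        {
            "id_a": pick_cases,
            "id_b": pick_ctrls,
            "family_a": fam.reindex(pick_cases).to_numpy(),
            "family_b": fam.reindex(pick_ctrls).to_numpy(),
            "kind": "random",
            "case_id": pick_cases,
            "control_id": pick_ctrls,
        }
    )
    return out


def random_pairs_quantitative(
    individuals,
    n_pairs: int,
    rng,
    family_of: pd.Series,
    max_attempts: int = 200,
) -> pd.DataFrame:
    """Random cross-family pairs without a case/control constraint.

    Used as the non-sibling baseline for quantitative traits: individuals
    are drawn without replacement and paired so no pair lies within one
    family.
    """
    ids = np.asarray(individuals, dtype=object)
    if 2 * n_pairs > len(ids):
        raise ValueError(f"requested {n_pairs} pairs from only {len(ids)} individuals")
    pick = rng.choice(ids, size=2 * n_pairs, replace=False)
    a, b = pick[:n_pairs].copy(), pick[n_pairs:].copy()
    fa = family_of.reindex(a).to_numpy()
    for _ in range(max_attempts):
        fb = family_of.reindex(b).to_numpy()
        bad = np.flatnonzero(fa == fb)
        if bad.size == 0:
            break
        n_extra = min(n_pairs - bad.size, bad.size + 8)
        good = np.setdiff1d(np.arange(n_pairs), bad)
        mix = np.concatenate([bad, rng.choice(good, size=n_extra, replace=False)]) if n_extra else bad
        b[mix] = rng.permutation(b[mix])
    else:
        raise ValueError("could not construct cross-family random pairs")
    return pd.DataFrame(
        {
            "id_a": a,
            "id_b": b,
            "family_a": family_of.reindex(a).to_numpy(),
            "family_b": family_of.reindex(b).to_numpy(),
            "kind": "random",
        }
    )


def asp_restrict(individuals, pedigree: Pedigree, status: pd.Series):
    """Affected-sibling-pair cohort.

    Controls must have at least one sibling who is a case; cases must have
    at least one *other* sibling who is a case.  Returns (case_ids,
    control_ids).  Idempotent by construction.
    """
    ids = set(np.asarray(individuals, dtype=object))
    case_ids, control_ids = [], []
    for sibs in pedigree.sibships():
        st = status.reindex(sibs).to_numpy()
        n_cases = int(np.nansum(st == 1))
        if n_cases == 0:
            continue
        for s, v in zip(sibs, st):
            if s not in ids or np.isnan(v):
                continue
            n_other_affected = n_cases - (1 if v == 1 else 0)
            if n_other_affected >= 1:
                (case_ids if v == 1 else control_ids).append(s)
    return np.array(case_ids, dtype=object), np.array(control_ids, dtype=object)


def highrisk_normal_pairs(
    pairs: pd.DataFrame,
    z: pd.Series,
    hi_z: float,
    normal_z: float = 1.0,
) -> pd.DataFrame:
    """Pairs where exactly one member is a high-risk score outlier.

    Kept when one member's z-score is strictly above ``hi_z`` and the
    other's strictly below ``normal_z`` (the ensemble-mean score defines
    the subset).  Annotates ``high_id`` / ``other_id``.  ``hi_z`` equal to
    ``normal_z`` is the degenerate sweep start (one member above, one
    below the same cut) and is allowed; ``hi_z < normal_z`` is rejected.
    """
    if hi_z < normal_z:
        raise ValueError("hi_z must not be below normal_z")
    if pairs.empty:
        out = pairs.copy()
        out["high_id"] = pd.Series(dtype=object)
        out["other_id"] = pd.Series(dtype=object)
        return out
    za = z.reindex(pairs["id_a"]).to_numpy()
    zb = z.reindex(pairs["id_b"]).to_numpy()
    a_high = (za > hi_z) & (zb < normal_z)
    b_high = (zb > hi_z) & (za < normal_z)
    keep = a_high | b_high
    out = pairs.loc[keep].copy()
    out["high_id"] = np.where(a_high[keep], out["id_a"], out["id_b"])
    out["other_id"] = np.where(a_high[keep], out["id_b"], out["id_a"])
    return out.reset_index(drop=True)


def extract_trios(pedigree: Pedigree) -> pd.DataFrame:
    """All 3-subsets of each sibship with >= 3 full siblings."""
    rows = []
    for sibs in pedigree.sibships():
        if len(sibs) < 3:
            continue
        fam = pedigree.family_of([sibs[0]]).iloc[0]
        for trio in combinations(sibs, 3):
            rows.append((*trio, fam))
    return pd.DataFrame(rows, columns=["id_a", "id_b", "id_c", "family_id"])
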