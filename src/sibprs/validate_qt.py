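"""Quantitative-trait validation statistics.

For pairs (sibling or randomized non-sibling) the battery computes the
correlation between score differences and phenotype differences
rho(dPGS, dy), the fraction of pairs where score rank order matches
phenotype rank order, and that fraction restricted to pairs whose actual
phenotype gap exceeds a threshold.  Under joint normality the rank-call
fraction obeys the arcsine law 1/2 + arcsin(rho)/pi, which the tests use
as an independent oracle.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import PhenotypeTable
from .metrics import FractionWithError, clopper_pearson_halfwidth, pearson
from .train import ScoreTable

__all__ = [
    "PairDifferenceResult",
    "pair_differences",
    "sign_agreement_fraction",
    "rank_call_fraction",
    "rank_call_by_gap",
    "trio_rank_call",
]


@dataclass
class PairDifferenceResult:
    """Signed per-pair differences and their score/phenotype correlation."""

    kind: str
    n_pairs: int
    rho_per_predictor: np.ndarray
    rho_mean: float
    rho_sd: float
    records: pd.DataFrame  # delta_y + delta_score_j columns + ensemble delta

    @property
    def delta_y(self) -> np.ndarray:
        return self.records["delta_y"].to_numpy()


def pair_differences(
    pairs: pd.DataFrame,
    scores: ScoreTable,
    y: PhenotypeTable,
    rng=None,
) -> PairDifferenceResult:
    """Per-pair signed differences under a randomized member ordering.

    The within-pair ordering is randomized once per pair (seeded) so the
    signed differences have symmetric marginals; rho(dPGS, dy) is invariant
    to the ordering since both signs flip together.  Pairs with a missing
    phenotype are dropped.
    """
    if pairs.empty:
        raise ValueError("empty pair set")
    ya = y.values.reindex(pairs["id_a"]).to_numpy()
    yb = y.values.reindex(pairs["id_b"]).to_numpy()
    ok = ~(np.isnan(ya) | np.isnan(yb))
    sub = pairs.loc[ok]
    ya, yb = ya[ok], yb[ok]
    if rng is None:
        rng = np.random.default_rng(0)
    flip = rng.random(len(sub)) < 0.5
    first = np.where(flip, sub["id_b"], sub["id_a"])
    second = np.where(flip, sub["id_a"], sub["id_b"])
    dy = np.where(flip, yb - ya, ya - yb)
    A = scores.matrix_for(first)
    B = scores.matrix_for(second)
    D = A - B
    rho = np.array([pearson(D[:, j], dy) for j in range(scores.n_predictors)])
    rec = pd.DataFrame(D, columns=[f"delta_score_{j + 1}" for j in range(D.shape[1])])
    rec.insert(0, "delta_y", dy)
    rec["delta_ensemble"] = D.mean(axis=1)
    kind = sub["kind"].iloc[0] if len(sub) else "unknown"
    return PairDifferenceResult(
        kind=kind,
        n_pairs=len(rec),
        rho_per_predictor=rho,
        rho_mean=float(rho.mean()),
        rho_sd=float(rho.std(ddof=1)) if len(rho) > 1 else 0.0,
        records=rec,
    )


def sign_agreement_fraction(delta_score: np.ndarray, delta_y: np.ndarray) -> float:
    """Fraction of pairs with sign(dPGS) == sign(dy); ties count 1/2.

    This is the computational kernel of :func:`rank_call_fraction`.
    """
    ds = np.asarray(delta_score, dtype=float)
    dy = np.asarray(delta_y, dtype=float)
    if len(ds) != len(dy) or len(ds) == 0:
        raise ValueError("inputs must be equal-length and non-empty")
    prod = np.sign(ds) * np.sign(dy)
    return float(np.where(prod > 0, 1.0, np.where(prod == 0, 0.5, 0.0)).mean())


def rank_call_fraction(
    pairs: pd.DataFrame,
    scores: ScoreTable,
    y: PhenotypeTable,
    rng=None,
) -> FractionWithError:
    """How often PGS rank order agrees with phenotype rank order.

    Computed per predictor; reported as ensemble mean with SD over the
    predictors and a Clopper–Pearson sampling error.
    """
    diff = pair_differences(pairs, scores, y, rng=rng)
    fracs = np.array(
        [
            sign_agreement_fraction(diff.records[f"delta_score_{j + 1}"], diff.delta_y)
            for j in range(len(diff.rho_per_predictor))
        ]
    )
    n = diff.n_pairs
    mean = float(fracs.mean())
    return FractionWithError(
        n=n,
        k=mean * n,
        fraction=mean,
        ensemble_sd=float(fracs.std(ddof=1)) if len(fracs) > 1 else 0.0,
        sampling_err=clopper_pearson_halfwidth(mean * n, n),
    )


def rank_call_by_gap(
    pairs: pd.DataFrame,
    scores: ScoreTable,
    y: PhenotypeTable,
    gap_thresholds,
    rng=None,
) -> pd.DataFrame:
    """Rank-call fraction restricted to pairs with |dy| above a threshold.

    Retention uses the actual phenotype gap; the five predictors are then
    each evaluated on the fixed retained subset.  Threshold 0 reduces to
    :func:`rank_call_fraction`.
    """
    gaps = np.asarray(list(gap_thresholds), dtype=float)
    if gaps.size == 0:
        raise ValueError("gap threshold grid is empty")
    if np.any(np.diff(gaps) < 0) or np.any(gaps < 0):
        raise ValueError("gap thresholds must be non-negative and increasing")
    diff = pair_differences(pairs, scores, y, rng=rng)
    dy = diff.delta_y
    n_pred = len(diff.rho_per_predictor)
    rows = []
    for g in gaps:
        keep = np.abs(dy) > g
        n = int(keep.sum())
        if n == 0:
            rows.append((g, 0, np.nan, np.nan, np.nan, np.nan))
            continue
        fracs = np.array(
            [
                sign_agreement_fraction(
                    diff.records[f"delta_score_{j + 1}"].to_numpy()[keep], dy[keep]
                )
                for j in range(n_pred)
            ]
        )
        mean = float(fracs.mean())
        sd = float(fracs.std(ddof=1)) if n_pred > 1 else 0.0
        cp = clopper_pearson_halfwidth(mean * n, n)
        rows.append((g, n, mean, sd, cp, max(sd, cp)))
    return pd.DataFrame(
        rows,
        columns=["gap_threshold", "n_pairs", "fraction", "ensemble_sd", "cp_halfwidth", "error"],
    )


def trio_rank_call(trios: pd.DataFrame, scores: ScoreTable, y: PhenotypeTable) -> FractionWithError:
    """Among sibling trios: how often the top-scoring member is the one
    with the largest phenotype value; ties share credit equally."""
    if trios.empty:
        raise ValueError("empty trio set")
    ids = trios[["id_a", "id_b", "id_c"]].to_numpy()
    yy = y.values.reindex(ids.ravel()).to_numpy().reshape(ids.shape)
    ok = ~np.isnan(yy).any(axis=1)
    ids, yy = ids[ok], yy[ok]
    if len(ids) == 0:
        raise ValueError("no trios with complete phenotypes")
    z = scores.ensemble_mean()
    zz = z.reindex(ids.ravel()).to_numpy().reshape(ids.shape)
    top_score = zz == zz.max(axis=1, keepdims=True)
    top_phen = yy == yy.max(axis=1, keepdims=True)
    hit = (top_score & top_phen).any(axis=1)
    credit = np.where(hit, 1.0 / top_score.sum(axis=1), 0.0)
    n = len(credit)
    k = float(credit.sum())
    return FractionWithError(
        n=n, k=k, fraction=k / n, ensemble_sd=0.0,
        sampling_err=clopper_pearson_halfwidth(k, n),
    )
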