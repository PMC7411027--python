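"""Case/control validation statistics.

Implements the between-sibling battery for disease traits: discordant-pair
call rates, high-risk outlier identification, continuously swept high-risk
thresholds, prevalence-versus-score-threshold curves with a two-Gaussian
prediction, AUC on the full versus affected-sibling-pair (ASP) cohorts,
and trio calling.  Pair credit for exact score ties is 1/2 (Mann–Whitney
tie convention).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import cohorts as _cohorts
from .datatypes import Pedigree
from .metrics import (
    FractionWithError,
    auc as _auc,
    clopper_pearson_halfwidth,
    wald_binomial_sd,
)
from .train import ScoreTable

__all__ = [
    "MixtureParams",
    "estimate_mixture",
    "sibling_call_rate",
    "highrisk_call_rate",
    "threshold_sweep",
    "prevalence_by_threshold",
    "gaussian_mixture_prevalence",
    "asp_prevalence",
    "auc_report",
    "trio_call_rate",
]

MIN_COUNT = 5  # bins/subsets below this are reported undefined


def _per_predictor_fraction(pairs: pd.DataFrame, scores: ScoreTable, a_col: str, b_col: str):
    """Per-predictor fraction of pairs where the ``a_col`` member outscores."""
    A = scores.matrix_for(pairs[a_col].to_numpy())
    B = scores.matrix_for(pairs[b_col].to_numpy())
    credit = np.where(A > B, 1.0, np.where(A == B, 0.5, 0.0))
    return credit.mean(axis=0), credit.sum(axis=0)


def sibling_call_rate(pairs: pd.DataFrame, scores: ScoreTable) -> FractionWithError:
    """Fraction of single-case pairs where the case has the higher score.

    Reported as the mean over the predictor ensemble with the
    between-predictor SD; the sampling error is a 68% Clopper–Pearson
    half-width at the mean fraction.
    """
    if pairs.empty:
        raise ValueError("empty pair set")
    fracs, _ = _per_predictor_fraction(pairs, scores, "case_id", "control_id")
    n = len(pairs)
    mean = float(fracs.mean())
    sd = float(fracs.std(ddof=1)) if len(fracs) > 1 else 0.0
    return FractionWithError(
        n=n,
        k=mean * n,
        fraction=mean,
        ensemble_sd=sd,
        sampling_err=clopper_pearson_halfwidth(mean * n, n),
    )


def highrisk_call_rate(pairs: pd.DataFrame, scores: ScoreTable | None = None):
    """Call rate on high-risk/normal-risk pairs (pre-filtered).

    ``pairs`` must carry ``high_id``/``other_id`` annotations from
    :func:`sibprs.cohorts.highrisk_normal_pairs` and ``case_id`` statuses.
    Returns None when no pair qualifies (printed "-" in the tables).
    """
    n = len(pairs)
    if n == 0:
        return None
    high_is_case = pairs["high_id"].to_numpy() == pairs["case_id"].to_numpy()
    # status, not score, decides success, so the fraction is fixed given the
    # (ensemble-mean defined) subset; per-predictor spread enters through
    # threshold_sweep, here the errors are Wald/Clopper-Pearson.
    k = float(high_is_case.sum())
    frac = k / n
    return FractionWithError(
        n=n,
        k=k,
        fraction=frac,
        ensemble_sd=0.0,
        sampling_err=clopper_pearson_halfwidth(k, n),
    )


def threshold_sweep(
    pairs: pd.DataFrame,
    scores: ScoreTable,
    z_grid,
    normal_z: float = 1.0,
) -> pd.DataFrame:
    """High-risk call rate versus the high-risk z threshold.

    The subset at each threshold is defined by the ensemble-mean score;
    the per-predictor spread of the resulting call fraction supplies the
    ensemble SD, and the error column is max(ensemble SD, CP half-width).
    Qualifying pair sets are nested as the threshold tightens; points with
    fewer than MIN_COUNT pairs are left undefined (not plotted).
    """
    z = scores.ensemble_mean()
    rows = []
    for t in z_grid:
        sub = _cohorts.highrisk_normal_pairs(pairs, z, hi_z=float(t), normal_z=normal_z)
        n = len(sub)
        if n < MIN_COUNT:
            rows.append((t, n, np.nan, np.nan, np.nan, np.nan))
            continue
        high_is_case = sub["high_id"].to_numpy() == sub["case_id"].to_numpy()
        k = float(high_is_case.sum())
        frac = k / n
        # per-predictor subsets: each member score re-defines the outlier set
        member_fracs = []
        for j in range(scores.n_predictors):
            sub_j = _cohorts.highrisk_normal_pairs(
                pairs, scores.column(j), hi_z=float(t), normal_z=normal_z
            )
            if len(sub_j) >= MIN_COUNT:
                hj = sub_j["high_id"].to_numpy() == sub_j["case_id"].to_numpy()
                member_fracs.append(hj.mean())
        ens_sd = float(np.std(member_fracs, ddof=1)) if len(member_fracs) > 1 else 0.0
        cp = clopper_pearson_halfwidth(k, n)
        rows.append((t, n, frac, ens_sd, cp, max(ens_sd, cp)))
    return pd.DataFrame(
        rows, columns=["hi_z", "n_pairs", "fraction", "ensemble_sd", "cp_halfwidth", "error"]
    )


@dataclass
class MixtureParams:
    """Six parameters of the two-Gaussian score model for cases/controls."""

    mu_case: float
    sd_case: float
    n_case: int
    mu_ctrl: float
    sd_ctrl: float
    n_ctrl: int

    def __post_init__(self):
        if self.sd_case <= 0 or self.sd_ctrl <= 0:
            raise ValueError("mixture SDs must be positive")
        if self.n_case < 1 or self.n_ctrl < 1:
            raise ValueError("mixture counts must be >= 1")


def estimate_mixture(z: pd.Series, status: pd.Series) -> MixtureParams:
    """Moment-match the two-Gaussian model from scores and statuses."""
    s = status.reindex(z.index)
    case = z[s == 1].to_numpy()
    ctrl = z[s == 0].to_numpy()
    if len(case) < 2 or len(ctrl) < 2:
        raise ValueError("need at least 2 cases and 2 controls")
    return MixtureParams(
        float(case.mean()), float(case.std(ddof=1)), len(case),
        float(ctrl.mean()), float(ctrl.std(ddof=1)), len(ctrl),
    )


def prevalence_by_threshold(z: pd.Series, status: pd.Series, z_grid, direction: str) -> pd.DataFrame:
    """Affected fraction among individuals below/above a score threshold.

    direction='below' keeps z < t (risk reduction by excluding high
    scores); 'above' keeps z > t.  Bins with fewer than MIN_COUNT
    individuals are undefined.  The overall prevalence is recorded in
    ``.attrs['overall_prevalence']`` (the reference line in the figures).
    """
    if direction not in ("below", "above"):
        raise ValueError("direction must be 'below' or 'above'")
    zz = z.to_numpy(dtype=float)
    st = status.reindex(z.index).to_numpy(dtype=float)
    rows = []
    for t in z_grid:
        mask = zz < t if direction == "below" else zz > t
        n = int(mask.sum())
        if n < MIN_COUNT:
            rows.append((t, n, np.nan, np.nan))
            continue
        k = float(st[mask].sum())
        frac = k / n
        rows.append((t, n, frac, wald_binomial_sd(k, n)))
    out = pd.DataFrame(rows, columns=["threshold", "n", "fraction", "binomial_sd"])
    out.attrs["overall_prevalence"] = float(np.nanmean(st))
    out.attrs["direction"] = direction
    return out


def gaussian_mixture_prevalence(params: MixtureParams, z_grid, direction: str) -> pd.DataFrame:
    """Predicted affected fraction from the two-Gaussian model.

    For 'above': n1*Phi_c((t-mu1)/sd1) / (n1*Phi_c(...) + n0*Phi_c(...));
    'below' uses CDFs.  This is the model-implied risk as a function of
    score, needing only the six mixture parameters.
    """
    if direction not in ("below", "above"):
        raise ValueError("direction must be 'below' or 'above'")
    t = np.asarray(z_grid, dtype=float)
    if direction == "above":
        wc = params.n_case * stats.norm.sf(t, params.mu_case, params.sd_case)
        wn = params.n_ctrl * stats.norm.sf(t, params.mu_ctrl, params.sd_ctrl)
    else:
        wc = params.n_case * stats.norm.cdf(t, params.mu_case, params.sd_case)
        wn = params.n_ctrl * stats.norm.cdf(t, params.mu_ctrl, params.sd_ctrl)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = wc / (wc + wn)
    return pd.DataFrame({"threshold": t, "predicted_fraction": frac})


def asp_prevalence(
    z: pd.Series,
    status: pd.Series,
    pedigree: Pedigree,
    z_grid,
    direction: str,
    with_mixture: bool = True,
):
    """Prevalence-vs-threshold restricted to the ASP cohort.

    The baseline reference becomes the ASP prevalence (individuals with an
    affected sibling are at elevated risk overall); a mixture-model
    prediction is attached for sparse conditions.
    """
    case_ids, ctrl_ids = _cohorts.asp_restrict(z.index.to_numpy(), pedigree, status)
    ids = np.concatenate([case_ids, ctrl_ids])
    if len(ids) == 0:
        raise ValueError("ASP cohort is empty")
    z_asp = z.loc[ids]
    curve = prevalence_by_threshold(z_asp, status, z_grid, direction)
    if with_mixture and len(case_ids) >= 2 and len(ctrl_ids) >= 2:
        params = estimate_mixture(z_asp, status)
        pred = gaussian_mixture_prevalence(params, z_grid, direction)
        curve = curve.merge(pred, on="threshold")
    return curve


def auc_report(scores: ScoreTable, status: pd.Series, pedigree: Pedigree) -> pd.DataFrame:
    """Per-cohort AUC: full sibling test set versus the ASP restriction.

    One row per cohort with case/control counts, the ensemble-mean AUC and
    the SD among the five predictors; the ASP row is NaN when a class is
    absent there.
    """
    all_ids = scores.sample_ids
    case_ids, ctrl_ids = _cohorts.asp_restrict(all_ids, pedigree, status)
    rows = []
    for name, ids in (("all", all_ids), ("asp", np.concatenate([case_ids, ctrl_ids]))):
        st = status.reindex(ids).to_numpy(dtype=float)
        n1, n0 = int((st == 1).sum()), int((st == 0).sum())
        if n1 == 0 or n0 == 0:
            rows.append((name, n1, n0, np.nan, np.nan))
            continue
        M = scores.matrix_for(ids)
        aucs = [
            _auc(M[:, j], st) for j in range(scores.n_predictors)
        ]
        rows.append(
            (name, n1, n0, float(np.mean(aucs)), float(np.std(aucs, ddof=1)) if len(aucs) > 1 else 0.0)
        )
    return pd.DataFrame(rows, columns=["cohort", "n_cases", "n_controls", "auc", "ensemble_sd"])


def trio_call_rate(trios: pd.DataFrame, scores: ScoreTable, status: pd.Series) -> FractionWithError:
    """Among single-case trios: how often the case has the highest score.

    Uses the ensemble-mean score; exact ties at the maximum share credit
    equally.  Null scores give 1/3 by symmetry.
    """
    if trios.empty:
        raise ValueError("empty trio set")
    ids = trios[["id_a", "id_b", "id_c"]].to_numpy()
    st = status.reindex(ids.ravel()).to_numpy(dtype=float).reshape(ids.shape)
    single_case = st.sum(axis=1) == 1
    ids = ids[single_case]
    st = st[single_case]
    if len(ids) == 0:
        raise ValueError("no single-case trios")
    z = scores.ensemble_mean()
    zz = z.reindex(ids.ravel()).to_numpy().reshape(ids.shape)
    zmax = zz.max(axis=1, keepdims=True)
    at_max = zz == zmax
    case_at_max = (at_max & (st == 1)).any(axis=1)
    credit = np.where(case_at_max, 1.0 / at_max.sum(axis=1), 0.0)
    n = len(credit)
    k = float(credit.sum())
    return FractionWithError(
        n=n, k=k, fraction=k / n, ensemble_sd=0.0,
        sampling_err=clopper_pearson_halfwidth(k, n),
    )
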