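"""L1-penalized polygenic predictor construction.

The pipeline follows the standard sparse-regression recipe for biobank
training data: (1) single-marker OLS of the phenotype on each SNP dosage
over the non-sibling training pool, (2) preselection of the top-k SNPs by
p-value rank, (3) the full LASSO regularization path

    O(lambda, beta) = 1/2 ||y - X beta||^2 + n * lambda * ||beta||_1

on standardized inputs, and (4) selection of the penalty that maximizes a
held-out performance metric (AUC for case/control, Pearson correlation for
quantitative traits).  Five predictors are trained on five non-overlapping
holdout sets so the ensemble spread estimates training noise.  Binary
phenotypes are treated linearly (y in {0,1}) throughout, including the
association scan.

The path itself is computed with scikit-learn's coordinate-descent
``lasso_path``; with alpha = lambda the two objectives share minimizers
(sklearn divides the L2 term by n).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import lasso_path

from .datatypes import GenotypeMatrix, Pedigree, PhenotypeTable
from .metrics import auc as _auc

__all__ = [
    "single_marker_regression",
    "rank_select",
    "fit_lasso_path",
    "lasso_objective",
    "kkt_residuals",
    "select_lambda",
    "train_ensemble",
    "compute_scores",
    "TrainConfig",
    "LassoPath",
    "Predictor",
    "PredictorEnsemble",
    "ScoreTable",
]

_COL_CHUNK = 1024  # columns per block in the vectorized association scan


def single_marker_regression(G: GenotypeMatrix, y: PhenotypeTable, training_ids) -> pd.DataFrame:
    """Per-variant OLS of phenotype on dosage: slope, SE, p-value.

    Binary phenotypes enter as 0/1.  Monomorphic variants get NaN slope and
    p-value and are ranked last by :func:`rank_select`.
    """
    rows = G.sample_indexer(training_ids)
    X = G.dosages[rows, :]
    yy = y.values_for(training_ids)
    n = len(yy)
    if n < 3:
        raise ValueError("need at least 3 training samples")
    sy = yy.sum()
    syy = float(yy @ yy)
    p = X.shape[1]
    slope = np.empty(p)
    se = np.empty(p)
    for lo in range(0, p, _COL_CHUNK):
        hi = min(lo + _COL_CHUNK, p)
        Xi = X[:, lo:hi].astype(np.float64)
        sx = Xi.sum(axis=0)
        sxx = np.einsum("ij,ij->j", Xi, Xi)
        sxy = yy @ Xi
        Sxx = sxx - sx * sx / n
        Sxy = sxy - sx * sy / n
        with np.errstate(divide="ignore", invalid="ignore"):
            b = Sxy / Sxx
            sse = (syy - sy * sy / n) - b * Sxy
            sigma2 = np.maximum(sse, 0.0) / (n - 2)
            s = np.sqrt(sigma2 / Sxx)
        b[Sxx == 0] = np.nan
        s[Sxx == 0] = np.nan
        slope[lo:hi] = b
        se[lo:hi] = s
    with np.errstate(divide="ignore", invalid="ignore"):
        t = slope / se
    pval = 2.0 * stats.t.sf(np.abs(t), n - 2)
    # perfect fits (se = 0, |t| = inf) underflow to the smallest positive p;
    # only monomorphic variants stay undefined
    pval = np.where(np.isnan(t), np.nan, np.maximum(pval, np.finfo(float).tiny))
    return pd.DataFrame(
        {"slope": slope, "se": se, "p_value": pval},
        index=pd.Index(G.variant_ids, name="variant_id"),
    )


def rank_select(assoc: pd.DataFrame, k: int) -> np.ndarray:
    """The k variants with smallest p-values; ties break by variant id.

    Undefined (NaN) p-values rank last.  k larger than the number of
    variants returns everything.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    pv = assoc["p_value"].to_numpy(dtype=float)
    pv = np.where(np.isnan(pv), np.inf, pv)
    ids = assoc.index.to_numpy(dtype=object)
    order = np.lexsort((ids, pv))
    return ids[order[: min(k, len(ids))]]


@dataclass
class LassoPath:
    """A full regularization path on standardized inputs.

    ``coefficients`` has shape (n_lambdas, k) in standardized-X units;
    ``lambda_grid`` is strictly decreasing starting at lambda_max (where
    all coefficients are exactly zero).  The standardization reference
    (per-variant mean/SD and phenotype mean) is frozen at training time.
    """

    variant_ids: np.ndarray
    lambda_grid: np.ndarray
    coefficients: np.ndarray
    intercepts: np.ndarray
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: float


def fit_lasso_path(
    X: np.ndarray,
    y: np.ndarray,
    variant_ids=None,
    n_lambdas: int = 100,
    lambda_min_ratio: float = 1e-3,
    tol: float = 1e-8,
    max_iter: int = 2000,
) -> LassoPath:
    """Fit the LASSO path of y on column-standardized X.

    lambda_max = max_j |x_j^T y| / n (computed on centered, standardized
    data), and the grid descends geometrically over ``n_lambdas`` points to
    lambda_max * lambda_min_ratio.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != len(y):
        raise ValueError("X and y shapes are inconsistent")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    if not np.isfinite(X).all() or not np.isfinite(y).all():
        raise ValueError("non-finite values in inputs")
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("monomorphic column passed to fit_lasso_path")
    Xs = (X - mu) / sd
    ym = float(y.mean())
    yc = y - ym
    try:
        alphas, coefs, _ = lasso_path(
            Xs, yc, eps=lambda_min_ratio, alphas=n_lambdas, tol=tol, max_iter=max_iter
        )
    except TypeError:  # scikit-learn < 1.9: alphas must be an array
        alphas, coefs, _ = lasso_path(
            Xs, yc, eps=lambda_min_ratio, n_alphas=n_lambdas, tol=tol, max_iter=max_iter
        )
    if variant_ids is None:
        variant_ids = np.array([f"x{j}" for j in range(X.shape[1])], dtype=object)
    return LassoPath(
        variant_ids=np.asarray(variant_ids, dtype=object),
        lambda_grid=alphas,
        coefficients=coefs.T,
        intercepts=np.full(len(alphas), ym),
        x_mean=mu,
        x_sd=sd,
        y_mean=ym,
    )


def lasso_objective(Xs: np.ndarray, yc: np.ndarray, beta: np.ndarray, lam: float) -> float:
    """O(lambda, beta) = 1/2 ||y - X beta||^2 + n lambda ||beta||_1."""
    r = yc - Xs @ beta
    return float(0.5 * r @ r + len(yc) * lam * np.abs(beta).sum())


def kkt_residuals(path: LassoPath, X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Max KKT violation at each path point on the training data.

    For active coordinates |x_j^T r| / n must equal lambda; for inactive
    ones it must not exceed lambda.
    """
    Xs = (np.asarray(X, dtype=float) - path.x_mean) / path.x_sd
    yc = np.asarray(y, dtype=float) - path.y_mean
    n = len(yc)
    out = np.empty(len(path.lambda_grid))
    for i, lam in enumerate(path.lambda_grid):
        b = path.coefficients[i]
        g = Xs.T @ (yc - Xs @ b) / n
        active = b != 0
        viol_active = np.abs(np.abs(g[active]) - lam) if active.any() else np.array([0.0])
        viol_inactive = np.maximum(np.abs(g[~active]) - lam, 0.0) if (~active).any() else np.array([0.0])
        out[i] = max(viol_active.max(), viol_inactive.max())
    return out


@dataclass
class Predictor:
    """A sparse predictor at one chosen penalty.

    ``weights`` are on the raw-dosage scale (standardized-scale beta
    divided by the training SD), indexed by ``variant_ids``; scoring is
    PRS_i = sum_j X_ij w_j.
    """

    variant_ids: np.ndarray
    weights: np.ndarray
    chosen_lambda: float
    metric_name: str
    metric_value: float
    trait: str
    holdout_ids: np.ndarray = field(default_factory=lambda: np.array([], dtype=object))

    def __post_init__(self):
        if not np.isfinite(self.weights).all():
            raise ValueError("predictor weights must be finite")

    @property
    def n_active(self) -> int:
        return int(np.count_nonzero(self.weights))


def _metric_per_lambda(scores_by_lambda: np.ndarray, y_val: np.ndarray, metric: str) -> np.ndarray:
    vals = np.empty(scores_by_lambda.shape[1])
    for i in range(scores_by_lambda.shape[1]):
        s = scores_by_lambda[:, i]
        if metric == "auc":
            vals[i] = _auc(s, y_val)
        else:
            vals[i] = 0.0 if np.std(s) == 0 else float(np.corrcoef(s, y_val)[0, 1])
    return vals


def select_lambda(
    path: LassoPath,
    X_val: np.ndarray,
    y_val: np.ndarray,
    metric: str,
    trait: str = "trait",
    holdout_ids=None,
) -> Predictor:
    """Pick the path point maximizing the held-out metric (ties -> larger lambda)."""
    if metric not in ("auc", "correlation"):
        raise ValueError("metric must be 'auc' or 'correlation'")
    y_val = np.asarray(y_val, dtype=float)
    if metric == "auc" and (not (y_val == 1).any() or not (y_val == 0).any()):
        raise ValueError("validation set must contain both cases and controls")
    Xs = (np.asarray(X_val, dtype=float) - path.x_mean) / path.x_sd
    S = Xs @ path.coefficients.T
    vals = _metric_per_lambda(S, y_val, metric)
    best = int(np.argmax(vals))  # first occurrence = largest lambda on ties
    beta = path.coefficients[best]
    w = beta / path.x_sd
    return Predictor(
        variant_ids=path.variant_ids.copy(),
        weights=w,
        chosen_lambda=float(path.lambda_grid[best]),
        metric_name=metric,
        metric_value=float(vals[best]),
        trait=trait,
        holdout_ids=np.asarray(holdout_ids if holdout_ids is not None else [], dtype=object),
    )


@dataclass
class TrainConfig:
    """Knobs of the ensemble training procedure.

    Holdout sizes follow the study design: 500 cases + 500 controls per
    holdout for binary traits (100+100 for low-count traits), 1000
    individuals for quantitative ones, five non-overlapping holdouts.
    ``k`` defaults to 50k SNPs at biobank scale but is configurable for
    desk-scale simulations where p << 50k.
    """

    k: int = 50_000
    n_lambdas: int = 100
    lambda_min_ratio: float = 1e-3
    tol: float = 1e-8
    max_iter: int = 2000
    repeats: int = 5
    holdout_cases: int = 500
    holdout_controls: int = 500
    holdout_quantitative: int = 1000
    seed: int = 0


@dataclass
class PredictorEnsemble:
    """Five predictors for one trait trained on disjoint holdouts."""

    predictors: list
    trait: str
    trait_kind: str

    @property
    def metric_values(self) -> np.ndarray:
        return np.array([p.metric_value for p in self.predictors])

    @property
    def metric_mean(self) -> float:
        return float(self.metric_values.mean())

    @property
    def metric_sd(self) -> float:
        return float(self.metric_values.std(ddof=1)) if len(self.predictors) > 1 else 0.0

    def check_holdouts_disjoint(self) -> bool:
        seen: set = set()
        for p in self.predictors:
            ids = set(p.holdout_ids)
            if ids & seen:
                return False
            seen |= ids
        return True


def train_ensemble(
    G: GenotypeMatrix,
    y: PhenotypeTable,
    pedigree: Pedigree,
    trait_kind: str,
    config: TrainConfig,
) -> PredictorEnsemble:
    """Train the five-predictor ensemble on the non-sibling pool.

    Everyone with at least one full sibling is set aside for testing and
    never enters training or model selection.  Each repeat holds out its
    own disjoint validation set, trains on the remaining pool (association
    scan + top-k preselection recomputed per split), and picks its own
    lambda on its holdout.
    """
    rng = np.random.default_rng(config.seed)
    sib = set(pedigree.sib_ids())
    pool = np.array([i for i in G.sample_ids if i not in sib], dtype=object)
    status = y.values_for(pool)
    metric = "auc" if trait_kind == "binary" else "correlation"

    if trait_kind == "binary":
        cases = pool[status == 1]
        ctrls = pool[status == 0]
        need_cases = config.repeats * config.holdout_cases
        need_ctrls = config.repeats * config.holdout_controls
        if len(cases) < need_cases or len(ctrls) < need_ctrls:
            raise ValueError(
                f"insufficient pool for {config.repeats} holdouts: "
                f"have {len(cases)} cases (need {need_cases}), "
                f"{len(ctrls)} controls (need {need_ctrls})"
            )
        cases = rng.permutation(cases)
        ctrls = rng.permutation(ctrls)
        holdouts = [
            np.concatenate(
                [
                    cases[i * config.holdout_cases : (i + 1) * config.holdout_cases],
                    ctrls[i * config.holdout_controls : (i + 1) * config.holdout_controls],
                ]
            )
            for i in range(config.repeats)
        ]
    else:
        need = config.repeats * config.holdout_quantitative
        if len(pool) < need + 2:
            raise ValueError(
                f"insufficient pool for {config.repeats} quantitative holdouts of "
                f"{config.holdout_quantitative} (pool has {len(pool)})"
            )
        perm = rng.permutation(pool)
        holdouts = [
            perm[i * config.holdout_quantitative : (i + 1) * config.holdout_quantitative]
            for i in range(config.repeats)
        ]

    predictors = []
    for hold in holdouts:
        hold_set = set(hold)
        train_ids = np.array([i for i in pool if i not in hold_set], dtype=object)
        assoc = single_marker_regression(G, y, train_ids)
        sel = rank_select(assoc, config.k)
        # drop variants monomorphic in this training split
        sel = sel[~assoc.loc[sel, "p_value"].isna().to_numpy()]
        X_tr = G.dosages_for(train_ids, sel).astype(float)
        path = fit_lasso_path(
            X_tr,
            y.values_for(train_ids),
            variant_ids=sel,
            n_lambdas=config.n_lambdas,
            lambda_min_ratio=config.lambda_min_ratio,
            tol=config.tol,
            max_iter=config.max_iter,
        )
        X_val = G.dosages_for(hold, sel).astype(float)
        pred = select_lambda(
            path, X_val, y.values_for(hold), metric, trait=y.trait, holdout_ids=hold
        )
        predictors.append(pred)
    ens = PredictorEnsemble(predictors, y.trait, trait_kind)
    assert ens.check_holdouts_disjoint()
    return ens


class ScoreTable:
    """Per-individual, per-predictor polygenic scores.

    Raw scores are PRS_i = sum_j X_ij w_j; z-scoring uses the designated
    reference cohort (population-SD convention) per predictor.
    """

    def __init__(self, sample_ids, scores: np.ndarray, z_scored: bool, ref_mean, ref_sd):
        self.sample_ids = np.asarray(sample_ids, dtype=object)
        self.scores = scores
        self.z_scored = z_scored
        self.ref_mean = np.asarray(ref_mean, dtype=float)
        self.ref_sd = np.asarray(ref_sd, dtype=float)
        self._index = pd.Index(self.sample_ids)

    @property
    def n_predictors(self) -> int:
        return self.scores.shape[1]

    def matrix_for(self, ids) -> np.ndarray:
        idx = self._index.get_indexer(np.asarray(ids, dtype=object))
        if (idx < 0).any():
            raise KeyError("unknown sample ids in score lookup")
        return self.scores[idx, :]

    def ensemble_mean(self) -> pd.Series:
        """Mean of the (z-scored) member scores, the ensemble score."""
        return pd.Series(self.scores.mean(axis=1), index=self._index)

    def subset(self, ids) -> "ScoreTable":
        """Restrict the table to a cohort (z-scoring reference unchanged)."""
        ids = np.asarray(ids, dtype=object)
        return ScoreTable(ids, self.matrix_for(ids), self.z_scored, self.ref_mean, self.ref_sd)

    def column(self, j: int) -> pd.Series:
        return pd.Series(self.scores[:, j], index=self._index)

    def frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.scores,
            index=pd.Index(self.sample_ids, name="individual_id"),
            columns=[f"predictor_{j + 1}" for j in range(self.n_predictors)],
        )
        df["ensemble_mean"] = self.scores.mean(axis=1)
        return df


def compute_scores(G: GenotypeMatrix, ensemble: PredictorEnsemble, reference_ids) -> ScoreTable:
    """Score every individual with every predictor, z-scored on a reference.

    Missing predictor variants in G raise (never silently dropped).  The
    reference cohort (typically the sibling test set) defines the per-
    predictor mean/SD used for z-scoring.
    """
    ref = np.asarray(reference_ids, dtype=object)
    if len(ref) == 0:
        raise ValueError("reference cohort is empty")
    raw = np.empty((G.n_samples, len(ensemble.predictors)))
    for j, pred in enumerate(ensemble.predictors):
        cols = G.variant_indexer(pred.variant_ids)  # raises on missing
        nz = pred.weights != 0
        if nz.any():
            raw[:, j] = G.dosages[:, cols[nz]].astype(float) @ pred.weights[nz]
        else:
            raw[:, j] = 0.0
    ref_rows = G.sample_indexer(ref)
    mu = raw[ref_rows, :].mean(axis=0)
    sd = raw[ref_rows, :].std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    z = (raw - mu) / sd
    return ScoreTable(G.sample_ids, z, True, mu, sd)
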