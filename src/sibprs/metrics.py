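"""Scalar statistics and error machinery for pair-calling analyses.

Fractions of correctly called pairs come with two uncertainty components:
the spread among the five predictors of an ensemble, and the binomial
sampling error from having finitely many pairs.  Table-style parenthetical
errors use the Wald SD sqrt(p(1-p)/n); figure-style errors take the larger
of the ensemble SD and a 68% Clopper–Pearson half-width.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

__all__ = [
    "auc",
    "wald_binomial_sd",
    "clopper_pearson_halfwidth",
    "combine_errors",
    "pearson",
    "expected_sign_agreement",
    "FractionWithError",
    "fraction_with_error",
]


def auc(scores, labels) -> float:
    """Mann–Whitney AUC: P(random case outscores a random control), ties 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    case = scores[labels == 1]
    ctrl = scores[labels == 0]
    n1, n0 = len(case), len(ctrl)
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC requires both cases and controls")
    ranks = stats.rankdata(np.concatenate([case, ctrl]))
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def wald_binomial_sd(k: float, n: int) -> float:
    """Wald SD of a binomial fraction: sqrt(p(1-p)/n) with p = k/n."""
    if n < 1:
        raise ValueError("n must be >= 1")
    p = k / n
    return float(np.sqrt(p * (1.0 - p) / n))


def clopper_pearson_halfwidth(k: float, n: int, confidence: float = 0.68) -> float:
    """Half-width of the central Clopper–Pearson interval.

    Exact binomial interval from beta quantiles; the returned half-width is
    the larger one-sided deviation from k/n.  ``k`` may be fractional
    (tie half-credits); it is rounded to the nearest count for the exact
    interval.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0 <= k <= n):
        raise ValueError("k must lie in [0, n]")
    kk = int(round(k))
    alpha = 1.0 - confidence
    lo = 0.0 if kk == 0 else float(stats.beta.ppf(alpha / 2.0, kk, n - kk + 1))
    hi = 1.0 if kk == n else float(stats.beta.ppf(1.0 - alpha / 2.0, kk + 1, n - kk))
    p = k / n
    return float(max(p - lo, hi - p))


def combine_errors(ensemble_sd: float, sampling_err: float) -> float:
    """The larger of the two uncertainty contributions."""
    if ensemble_sd < 0 or sampling_err < 0:
        raise ValueError("error components must be non-negative")
    return float(max(ensemble_sd, sampling_err))


def pearson(x, y) -> float:
    """Sample Pearson correlation; rejects constant inputs."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("inputs must have equal length >= 2")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("pearson correlation undefined for constant input")
    return float(np.corrcoef(x, y)[0, 1])


def expected_sign_agreement(rho: float) -> float:
    """P(sign agreement) of a bivariate-normal pair: 1/2 + arcsin(rho)/pi."""
    if abs(rho) > 1:
        raise ValueError("|rho| must be <= 1")
    return float(0.5 + np.arcsin(rho) / np.pi)


@dataclass
class FractionWithError:
    """A called fraction with both error components.

    ``k`` counts successes and may carry half-counts from ties.  The
    ``low_stats`` flag marks entries whose combined uncertainty exceeds 10%
    of the central value.
    """

    n: int
    k: float
    fraction: float
    ensemble_sd: float
    sampling_err: float

    @property
    def wald_sd(self) -> float:
        return wald_binomial_sd(self.k, self.n)

    @property
    def combined_err(self) -> float:
        return combine_errors(self.ensemble_sd, self.sampling_err)

    @property
    def low_stats(self) -> bool:
        if self.fraction == 0:
            return True
        return self.combined_err > 0.1 * self.fraction


def fraction_with_error(
    k: float,
    n: int,
    ensemble_sd: float = 0.0,
    confidence: float = 0.68,
) -> FractionWithError:
    """Build a FractionWithError with a Clopper–Pearson sampling error."""
    return FractionWithError(
        n=n,
        k=k,
        fraction=k / n,
        ensemble_sd=ensemble_sd,
        sampling_err=clopper_pearson_halfwidth(k, n, confidence),
    )
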