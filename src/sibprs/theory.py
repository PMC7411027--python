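"""Model-implied reference values used as independent oracles.

These functions predict the pair-calling statistics from the generative
model itself (jointly Gaussian scores and liabilities, expected kinship
0.5), by closed form where available and otherwise by direct Monte Carlo
on the model — never by running the estimation pipeline.
"""
from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = [
    "highrisk_pair_probability",
    "sib_random_call_rates",
    "balding_nichols_variance",
]


def balding_nichols_variance(f: float, fst: float) -> float:
    """Variance of the subpopulation allele frequency: Fst * f * (1 - f)."""
    return fst * f * (1.0 - f)


def highrisk_pair_probability(
    mu_case: float, sd_case: float, mu_ctrl: float, sd_ctrl: float,
    hi_z: float, normal_z: float = 1.0,
) -> float:
    """P(high-risk member is the case) for independent case-control pairs.

    With independent members, conditioning on {one member > hi_z, the other
    < normal_z} gives a ratio of Gaussian tail products — no integration
    needed.
    """
    a = stats.norm.sf(hi_z, mu_case, sd_case) * stats.norm.cdf(normal_z, mu_ctrl, sd_ctrl)
    b = stats.norm.sf(hi_z, mu_ctrl, sd_ctrl) * stats.norm.cdf(normal_z, mu_case, sd_case)
    if a + b == 0:
        raise ValueError("no probability mass in the high/normal region")
    return float(a / (a + b))


def sib_random_call_rates(
    rho_score_gv: float,
    h2: float,
    prevalence: float,
    n_mc: int = 2_000_000,
    seed: int = 0,
    hi_z: float | None = None,
    normal_z: float = 1.0,
):
    """Monte-Carlo call rates predicted by the liability model.

    The model: liability y = g + e with var(g) = h2 and var(y) = 1; the
    score s has unit variance with corr(s, g) = rho_score_gv, hence
    corr(s, y) = rho_score_gv * sqrt(h2).  Between full siblings every
    genotype-linear quantity correlates at the expected kinship 1/2, while
    environments are independent (confound-free case).  Cases are
    liabilities above the (1 - K) quantile.

    Returns ``(sib_rate, random_rate, mc_se)``: the probability that the
    higher-scoring member of a discordant pair is the case, for sibling and
    for independent pairs.  With ``hi_z`` set, pairs are additionally
    restricted to one member's score above ``hi_z`` and the other's below
    ``normal_z``.
    """
    if not (0 < prevalence < 1):
        raise ValueError("prevalence must lie in (0,1)")
    rng = np.random.default_rng(seed)
    r = rho_score_gv * np.sqrt(h2)  # corr(score, liability)
    thr = stats.norm.ppf(1 - prevalence)

    def _rates(cov: np.ndarray) -> tuple[float, int]:
        L = np.linalg.cholesky(cov)
        x = rng.standard_normal((n_mc, 4)) @ L.T  # columns: s1, s2, y1, y2
        s1, s2, y1, y2 = x.T
        c1 = y1 > thr
        c2 = y2 > thr
        disc = c1 ^ c2
        s_case = np.where(c1, s1, s2)[disc]
        s_ctrl = np.where(c1, s2, s1)[disc]
        if hi_z is not None:
            keep = ((s_case > hi_z) & (s_ctrl < normal_z)) | (
                (s_ctrl > hi_z) & (s_case < normal_z)
            )
            s_case, s_ctrl = s_case[keep], s_ctrl[keep]
        n = len(s_case)
        if n == 0:
            raise ValueError("no qualifying pairs in Monte-Carlo oracle")
        k = np.where(s_case > s_ctrl, 1.0, np.where(s_case == s_ctrl, 0.5, 0.0)).sum()
        return float(k / n), n

    # sibling pairs: scores and genetic liability components share at 0.5
    cov_sib = np.array(
        [
            [1.0, 0.5, r, 0.5 * r],
            [0.5, 1.0, 0.5 * r, r],
            [r, 0.5 * r, 1.0, 0.5 * h2],
            [0.5 * r, r, 0.5 * h2, 1.0],
        ]
    )
    cov_rand = np.array(
        [
            [1.0, 0.0, r, 0.0],
            [0.0, 1.0, 0.0, r],
            [r, 0.0, 1.0, 0.0],
            [0.0, r, 0.0, 1.0],
        ]
    )
    sib_rate, n_sib = _rates(cov_sib)
    rand_rate, n_rand = _rates(cov_rand)
    mc_se = float(np.sqrt(0.25 / min(n_sib, n_rand)))
    return sib_rate, rand_rate, mc_se
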