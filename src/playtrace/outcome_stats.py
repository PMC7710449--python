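"""Group-comparison statistics for the trial outcomes.

Treatment vs control comparisons of healthy-food choice and identification
use the Mann-Whitney U test (no normality assumption) with Cohen's d as the
effect size; power and sample-size calculations use the noncentral-t power
function of the two-sample t test; inter-rater agreement for the baseline
food-preference coding uses Cohen's kappa.

The exact Mann-Whitney branch enumerates the permutation null over group
labelings via a dynamic program on (doubled) midranks, so it is tie-safe and
feasible at study scale; the asymptotic branch is the tie-corrected normal
approximation with continuity correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "MannWhitneyResult",
    "GroupComparison",
    "mann_whitney_u",
    "cohens_d_from_summary",
    "cohens_d",
    "achieved_power",
    "required_sample_size",
    "cohens_kappa",
    "compare_groups",
]


class MannWhitneyResult(NamedTuple):
    u: float          # min-convention statistic: min(U1, U2)
    p: float          # two-sided p-value
    mode: str         # "exact" or "normal_approx"
    degenerate: bool  # all pooled values identical


def _exact_mw_p(a: np.ndarray, b: np.ndarray, u_obs_doubled: int) -> float:
    """P(U_min <= observed) under the exact permutation null, tie-safe.

    Works on doubled midranks (integers even with ties) and counts, for every
    size-n1 subset of the pooled sample, the doubled rank sum via a DP over
    items; U1 follows by the rank-sum identity.
    """
    n1, n2 = len(a), len(b)
    n = n1 + n2
    ranks2 = np.rint(2 * stats.rankdata(np.concatenate([a, b]))).astype(int)
    max_sum = int(ranks2.sum())
    # dp[k][s] = number of k-subsets with doubled rank sum s
    dp = np.zeros((n1 + 1, max_sum + 1), dtype=float)
    dp[0, 0] = 1.0
    for r in ranks2:
        for k in range(n1, 0, -1):  # descending so each item is used at most once
            dp[k, r:] += dp[k - 1, : max_sum + 1 - r]
    total = math.comb(n, n1)
    sums = np.nonzero(dp[n1])[0]
    weights = dp[n1, sums]
    u1d = sums - n1 * (n1 + 1)          # doubled U1 for each achievable rank sum
    u2d = 2 * n1 * n2 - u1d
    umind = np.minimum(u1d, u2d)
    favorable = float(weights[umind <= u_obs_doubled].sum())
    return min(1.0, favorable / total)


def mann_whitney_u(a: Sequence[float], b: Sequence[float],
                   mode: str = "auto") -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test; U in the min(U1, U2) convention.

    ``mode="exact"`` enumerates the permutation null (tie-safe; the two-sided
    p is P(U_min <= observed)); ``mode="normal_approx"`` applies the
    tie-corrected normal approximation with continuity correction;
    ``mode="auto"`` uses the exact branch when min(n) <= 10 and n1+n2 <= 25.
    Two identical pooled samples are degenerate and return p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    r1 = float(ranks[:n1].sum())
    u1 = r1 - n1 * (n1 + 1) / 2.0
    u2 = n1 * n2 - u1
    u_min = min(u1, u2)

    if np.ptp(pooled) == 0:
        return MannWhitneyResult(u=u_min, p=1.0, mode=mode, degenerate=True)

    if mode == "auto":
        mode = "exact" if (min(n1, n2) <= 10 and n1 + n2 <= 25) else "normal_approx"
    if mode == "exact":
        p = _exact_mw_p(a, b, int(round(2 * u_min)))
    elif mode == "normal_approx":
        p = float(stats.mannwhitneyu(a, b, alternative="two-sided",
                                     method="asymptotic", use_continuity=True).pvalue)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return MannWhitneyResult(u=u_min, p=min(1.0, p), mode=mode, degenerate=False)


def cohens_d_from_summary(mean_t: float, sd_t: float, n_t: int,
                          mean_c: float, sd_c: float, n_c: int) -> float:
    """Cohen's d from group summaries with Bessel-corrected pooled SD.

    d = (mean_t - mean_c) / s_p, s_p^2 = ((n_t-1) sd_t^2 + (n_c-1) sd_c^2)
    / (n_t + n_c - 2).
    """
    if n_t < 2 or n_c < 2:
        raise ValueError("each group needs at least 2 observations")
    if sd_t < 0 or sd_c < 0:
        raise ValueError("standard deviations must be nonnegative")
    s_pooled = math.sqrt(((n_t - 1) * sd_t ** 2 + (n_c - 1) * sd_c ** 2)
                         / (n_t + n_c - 2))
    diff = mean_t - mean_c
    if s_pooled == 0:
        if diff == 0:
            return 0.0
        raise ZeroDivisionError("pooled SD is zero with unequal means: d is infinite")
    return diff / s_pooled


def cohens_d(a: Sequence[float], b: Sequence[float]) -> float:
    """Cohen's d from raw samples (group a minus group b)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return cohens_d_from_summary(float(a.mean()), float(a.std(ddof=1)), a.size,
                                 float(b.mean()), float(b.std(ddof=1)), b.size)


def _check_power_args(alpha: float, sided: str) -> None:
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if sided not in ("one", "two"):
        raise ValueError("sided must be 'one' or 'two'")


def achieved_power(d: float, n_t: int, n_c: int, alpha: float = 0.05,
                   sided: str = "two") -> float:
    """Power of the two-sample t test at effect size d via the noncentral t.

    The noncentrality parameter is d * sqrt(n_t n_c / (n_t + n_c)) on
    n_t + n_c - 2 degrees of freedom.  At d = 0 the power equals alpha.
    """
    _check_power_args(alpha, sided)
    if n_t < 2 or n_c < 2:
        raise ValueError("each group needs at least 2 observations")
    df = n_t + n_c - 2
    ncp = d * math.sqrt(n_t * n_c / (n_t + n_c))
    if sided == "one":
        crit = stats.t.ppf(1 - alpha, df)
        return float(stats.nct.sf(crit, df, ncp))
    crit = stats.t.ppf(1 - alpha / 2, df)
    return float(stats.nct.sf(crit, df, ncp) + stats.nct.cdf(-crit, df, ncp))


def required_sample_size(d: float, alpha: float = 0.05, power: float = 0.80,
                         sided: str = "one", max_per_group: int = 1_000_000) -> int:
    """Smallest even total n (two equal groups) reaching the target power.

    Walks the per-group size up until the noncentral-t power of the
    two-sample t test meets ``power``; returns the total (2 per-group).
    """
    _check_power_args(alpha, sided)
    if d <= 0:
        raise ValueError("effect size d must be positive")
    if not 0 < power < 1:
        raise ValueError("power must lie in (0, 1)")
    for n in range(2, max_per_group + 1):
        if achieved_power(d, n, n, alpha=alpha, sided=sided) >= power - 1e-12:
            return 2 * n
    raise ValueError("required sample size exceeds the search limit; "
                     "settings may be unattainable")


def cohens_kappa(r1: Sequence, r2: Sequence) -> float:
    """Cohen's kappa for two raters' labels on the same items.

    kappa = (p_o - p_e) / (1 - p_e) with chance agreement p_e from marginal
    products.  When both raters are constant with the same label (p_e = 1 and
    perfect agreement) kappa is defined as 1.
    """
    r1 = list(r1)
    r2 = list(r2)
    if len(r1) != len(r2) or len(r1) == 0:
        raise ValueError("rater label vectors must have equal, nonzero length")
    n = len(r1)
    p_o = sum(x == y for x, y in zip(r1, r2)) / n
    labels = set(r1) | set(r2)
    p_e = sum((r1.count(l) / n) * (r2.count(l) / n) for l in labels)
    if p_e >= 1.0:
        return 1.0  # both raters constant and identical: full (trivial) agreement
    return (p_o - p_e) / (1.0 - p_e)


@dataclass(frozen=True)
class GroupComparison:
    """Treatment-vs-control summary for one outcome (means, U, p, d)."""

    outcome: str
    mean_t: float
    sd_t: float
    n_t: int
    mean_c: float
    sd_c: float
    n_c: int
    u_statistic: float
    p_value: float
    cohens_d: float
    degenerate: bool = False


def compare_groups(outcome: str, treatment: Sequence[float], control: Sequence[float],
                   mode: str = "auto") -> GroupComparison:
    """Full group comparison of one outcome: summaries, Mann-Whitney U, d."""
    t = np.asarray(treatment, dtype=float)
    c = np.asarray(control, dtype=float)
    if t.size < 2 or c.size < 2:
        raise ValueError("each group needs at least 2 observations")
    mw = mann_whitney_u(t, c, mode=mode)
    return GroupComparison(
        outcome=outcome,
        mean_t=float(t.mean()), sd_t=float(t.std(ddof=1)), n_t=int(t.size),
        mean_c=float(c.mean()), sd_c=float(c.std(ddof=1)), n_c=int(c.size),
        u_statistic=mw.u, p_value=mw.p, cohens_d=cohens_d(t, c),
        degenerate=mw.degenerate,
    )
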