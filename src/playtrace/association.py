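"""Association analysis: correlation screening, model selection, regressions.

The screening step correlates each gameplay measure with the pooled
healthy-choice count (GoodChoice) via Kendall's tau-b, which avoids any
linearity assumption on a bounded count outcome.  The outcome distribution is
chosen by AIC between a normal and a Poisson fit, candidate measures are
screened by bidirectional AIC-stepwise selection, and the final models are
linear and log-link Poisson regressions with heteroskedasticity-robust
(sandwich) standard errors: HC1 for the linear models, the classical HC0
sandwich for Poisson.  Both flavors are configurable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import gammaln

__all__ = [
    "DegenerateDataError",
    "TermEstimate",
    "RegressionResult",
    "KendallResult",
    "DistributionFit",
    "kendall_tau",
    "distribution_fit_aic",
    "stepwise_select",
    "fit_linear_robust",
    "fit_poisson_robust",
    "normality_check",
    "screen_measures",
]

INTERCEPT = "Intercept"


class DegenerateDataError(ValueError):
    """The data admit no meaningful fit (constant outcome, all-zero counts, ...)."""


class KendallResult(NamedTuple):
    tau: float
    p: float


class DistributionFit(NamedTuple):
    aic_normal: float
    aic_poisson: float
    chosen: str              # "normal" or "poisson"
    normal_degenerate: bool  # zero-variance y: normal loglik unbounded


@dataclass(frozen=True)
class TermEstimate:
    name: str
    coefficient: float
    robust_se: float
    p_value: float


@dataclass(frozen=True)
class RegressionResult:
    """A fitted outcome regression with robust standard errors."""

    family: str                      # "normal" or "poisson"
    terms: tuple[TermEstimate, ...]
    aic: float
    n: int
    adj_r2: Optional[float] = None   # normal family only
    cov_type: str = "HC1"
    degenerate: bool = False         # e.g. zero residual variance

    def coef(self, name: str) -> float:
        return self._term(name).coefficient

    def se(self, name: str) -> float:
        return self._term(name).robust_se

    def pvalue(self, name: str) -> float:
        return self._term(name).p_value

    def _term(self, name: str) -> TermEstimate:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(f"no term named {name!r}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{"term": t.name, "coefficient": t.coefficient,
                              "robust_se": t.robust_se, "p_value": t.p_value}
                             for t in self.terms])


# --------------------------------------------------------------------------
# Correlation screening
# --------------------------------------------------------------------------


def kendall_tau(x: Sequence[float], y: Sequence[float]) -> KendallResult:
    """Kendall's tau-b with a two-sided p-value.

    Uses exact enumeration of the permutation null for n <= 8 without ties,
    the tie-adjusted large-sample test otherwise.  Constant x or y leaves tau
    undefined and raises :class:`DegenerateDataError`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("x and y must have equal length >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError("tau is undefined for a constant variable")
    no_ties = (np.unique(x).size == x.size) and (np.unique(y).size == y.size)
    method = "exact" if (x.size <= 8 and no_ties) else "asymptotic"
    res = stats.kendalltau(x, y, method=method)
    return KendallResult(tau=float(res.statistic), p=float(res.pvalue))


def screen_measures(data: pd.DataFrame, outcome: str,
                    measures: Sequence[str]) -> pd.DataFrame:
    """Tau-b of each gameplay measure against the outcome (screening table)."""
    rows = []
    for m in measures:
        sub = data[[m, outcome]].dropna()
        tau, p = kendall_tau(sub[m], sub[outcome])
        rows.append({"measure": m, "tau": tau, "p_value": p, "n": len(sub)})
    return pd.DataFrame(rows).set_index("measure")


# --------------------------------------------------------------------------
# Distribution choice
# --------------------------------------------------------------------------


def distribution_fit_aic(y: Sequence[float]) -> DistributionFit:
    """AIC of a normal (k=2) vs Poisson (k=1) fit to the outcome.

    Uses maximum-likelihood parameters (normal sd without Bessel correction;
    Poisson rate = mean) and AIC = 2k - 2 loglik.  The Poisson branch
    requires nonnegative integers.  Zero-variance y makes the normal
    likelihood unbounded; it is flagged and Poisson is chosen.
    """
    y = np.asarray(y, dtype=float)
    if y.size == 0:
        raise ValueError("y must be nonempty")
    if (y < 0).any() or not np.allclose(y, np.rint(y)):
        raise ValueError("the Poisson branch requires nonnegative integer y")
    n = y.size
    lam = float(y.mean())
    if lam == 0:
        ll_pois = 0.0 if (y == 0).all() else -math.inf
    else:
        ll_pois = float(np.sum(y * math.log(lam) - lam - gammaln(y + 1)))
    aic_pois = 2 * 1 - 2 * ll_pois

    sd = float(y.std(ddof=0))
    if sd == 0:
        return DistributionFit(aic_normal=math.nan, aic_poisson=aic_pois,
                               chosen="poisson", normal_degenerate=True)
    ll_norm = float(np.sum(stats.norm.logpdf(y, loc=y.mean(), scale=sd)))
    aic_norm = 2 * 2 - 2 * ll_norm
    chosen = "normal" if aic_norm <= aic_pois else "poisson"
    return DistributionFit(aic_normal=aic_norm, aic_poisson=aic_pois,
                           chosen=chosen, normal_degenerate=False)


# --------------------------------------------------------------------------
# Design-matrix plumbing
# --------------------------------------------------------------------------


def _design(X: Optional[pd.DataFrame], n: Optional[int] = None,
            add_intercept: bool = True) -> pd.DataFrame:
    """Coerce regressors to float and prepend an intercept column if absent.

    ``X=None`` yields an intercept-only design of length ``n``.
    """
    if X is None:
        return pd.DataFrame({INTERCEPT: np.ones(int(n))})
    X = pd.DataFrame(X).astype(float)
    is_const = [c for c in X.columns if X[c].nunique() == 1]
    if add_intercept and not is_const:
        X = X.copy()
        X.insert(0, INTERCEPT, 1.0)
    return X


def _aliased_columns(X: pd.DataFrame) -> list[str]:
    """Columns linearly dependent on the columns before them (QR diagnostic)."""
    arr = X.to_numpy(dtype=float)
    aliased = []
    rank = 0
    for j, col in enumerate(X.columns):
        r = np.linalg.matrix_rank(arr[:, : j + 1])
        if r == rank:
            aliased.append(col)
        rank = r
    return aliased


def _check_full_rank(X: pd.DataFrame) -> None:
    if np.linalg.matrix_rank(X.to_numpy(dtype=float)) < X.shape[1]:
        raise ValueError(f"design matrix is rank deficient; aliased columns: "
                         f"{_aliased_columns(X)}")


def _terms_from_fit(res) -> tuple[TermEstimate, ...]:
    return tuple(TermEstimate(name=str(name), coefficient=float(res.params[name]),
                              robust_se=float(res.bse[name]),
                              p_value=float(res.pvalues[name]))
                 for name in res.params.index)


# --------------------------------------------------------------------------
# Regressions
# --------------------------------------------------------------------------


def fit_linear_robust(y: Sequence[float], X: Optional[pd.DataFrame] = None,
                      cov_type: str = "HC1") -> RegressionResult:
    """OLS with heteroskedasticity-consistent standard errors (default HC1)."""
    y = np.asarray(y, dtype=float)
    X = _design(X, n=len(y))
    if len(y) != len(X):
        raise ValueError("y and X must have the same length")
    if len(y) < X.shape[1] + 1:
        raise ValueError("need n >= number of terms + 1")
    _check_full_rank(X)
    model = sm.OLS(y, X)
    degenerate = False
    ols = model.fit()
    if ols.ssr <= 1e-12 * max(1.0, float(np.sum(y ** 2))):
        # perfect fit: robust SEs are zero; report the classical fit, flagged
        res = ols
        degenerate = True
    else:
        res = model.fit(cov_type=cov_type)
    return RegressionResult(family="normal", terms=_terms_from_fit(res),
                            aic=float(res.aic), n=int(len(y)),
                            adj_r2=float(res.rsquared_adj), cov_type=cov_type,
                            degenerate=degenerate)


def fit_poisson_robust(y: Sequence[float], X: Optional[pd.DataFrame] = None,
                       cov_type: str = "HC0") -> RegressionResult:
    """Log-link Poisson ML with sandwich-robust standard errors (default HC0)."""
    y = np.asarray(y, dtype=float)
    if (y < 0).any() or not np.allclose(y, np.rint(y)):
        raise ValueError("Poisson regression requires nonnegative integer y")
    X = _design(X, n=len(y))
    if len(y) != len(X):
        raise ValueError("y and X must have the same length")
    _check_full_rank(X)
    if (y == 0).all():
        raise DegenerateDataError(
            "all counts are zero: the Poisson ML intercept diverges to -inf")
    model = sm.GLM(y, X, family=sm.families.Poisson())
    res = model.fit(cov_type=cov_type, maxiter=200)
    if not res.converged:
        raise RuntimeError(f"Poisson ML did not converge "
                           f"(iterations: {res.fit_history['iteration']})")
    return RegressionResult(family="poisson", terms=_terms_from_fit(res),
                            aic=float(res.aic), n=int(len(y)),
                            adj_r2=None, cov_type=cov_type)


def normality_check(residuals: Sequence[float]) -> tuple[float, float]:
    """Shapiro-Wilk test of the residuals: returns (W, p)."""
    r = np.asarray(residuals, dtype=float)
    if not 3 <= r.size <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(r) == 0:
        raise DegenerateDataError("residuals are constant")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.shapiro(r)
    return float(res.statistic), float(res.pvalue)


# --------------------------------------------------------------------------
# Stepwise selection
# --------------------------------------------------------------------------


def _ols_aic(y: np.ndarray, X: pd.DataFrame) -> float:
    return float(sm.OLS(y, X).fit().aic)


def stepwise_select(y: Sequence[float], candidates: pd.DataFrame,
                    forced: Sequence[str] = (), family: str = "normal") -> list[str]:
    """Bidirectional AIC-stepwise selection starting from the full model.

    At each step every single-term drop and re-add is scored by AIC and the
    best move is taken; ties are broken toward the smaller model (an
    equal-AIC drop is accepted, an equal-AIC add is not).  ``forced`` columns
    are always kept and never subject to selection.  Collinear candidates are
    dropped up front with a warning.  Deterministic given column order.
    Returns the selected candidate names (forced terms excluded).
    """
    if family != "normal":
        raise ValueError("stepwise selection is defined for the normal family")
    y = np.asarray(y, dtype=float)
    candidates = pd.DataFrame(candidates).astype(float)
    forced = list(forced)
    unknown = [f for f in forced if f not in candidates.columns]
    if unknown:
        raise KeyError(f"forced terms not among the candidates: {unknown}")
    free = [c for c in candidates.columns if c not in forced]
    if len(y) <= len(free) + len(forced) + 2:
        raise ValueError("need n > number of candidates + 2")

    # drop candidates collinear with intercept/forced/earlier candidates
    base_cols = pd.DataFrame({INTERCEPT: np.ones(len(y))})
    kept_free: list[str] = []
    for c in free:
        trial = pd.concat([base_cols, candidates[forced + kept_free + [c]]], axis=1)
        if np.linalg.matrix_rank(trial.to_numpy()) == trial.shape[1]:
            kept_free.append(c)
        else:
            warnings.warn(f"dropping collinear candidate {c!r}", stacklevel=2)
    free = kept_free

    def aic_of(sel: list[str]) -> float:
        X = pd.concat([base_cols, candidates[forced + sel]], axis=1)
        return _ols_aic(y, X)

    selected = list(free)
    current = aic_of(selected)
    while True:
        moves: list[tuple[float, int, list[str]]] = []
        for c in selected:  # drops (preferred on ties: listed first, size smaller)
            trial = [x for x in selected if x != c]
            moves.append((aic_of(trial), len(trial), trial))
        for c in free:      # adds
            if c not in selected:
                trial = selected + [c]
                moves.append((aic_of(trial), len(trial), trial))
        if not moves:
            break
        best_aic, best_size, best_sel = min(moves, key=lambda t: (t[0], t[1]))
        accept = best_aic < current or (best_aic == current and best_size < len(selected))
        if not accept:
            break
        current, selected = best_aic, best_sel
    return selected
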