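"""Correlation screening, distribution choice, stepwise selection, regressions."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from playtrace.association import (
    INTERCEPT,
    DegenerateDataError,
    distribution_fit_aic,
    fit_linear_robust,
    fit_poisson_robust,
    kendall_tau,
    normality_check,
    screen_measures,
    stepwise_select,
)


def brute_force_tau_b(x, y):
    """Oracle: O(n^2) pair counting with the tie-adjusted (tau-b) denominator."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    conc = disc = tx = ty = 0
    for i, j in itertools.combinations(range(n), 2):
        dx, dy = x[i] - x[j], y[i] - y[j]
        if dx == 0 and dy == 0:
            tx += 1
            ty += 1
        elif dx == 0:
            tx += 1
        elif dy == 0:
            ty += 1
        elif dx * dy > 0:
            conc += 1
        else:
            disc += 1
    n0 = n * (n - 1) / 2
    return (conc - disc) / math.sqrt((n0 - tx) * (n0 - ty))


class TestKendallTau:
    def test_perfect_agreement(self):
        assert kendall_tau([1, 2, 3], [1, 2, 3]).tau == pytest.approx(1.0)

    def test_single_swap(self):
        assert kendall_tau([1, 2, 3], [1, 3, 2]).tau == pytest.approx(1 / 3)

    def test_perfect_reversal(self):
        assert kendall_tau([1, 2, 3], [3, 2, 1]).tau == pytest.approx(-1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 5, 20).astype(float)  # ties on both sides
        y = rng.integers(0, 5, 20).astype(float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            return
        assert kendall_tau(x, y).tau == pytest.approx(brute_force_tau_b(x, y))

    def test_symmetric_and_monotone_invariant(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=12), rng.normal(size=12)
        t1 = kendall_tau(x, y)
        assert t1.tau == pytest.approx(kendall_tau(y, x).tau)
        assert kendall_tau(np.exp(x), y ** 3).tau == pytest.approx(t1.tau)

    def test_constant_variable_undefined(self):
        with pytest.raises(DegenerateDataError):
            kendall_tau([1, 1, 1], [1, 2, 3])

    def test_screen_table_shape(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({"m1": rng.normal(size=30), "m2": rng.normal(size=30),
                           "out": rng.integers(0, 5, 30)})
        screen = screen_measures(df, "out", ["m1", "m2"])
        assert list(screen.index) == ["m1", "m2"]
        assert ((screen["tau"] >= -1) & (screen["tau"] <= 1)).all()


class TestDistributionFit:
    def test_poisson_aic_closed_form(self):
        fit = distribution_fit_aic([0, 1, 2])
        # loglik at rate 1: -3 - log 2
        assert fit.aic_poisson == pytest.approx(2 + 2 * (3 + math.log(2)))
        assert round(fit.aic_poisson, 2) == 9.39

    def test_underdispersed_counts_prefer_normal(self):
        rng = np.random.default_rng(0)
        y = np.rint(rng.normal(20, 1.5, 150)).clip(min=0)
        assert distribution_fit_aic(y).chosen == "normal"

    def test_poisson_data_prefer_poisson(self):
        rng = np.random.default_rng(0)
        chosen = [distribution_fit_aic(np.random.default_rng(s).poisson(2.0, 200)).chosen
                  for s in range(40)]
        assert chosen.count("poisson") >= 38  # >= 95% of seeds

    def test_zero_variance_flagged(self):
        fit = distribution_fit_aic([3, 3, 3])
        assert fit.normal_degenerate and fit.chosen == "poisson"

    def test_negative_or_fractional_rejected(self):
        with pytest.raises(ValueError):
            distribution_fit_aic([1.5, 2.0])


class TestLinearRobust:
    def test_exact_line_flagged_degenerate(self):
        x = np.arange(10.0)
        res = fit_linear_robust(2 * x + 1, pd.DataFrame({"x": x}))
        assert res.coef(INTERCEPT) == pytest.approx(1.0)
        assert res.coef("x") == pytest.approx(2.0)
        assert res.degenerate

    def test_coefficient_recovery_coverage(self):
        beta = np.array([2.4, 1.2, -8.4])
        hits = 0
        n_seeds = 200
        for s in range(n_seeds):
            rng = np.random.default_rng(s)
            X = pd.DataFrame({"x1": rng.normal(size=25), "x2": rng.normal(size=25)})
            y = beta[0] + beta[1] * X["x1"] + beta[2] * X["x2"] + rng.normal(0, 1, 25)
            res = fit_linear_robust(y, X)
            ok = all(abs(res.coef(t) - b) <= 3 * res.se(t)
                     for t, b in zip([INTERCEPT, "x1", "x2"], beta))
            hits += ok
        assert hits / n_seeds >= 0.95

    def test_hc1_exceeds_classical_under_heteroskedasticity(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(1, 5, 300)
        y = 1 + 2 * x + rng.normal(0, 1, 300) * x ** 2
        robust = fit_linear_robust(y, pd.DataFrame({"x": x}), cov_type="HC1")
        classical = fit_linear_robust(y, pd.DataFrame({"x": x}), cov_type="nonrobust")
        assert robust.se("x") > classical.se("x")

    def test_rank_deficiency_names_aliased_column(self):
        x = np.arange(12.0)
        X = pd.DataFrame({"x": x, "x_copy": 2 * x})
        with pytest.raises(ValueError, match="x_copy"):
            fit_linear_robust(x, X)

    def test_matches_statsmodels_reference(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(8)
        X = pd.DataFrame({"x": rng.normal(size=40)})
        y = 1 + 0.5 * X["x"] + rng.normal(0, 1, 40)
        res = fit_linear_robust(y, X)
        ref = sm.OLS(y, sm.add_constant(X)).fit(cov_type="HC1")
        assert res.coef("x") == pytest.approx(ref.params["x"])
        assert res.se("x") == pytest.approx(ref.bse["x"])
        assert res.aic == pytest.approx(ref.aic)
        assert res.adj_r2 == pytest.approx(ref.rsquared_adj)


class TestPoissonRobust:
    def test_intercept_only_closed_form(self):
        res = fit_poisson_robust([1, 2, 3])
        assert res.coef(INTERCEPT) == pytest.approx(math.log(2), abs=1e-6)

    def test_all_zero_counts_flagged(self):
        with pytest.raises(DegenerateDataError):
            fit_poisson_robust([0, 0, 0, 0])

    def test_non_integer_rejected(self):
        with pytest.raises(ValueError):
            fit_poisson_robust([1.2, 2.0], pd.DataFrame({"x": [1.0, 2.0]}))

    def test_coefficient_recovery_within_robust_cis(self):
        beta0, beta1 = 0.5, 0.7
        hits = 0
        n_seeds = 100
        for s in range(n_seeds):
            rng = np.random.default_rng(10_000 + s)
            x = rng.normal(size=500)
            y = rng.poisson(np.exp(beta0 + beta1 * x))
            res = fit_poisson_robust(y, pd.DataFrame({"x": x}))
            hits += (abs(res.coef(INTERCEPT) - beta0) <= 3 * res.se(INTERCEPT)
                     and abs(res.coef("x") - beta1) <= 3 * res.se("x"))
        assert hits / n_seeds >= 0.95

    def test_sign_consistency_across_families(self):
        rng = np.random.default_rng(12)
        x1, x2 = rng.normal(size=200), rng.normal(size=200)
        y = rng.poisson(np.exp(0.8 + 0.6 * x1 - 0.6 * x2))
        X = pd.DataFrame({"x1": x1, "x2": x2})
        lin = fit_linear_robust(y, X)
        poi = fit_poisson_robust(y, X)
        for t in ("x1", "x2"):
            assert np.sign(lin.coef(t)) == np.sign(poi.coef(t))


class TestNormalityCheck:
    def test_gaussian_rejection_rate_near_alpha(self):
        rejections = sum(normality_check(np.random.default_rng(s).normal(size=100))[1] < 0.05
                         for s in range(400))
        assert 0.02 <= rejections / 400 <= 0.09

    def test_skewed_residuals_detected(self):
        rejections = sum(normality_check(np.random.default_rng(s).exponential(size=100))[1] < 0.05
                         for s in range(100))
        assert rejections >= 99

    def test_tiny_sample_rejected(self):
        with pytest.raises(ValueError):
            normality_check([0.1, 0.2])


class TestStepwise:
    @staticmethod
    def _exhaustive_best(y, cands):
        import statsmodels.api as sm

        best, best_key = None, None
        for k in range(len(cands.columns) + 1):
            for combo in itertools.combinations(cands.columns, k):
                X = sm.add_constant(cands[list(combo)]) if combo else \
                    pd.DataFrame({INTERCEPT: np.ones(len(y))})
                aic = sm.OLS(y, X).fit().aic
                key = (aic, k)
                if best_key is None or key < best_key:
                    best, best_key = set(combo), key
        return best

    def test_true_effect_retained_and_matches_exhaustive_search(self):
        rng = np.random.default_rng(0)
        n = 200
        cands = pd.DataFrame({"signal": rng.normal(size=n),
                              "noise1": rng.normal(size=n),
                              "noise2": rng.normal(size=n)})
        y = 1.0 + 1.0 * cands["signal"] + rng.normal(0, 0.5, n)
        selected = stepwise_select(y, cands)
        assert "signal" in selected
        assert set(selected) == self._exhaustive_best(y, cands)

    def test_pure_noise_mostly_discarded(self):
        # each noise term survives AIC-stepwise with prob P(chi2_1 > 2) ~ 0.16,
        # so with 3 candidates the typical (median) selected set is empty
        sizes = []
        for s in range(50):
            rng = np.random.default_rng(s)
            n = 200
            cands = pd.DataFrame({f"n{i}": rng.normal(size=n) for i in range(3)})
            y = rng.normal(size=n)
            sizes.append(len(stepwise_select(y, cands)))
        assert np.median(sizes) == 0

    def test_forced_terms_respected(self):
        rng = np.random.default_rng(2)
        n = 100
        cands = pd.DataFrame({"adjust": rng.normal(size=n), "noise": rng.normal(size=n)})
        y = rng.normal(size=n)
        selected = stepwise_select(y, cands, forced=["adjust"])
        assert "adjust" not in selected  # forced terms are kept outside selection

    def test_collinear_candidate_dropped_with_warning(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=60)
        cands = pd.DataFrame({"x": x, "x2": 2 * x, "z": rng.normal(size=60)})
        y = x + rng.normal(0, 0.5, 60)
        with pytest.warns(UserWarning, match="collinear"):
            selected = stepwise_select(y, cands)
        assert "x2" not in selected

    def test_noise_column_raises_aic_in_expectation(self):
        import statsmodels.api as sm

        diffs = []
        for s in range(60):
            rng = np.random.default_rng(s)
            n = 80
            x = rng.normal(size=n)
            y = 1 + x + rng.normal(size=n)
            X0 = sm.add_constant(pd.DataFrame({"x": x}))
            X1 = X0.assign(noise=rng.normal(size=n))
            f0, f1 = sm.OLS(y, X0).fit(), sm.OLS(y, X1).fit()
            assert f1.ssr <= f0.ssr + 1e-9  # in-sample fit never worsens
            diffs.append(f1.aic - f0.aic)
        assert np.mean(diffs) > 0
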