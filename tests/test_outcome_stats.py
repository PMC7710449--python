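"""Group-comparison statistics: Mann-Whitney, Cohen's d, power, kappa."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from playtrace.outcome_stats import (
    achieved_power,
    cohens_d,
    cohens_d_from_summary,
    cohens_kappa,
    compare_groups,
    mann_whitney_u,
    required_sample_size,
)


def brute_force_mw_p(a, b):
    """Oracle: full enumeration of group labelings; P(U_min <= observed)."""
    a, b = list(a), list(b)
    pooled = np.array(a + b, dtype=float)
    n1, n = len(a), len(a) + len(b)
    ranks = stats.rankdata(pooled)

    def u_min(idx):
        r1 = ranks[list(idx)].sum()
        u1 = r1 - n1 * (n1 + 1) / 2
        return min(u1, n1 * (n - n1) - u1)

    observed = u_min(range(n1))
    vals = [u_min(c) for c in itertools.combinations(range(n), n1)]
    return sum(v <= observed + 1e-9 for v in vals) / len(vals)


class TestMannWhitney:
    def test_separated_small_groups(self):
        res = mann_whitney_u([1, 2], [3, 4], mode="exact")
        assert res.u == 0
        assert res.p == pytest.approx(1 / 3)

    def test_identical_samples_degenerate(self):
        res = mann_whitney_u([2, 2, 2], [2, 2, 2])
        assert res.p == 1.0 and res.degenerate

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 4, size=rng.integers(2, 6)).astype(float)  # heavy ties
        b = rng.integers(0, 4, size=rng.integers(2, 6)).astype(float)
        res = mann_whitney_u(a, b, mode="exact")
        if res.degenerate:
            return
        assert res.p == pytest.approx(brute_force_mw_p(a, b))

    def test_exact_close_to_normal_approx(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(0, 1, 8), rng.normal(0.5, 1, 8)
        p_exact = mann_whitney_u(a, b, mode="exact").p
        p_approx = mann_whitney_u(a, b, mode="normal_approx").p
        assert abs(p_exact - p_approx) < 0.02

    def test_auto_mode_switches_on_size(self):
        small = mann_whitney_u([1, 2, 3], [4, 5, 6])
        big = mann_whitney_u(np.arange(30.0), np.arange(30.0) + 0.5)
        assert small.mode == "exact" and big.mode == "normal_approx"

    def test_p_is_one_at_maximal_u(self):
        # the least extreme observable U has every labeling at least as extreme
        res = mann_whitney_u([1, 4], [2, 3], mode="exact")
        assert res.p == 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestCohensD:
    def test_change_in_id_summary_cells(self):
        assert cohens_d_from_summary(-0.26, 0.59, 27, 0.23, 1.12, 31) == pytest.approx(-0.54, abs=0.005)

    def test_change_in_choice_summary_cells(self):
        # the treatment SD is printed with a stray sign; magnitude used
        assert cohens_d_from_summary(-0.11, 0.93, 27, -0.13, 1.02, 31) == pytest.approx(0.02, abs=0.005)

    def test_equal_means_zero(self):
        assert cohens_d_from_summary(1.0, 0.5, 10, 1.0, 0.7, 12) == 0.0

    def test_antisymmetric_under_group_swap(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(1, 1, 15), rng.normal(0, 1, 12)
        assert cohens_d(a, b) == pytest.approx(-cohens_d(b, a))

    def test_zero_pooled_sd_unequal_means(self):
        with pytest.raises(ZeroDivisionError):
            cohens_d_from_summary(1.0, 0.0, 5, 2.0, 0.0, 5)


class TestPower:
    def test_planning_scenario_one_sided(self):
        assert required_sample_size(0.50, alpha=0.05, power=0.80, sided="one") == 102

    def test_planning_scenario_two_sided(self):
        assert required_sample_size(0.50, alpha=0.05, power=0.80, sided="two") == 128

    def test_achieved_power_large_effect(self):
        assert achieved_power(1.25, 27, 31, alpha=0.05, sided="one") > 0.99
        assert achieved_power(1.25, 27, 31, alpha=0.05, sided="two") > 0.99

    def test_null_effect_power_equals_alpha(self):
        assert achieved_power(0.0, 30, 30, alpha=0.05, sided="one") == pytest.approx(0.05, abs=1e-6)
        assert achieved_power(0.0, 30, 30, alpha=0.05, sided="two") == pytest.approx(0.05, abs=1e-6)

    def test_monotonicity(self):
        assert required_sample_size(0.5, power=0.9) > required_sample_size(0.5, power=0.8)
        assert achieved_power(0.5, 40, 40) > achieved_power(0.5, 20, 20)

    @pytest.mark.parametrize("d,sided", [(0.5, "one"), (0.5, "two"), (0.8, "two")])
    def test_consistency_with_achieved_power(self, d, sided):
        n = required_sample_size(d, alpha=0.05, power=0.80, sided=sided)
        assert achieved_power(d, n // 2, n // 2, sided=sided) >= 0.80
        assert achieved_power(d, n // 2 - 1, n // 2 - 1, sided=sided) < 0.80

    def test_agrees_with_statsmodels_solver(self):
        from statsmodels.stats.power import TTestIndPower

        solver = TTestIndPower()
        for d, sided in [(0.5, "one"), (0.5, "two"), (1.0, "two")]:
            alt = "larger" if sided == "one" else "two-sided"
            n_frac = solver.solve_power(effect_size=d, alpha=0.05, power=0.80,
                                        ratio=1.0, alternative=alt)
            assert required_sample_size(d, sided=sided) == 2 * math.ceil(n_frac - 1e-9)

    def test_invalid_settings(self):
        with pytest.raises(ValueError):
            required_sample_size(0.0)
        with pytest.raises(ValueError):
            achieved_power(0.5, 30, 30, alpha=1.5)


class TestKappa:
    def test_perfect_agreement(self):
        assert cohens_kappa(["a", "b", "a"], ["a", "b", "a"]) == 1.0

    def test_chance_level_agreement(self):
        assert cohens_kappa([1, 1, 0, 0], [1, 0, 1, 0]) == pytest.approx(0.0)

    def test_two_by_two_table(self):
        r1 = [1] * 25 + [0] * 25              # yes/yes 20, yes/no 5, no/yes 10, no/no 15
        r2 = [1] * 20 + [0] * 5 + [1] * 10 + [0] * 15
        assert cohens_kappa(r1, r2) == pytest.approx(0.40)

    def test_matches_sklearn(self):
        rng = np.random.default_rng(9)
        r1 = rng.integers(0, 3, 60)
        r2 = np.where(rng.random(60) < 0.7, r1, rng.integers(0, 3, 60))
        from sklearn.metrics import cohen_kappa_score

        assert cohens_kappa(r1.tolist(), r2.tolist()) == pytest.approx(
            cohen_kappa_score(r1, r2))

    def test_constant_identical_raters(self):
        assert cohens_kappa([1, 1, 1], [1, 1, 1]) == 1.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            cohens_kappa([1, 2], [1])


def test_compare_groups_bundles_summaries():
    rng = np.random.default_rng(0)
    t = rng.binomial(4, 0.6, 27).astype(float)
    c = rng.binomial(4, 0.3, 31).astype(float)
    comp = compare_groups("GoodChoice", t, c)
    assert comp.n_t == 27 and comp.n_c == 31
    assert comp.mean_t == pytest.approx(t.mean())
    assert comp.cohens_d == pytest.approx(cohens_d(t, c))
    assert 0 <= comp.p_value <= 1
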