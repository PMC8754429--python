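"""Rate-ratio statistics against independent oracles and hand-derived values."""

from __future__ import annotations

import itertools
import math
import statistics

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coldcomp.curation import Reaction
from coldcomp.stats import (
    bonferroni_threshold,
    bootstrap_median_ci,
    compare_to_control,
    control_fold_changes,
    fit_reaction_slope,
    mann_whitney_u,
    rate_ratio,
)

from conftest import make_reaction


# ---------------------------------------------------------------------------
# Independent oracles


def exact_mwu_p(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney p by full enumeration of rank arrangements.

    Tie-free samples only.  Returns (U_of_x, p).  Independent of scipy: U is
    counted pairwise and the null distribution enumerated over all
    C(n1+n2, n1) equally likely assignments of the pooled ranks.
    """
    n1, n2 = len(x), len(y)
    u_obs = sum(1 for xi in x for yj in y if xi > yj)
    pooled = sorted(x) + sorted(y)
    assert len(set(pooled)) == n1 + n2, "oracle requires tie-free data"
    us = []
    for combo in itertools.combinations(range(n1 + n2), n1):
        in_x = set(combo)
        u = sum(1 for i in in_x for j in range(n1 + n2) if j not in in_x and i > j)
        us.append(u)
    us = np.array(us)
    p_low = np.mean(us <= u_obs)
    p_high = np.mean(us >= u_obs)
    return float(u_obs), float(min(1.0, 2.0 * min(p_low, p_high)))


def closed_form_ols(t, y):
    """Two-parameter OLS by the textbook sums, independent of scipy."""
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    tbar, ybar = t.mean(), y.mean()
    sxx = np.sum((t - tbar) ** 2)
    sxy = np.sum((t - tbar) * (y - ybar))
    syy = np.sum((y - ybar) ** 2)
    slope = sxy / sxx
    intercept = ybar - slope * tbar
    r2 = 1.0 if syy == 0 else sxy**2 / (sxx * syy)
    return slope, intercept, r2


class TestRateRatio:
    def test_identical_rates_give_unit_ratio(self):
        result = rate_ratio(make_reaction([(10.0, 5.0), (40.0, 5.0)]))
        assert result.ratio == 1.0
        assert (result.t_cold_C, result.t_warm_C) == (10.0, 40.0)

    def test_shared_minimum_uses_median(self):
        # Two variants share the coldest T_Growth: their median (5) is k_cold.
        result = rate_ratio(make_reaction([(5.0, 2.0), (5.0, 8.0), (50.0, 4.0)]))
        assert result.k_cold == 5.0
        assert result.k_warm == 4.0
        assert result.ratio == pytest.approx(1.25)

    def test_zero_spread_yields_no_result(self):
        assert rate_ratio(make_reaction([(30.0, 1.0), (30.0, 2.0)])) is None

    @settings(max_examples=60, deadline=None)
    @given(
        variants=st.lists(
            st.tuples(
                st.floats(min_value=-5, max_value=120, allow_nan=False),
                st.floats(min_value=1e-3, max_value=1e3, allow_nan=False),
            ),
            min_size=2,
            max_size=6,
        )
    )
    def test_temperature_reflection_gives_reciprocal(self, variants):
        """Reflecting the temperature axis (T -> -T) swaps cold and warm."""
        if len({t for t, _ in variants}) < 2:
            return
        fwd = rate_ratio(make_reaction(variants))
        rev = rate_ratio(make_reaction([(-t, k) for t, k in variants]))
        assert fwd is not None and rev is not None
        assert rev.ratio == pytest.approx(1.0 / fwd.ratio, rel=1e-12)


class TestControlFoldChanges:
    def test_fold_pair_from_same_t_pair(self):
        (fold,) = control_fold_changes([make_reaction([(30.0, 2.0), (30.0, 8.0)])])
        assert fold.fold_up == 4.0
        assert fold.fold_down == 0.25

    def test_distinct_temperatures_contribute_nothing(self):
        assert control_fold_changes([make_reaction([(10.0, 2.0), (40.0, 8.0)])]) == []

    def test_equal_rates_give_unit_pair(self):
        (fold,) = control_fold_changes([make_reaction([(30.0, 3.0), (30.0, 3.0)])])
        assert (fold.fold_up, fold.fold_down) == (1.0, 1.0)

    def test_largest_group_selected_ties_to_coldest(self):
        reaction = make_reaction(
            [(10.0, 1.0), (10.0, 2.0), (40.0, 1.0), (40.0, 8.0)]
        )
        (fold,) = control_fold_changes([reaction])
        assert fold.t_growth_C == 10.0  # equal sizes -> lowest temperature
        assert fold.fold_up == 2.0

    @settings(max_examples=40, deadline=None)
    @given(
        spreads=st.lists(
            st.floats(min_value=1.0, max_value=1e3, allow_nan=False), min_size=1, max_size=30
        )
    )
    def test_flattened_control_median_is_exactly_one(self, spreads):
        """The flattened {fold_up, fold_down} multiset is closed under
        reciprocals, so its geometric (log-space) median is exactly 1."""
        reactions = [
            make_reaction([(20.0, 1.0), (20.0, s)], key=("1.1.1.1", f"s{i}"))
            for i, s in enumerate(spreads)
        ]
        controls = control_fold_changes(reactions)
        flattened = [f for c in controls for f in (c.fold_up, c.fold_down)]
        assert math.exp(np.median(np.log(flattened))) == pytest.approx(1.0, abs=1e-12)
        summary = bootstrap_median_ci(flattened, reps=300, seed=0, log_scale=True)
        assert summary.median == pytest.approx(1.0, abs=1e-12)


class TestMannWhitney:
    def test_identical_samples_give_central_u(self):
        res = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.u_statistic == pytest.approx(4.5)

    def test_separated_samples_exact_p(self):
        res = mann_whitney_u([1.0, 2.0], [3.0, 4.0])
        assert res.u_statistic == 0.0
        assert res.method == "exact"
        assert res.p_two_sided == pytest.approx(1.0 / 3.0)

    def test_swap_antisymmetry(self):
        x, y = [1.0, 5.0, 2.0], [4.0, 3.0, 6.0, 7.0]
        fwd = mann_whitney_u(x, y)
        rev = mann_whitney_u(y, x)
        assert fwd.p_two_sided == pytest.approx(rev.p_two_sided)
        assert rev.u_statistic == fwd.n1 * fwd.n2 - fwd.u_statistic

    def test_empty_sample_is_error(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    @settings(max_examples=60, deadline=None)
    @given(data=st.data())
    def test_agrees_with_exhaustive_enumeration(self, data):
        n1 = data.draw(st.integers(2, 4))
        n2 = data.draw(st.integers(2, 8 - n1))
        values = data.draw(
            st.lists(
                st.floats(min_value=-100, max_value=100, allow_nan=False),
                min_size=n1 + n2, max_size=n1 + n2, unique=True,
            )
        )
        x, y = values[:n1], values[n1:]
        u_oracle, p_oracle = exact_mwu_p(x, y)
        res = mann_whitney_u(x, y)
        assert res.u_statistic == u_oracle
        assert res.p_two_sided == pytest.approx(p_oracle, rel=1e-12)

    def test_exact_and_asymptotic_agree_in_overlap(self):
        from scipy.stats import mannwhitneyu as scipy_mwu

        rng = np.random.default_rng(42)
        x = rng.normal(0, 1, 20)
        y = rng.normal(0.3, 1, 20)
        exact = mann_whitney_u(x, y)  # n1*n2 = 400 -> exact regime
        assert exact.method == "exact"
        p_asym = scipy_mwu(x, y, alternative="two-sided", method="asymptotic").pvalue
        assert exact.p_two_sided == pytest.approx(p_asym, abs=0.005)


class TestBootstrapMedianCI:
    def test_constant_sample(self):
        res = bootstrap_median_ci([4.0, 4.0, 4.0, 4.0], reps=200, seed=1)
        assert (res.median, res.ci_low, res.ci_high) == (4.0, 4.0, 4.0)

    def test_three_point_sample_matches_full_enumeration(self):
        # All 27 equally likely resamples of {1,2,3}: the resample median is
        # 1 with mass 7/27, 2 with 13/27, 3 with 7/27 (oracle enumerated
        # below), so the 2.5th percentile is 1 and the 97.5th is 3.
        sample = [1.0, 2.0, 3.0]
        medians = [
            statistics.median(resample)
            for resample in itertools.product(sample, repeat=3)
        ]
        counts = {m: medians.count(m) for m in set(medians)}
        assert counts == {1.0: 7, 2.0: 13, 3.0: 7}
        res = bootstrap_median_ci(sample, reps=4000, seed=3)
        assert (res.ci_low, res.ci_high) == (1.0, 3.0)

    def test_deterministic_given_seed(self):
        sample = list(np.random.default_rng(0).normal(size=30))
        a = bootstrap_median_ci(sample, reps=500, seed=11)
        b = bootstrap_median_ci(sample, reps=500, seed=11)
        assert a == b

    def test_requires_two_values(self):
        with pytest.raises(ValueError):
            bootstrap_median_ci([1.0], reps=10, seed=0)

    def test_coverage_of_true_median(self):
        """95% percentile CI covers the true median at a rate in [0.88, 0.99]
        over 200 lognormal samples (true median = 1)."""
        rng = np.random.default_rng(1234)
        covered = 0
        for i in range(200):
            sample = np.exp(rng.normal(0.0, 1.0, size=60))
            res = bootstrap_median_ci(sample, reps=600, seed=int(rng.integers(2**31)))
            covered += res.ci_low <= 1.0 <= res.ci_high
        assert 0.88 <= covered / 200 <= 0.99


class TestFitReactionSlope:
    def test_exact_line(self):
        reaction = make_reaction([(10.0, 10.0**1.0), (20.0, 10.0**0.8), (30.0, 10.0**0.6)])
        fit = fit_reaction_slope(reaction)
        assert fit.m_rate == pytest.approx(-0.02, rel=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_hand_derived_noisy_line(self):
        reaction = make_reaction([(10.0, 10.0**1.0), (20.0, 10.0**0.9), (30.0, 10.0**0.6)])
        fit = fit_reaction_slope(reaction)
        assert fit.m_rate == pytest.approx(-0.02, rel=1e-9)
        assert fit.r_squared == pytest.approx(12.0 / 13.0, rel=1e-9)  # = 0.923...

    def test_two_variants_give_no_fit(self):
        assert fit_reaction_slope(make_reaction([(10.0, 1.0), (20.0, 2.0)])) is None

    def test_zero_temperature_variance_gives_no_fit(self):
        reaction = make_reaction([(30.0, 1.0), (30.0, 2.0), (30.0, 3.0)])
        assert fit_reaction_slope(reaction) is None

    @settings(max_examples=60, deadline=None)
    @given(data=st.data())
    def test_agrees_with_closed_form(self, data):
        n = data.draw(st.integers(3, 8))
        t = [float(v) for v in data.draw(
            st.lists(st.integers(0, 100), min_size=n, max_size=n, unique=True)
        )]
        logk = data.draw(
            st.lists(st.floats(min_value=-3, max_value=3, allow_nan=False),
                     min_size=n, max_size=n)
        )
        reaction = make_reaction([(ti, 10.0**yi) for ti, yi in zip(t, logk)])
        fit = fit_reaction_slope(reaction)
        slope, intercept, r2 = closed_form_ols(t, np.log10([m.k for m in reaction.measurements]))
        assert fit.m_rate == pytest.approx(slope, rel=1e-10, abs=1e-10)
        assert fit.intercept == pytest.approx(intercept, rel=1e-10, abs=1e-10)
        assert fit.r_squared == pytest.approx(r2, rel=1e-8, abs=1e-10)


class TestBonferroni:
    def test_screen_of_951_tests(self):
        assert bonferroni_threshold(0.05, 951) == pytest.approx(5.2576235541535224e-05)

    @pytest.mark.parametrize("alpha,m,expected", [(0.05, 1, 0.05), (0.01, 2, 0.005)])
    def test_simple_cases(self, alpha, m, expected):
        assert bonferroni_threshold(alpha, m) == expected

    def test_zero_tests_is_error(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)


class TestCompareToControl:
    def test_degenerate_all_ones(self):
        reactions = [
            make_reaction([(10.0, 1.0), (40.0, 1.0)], key=("1.1.1.1", f"s{i}"))
            for i in range(4)
        ]
        ctrl_reactions = [
            make_reaction([(20.0, 1.0), (20.0, 1.0)], key=("2.2.2.2", f"c{i}"))
            for i in range(3)
        ]
        ratios = [rate_ratio(r) for r in reactions]
        controls = control_fold_changes(ctrl_reactions)
        report = compare_to_control(ratios, controls, reps=200, seed=0)
        assert report.data_summary.median == 1.0
        assert report.control_summary.median == 1.0
        assert report.utest.u_statistic == pytest.approx(4 * 6 / 2)
        assert report.n_equal_one == 4

    def test_partition_sums_to_ratio_count(self):
        rng = np.random.default_rng(5)
        reactions = [
            make_reaction([(10.0, float(rng.lognormal())), (40.0, float(rng.lognormal()))],
                          key=("1.1.1.1", f"s{i}"))
            for i in range(25)
        ]
        ratios = [rate_ratio(r) for r in reactions]
        controls = control_fold_changes(
            [make_reaction([(20.0, 1.0), (20.0, 2.0)], key=("3.3.3.3", "c"))]
        )
        report = compare_to_control(ratios, controls, reps=200, seed=1)
        assert report.n_above_one + report.n_below_one + report.n_equal_one == len(ratios)

    def test_empty_inputs_are_errors(self):
        with pytest.raises(ValueError):
            compare_to_control([], [], reps=10, seed=0)
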