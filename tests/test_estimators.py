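from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import rangeshift as rs
from rangeshift.estimators import Z95, diff_estimate, domain_mean, percentile_shift


def _m(plots, flags):
    return pd.Series(flags, index=pd.Index(plots["plot_id"], name="plot_id"))


def brute_force_diff(w, y, zs, zt):
    """Exact-rational oracle for the ratio difference, influence values and
    the pooled with-replacement variance."""
    w = [Fraction(x).limit_denominator(10**9) for x in w]
    y = [Fraction(x).limit_denominator(10**9) for x in y]
    ns = sum(wi for wi, z in zip(w, zs) if z)
    nt = sum(wi for wi, z in zip(w, zt) if z)
    rs_ = sum(wi * yi for wi, yi, z in zip(w, y, zs) if z) / ns
    rt_ = sum(wi * yi for wi, yi, z in zip(w, y, zt) if z) / nt
    u = [
        wi * (Fraction(int(zsi)) * (yi - rs_) / ns - Fraction(int(zti)) * (yi - rt_) / nt)
        for wi, yi, zsi, zti in zip(w, y, zs, zt)
    ]
    n = len(w)
    var = Fraction(n, n - 1) * sum(ui * ui for ui in u)
    return float(rs_ - rt_), float(var), [float(ui) for ui in u]


def jackknife_variance(w, y, zs, zt):
    """Delete-one-plot jackknife variance of the ratio difference."""
    n = len(w)
    reps = []
    for i in range(n):
        keep = [j for j in range(n) if j != i]
        d, _, _ = brute_force_diff(
            [w[j] for j in keep], [y[j] for j in keep],
            [zs[j] for j in keep], [zt[j] for j in keep],
        )
        reps.append(d)
    mean = sum(reps) / n
    return (n - 1) / n * sum((r - mean) ** 2 for r in reps)


class TestDomainMean:
    def test_single_member_mean_is_its_value(self, toy_plots):
        plots = toy_plots.assign(weight=24.0)
        m = _m(plots, [True, False, False, False, False, False])
        est = domain_mean(plots, m, "mat_c")
        assert est.mean == 16.0 and est.n_plots == 1

    def test_two_plot_equal_weights_average(self, toy_plots):
        plots = toy_plots.assign(weight=24.0)
        plots.loc[:, "mat_c"] = [4.0, 6.0, 8.0, 9.0, 6.0, 4.0]
        m = _m(plots, [True, True, False, False, False, False])
        assert domain_mean(plots, m, "mat_c").mean == 5.0

    def test_unequal_weights_hand_value(self, toy_plots):
        # (24·4 + 26.6·6) / (24 + 26.6) = 5.051383...
        plots = toy_plots.copy()
        plots.loc[:, "mat_c"] = [4.0, 1.0, 1.0, 6.0, 1.0, 1.0]
        m = _m(plots, [True, False, False, True, False, False])
        est = domain_mean(plots, m, "mat_c")
        np.testing.assert_allclose(est.mean, (24 * 4 + 26.6 * 6) / (24 + 26.6), rtol=1e-14)

    def test_full_domain_equals_overall_weighted_mean(self, toy_plots):
        m = _m(toy_plots, [True] * 6)
        est = domain_mean(toy_plots, m, "mat_c")
        w, y = toy_plots["weight"], toy_plots["mat_c"]
        np.testing.assert_allclose(est.mean, np.average(y, weights=w), rtol=1e-14)

    def test_empty_domain_is_error(self, toy_plots):
        with pytest.raises(rs.InsufficientDataError):
            domain_mean(toy_plots, _m(toy_plots, [False] * 6), "mat_c")


class TestDiffEstimate:
    def test_identical_memberships_give_exact_zero(self, toy_plots):
        m = _m(toy_plots, [True, False, True, True, False, True])
        est = diff_estimate(toy_plots, m, m, "mat_c")
        assert est.diff == 0.0 and est.se == 0.0

    def test_constant_attribute_gives_zero(self, toy_plots):
        plots = toy_plots.assign(mat_c=7.5)
        s = _m(plots, [True, True, False, False, True, False])
        t = _m(plots, [False, True, True, False, False, True])
        est = diff_estimate(plots, s, t, "mat_c")
        assert est.diff == pytest.approx(0.0, abs=1e-15)
        assert est.se == pytest.approx(0.0, abs=1e-15)

    def test_matches_exact_rational_oracle(self, toy_plots):
        zs = [True, True, False, True, False, False]
        zt = [False, True, True, False, True, True]
        est = diff_estimate(toy_plots, _m(toy_plots, zs), _m(toy_plots, zt), "mat_c")
        d, var, u = brute_force_diff(toy_plots["weight"], toy_plots["mat_c"], zs, zt)
        np.testing.assert_allclose(est.diff, d, rtol=1e-12)
        np.testing.assert_allclose(est.se, np.sqrt(var), rtol=1e-12)
        np.testing.assert_allclose(est.influence.to_numpy(), u, rtol=1e-12, atol=1e-18)
        assert est.ci_low == est.diff - Z95 * est.se
        assert est.ci_high == est.diff + Z95 * est.se

    def test_linearized_se_near_jackknife(self, toy_plots):
        zs = [True, True, False, True, False, True]
        zt = [False, True, True, False, True, True]
        est = diff_estimate(toy_plots, _m(toy_plots, zs), _m(toy_plots, zt), "mat_c")
        jk = np.sqrt(jackknife_variance(
            list(toy_plots["weight"]), list(toy_plots["mat_c"]), zs, zt
        ))
        assert abs(est.se - jk) / jk < 0.25

    def test_missing_attribute_plots_are_skipped(self, toy_plots):
        plots = toy_plots.copy()
        plots.loc[5, "tmin_c"] = np.nan
        s = _m(plots, [True, True, False, True, False, True])
        t = _m(plots, [False, True, True, False, True, True])
        est = diff_estimate(plots, s, t, "tmin_c")
        # same answer as dropping the plot outright
        dropped = plots.iloc[:5]
        est2 = diff_estimate(dropped, s.iloc[:5], t.iloc[:5], "tmin_c")
        assert est.diff == est2.diff and est.se == est2.se

    def test_empty_domain_is_error(self, toy_plots):
        s = _m(toy_plots, [True] * 6)
        t = _m(toy_plots, [False] * 6)
        with pytest.raises(rs.InsufficientDataError):
            diff_estimate(toy_plots, s, t, "mat_c")


def _property_plots():
    return pd.DataFrame(
        {
            "plot_id": [f"p{i}" for i in range(1, 7)],
            "stratum": ["CA-OR"] * 3 + ["WA"] * 3,
            "latitude": [33.0, 35.0, 38.0, 45.0, 46.5, 48.0],
            "elevation_m": [100.0, 800.0, 1500.0, 300.0, 900.0, 1200.0],
            "mat_c": [16.0, 12.0, 8.0, 9.0, 6.0, 4.0],
            "tmin_c": 0.0,
            "tmax_c": 0.0,
            "forested": True,
            "weight": [24.0, 24.0, 24.0, 26.6, 26.6, 26.6],
        }
    )


class TestInvarianceProperties:
    @settings(max_examples=25, deadline=None)
    @given(scale=st.floats(0.01, 100.0), shift=st.floats(-50.0, 50.0))
    def test_weight_scale_invariance_and_location_equivariance(self, scale, shift):
        """Estimates are invariant to rescaling all weights and equivariant
        under shifting the attribute."""
        plots = _property_plots()
        zs = [True, True, False, True, False, False]
        zt = [False, True, True, False, True, True]
        s, t = _m(plots, zs), _m(plots, zt)
        base = diff_estimate(plots, s, t, "mat_c")
        scaled = plots.assign(weight=plots["weight"] * scale)
        est = diff_estimate(scaled, s, t, "mat_c")
        np.testing.assert_allclose(est.diff, base.diff, rtol=1e-10)
        np.testing.assert_allclose(est.se, base.se, rtol=1e-10)
        moved = plots.assign(mat_c=plots["mat_c"] + shift)
        est = diff_estimate(moved, s, t, "mat_c")
        np.testing.assert_allclose(est.diff, base.diff, rtol=1e-9, atol=1e-9)
        m_base = domain_mean(plots, s, "mat_c").mean
        m_moved = domain_mean(moved, s, "mat_c").mean
        np.testing.assert_allclose(m_moved, m_base + shift, rtol=1e-12)

    def test_quantile_scale_invariance(self):
        rng = np.random.default_rng(0)
        v, w = rng.normal(size=40), rng.uniform(0.5, 2.0, 40)
        for p in (0.05, 0.5, 0.95):
            assert rs.weighted_quantile(v, w, p) == rs.weighted_quantile(v, 17.3 * w, p)


class TestWeightedQuantile:
    def test_left_continuous_convention_on_1_to_100(self):
        v = np.arange(1, 101, dtype=float)
        assert rs.weighted_quantile(v, np.ones(100), 0.05) == 5.0
        assert rs.weighted_quantile(v, np.ones(100), 0.95) == 95.0

    def test_smallest_value_reaching_cdf(self):
        # weights concentrate 60% of mass on the value 2
        assert rs.weighted_quantile([1, 2, 3], [0.2, 0.6, 0.2], 0.5) == 2.0
        assert rs.weighted_quantile([1, 2, 3], [0.2, 0.6, 0.2], 0.81) == 3.0

    def test_empty_is_error(self):
        with pytest.raises(rs.InsufficientDataError):
            rs.weighted_quantile([], [], 0.5)


class TestPercentileShift:
    @pytest.fixture
    def wide_plots(self):
        rng = np.random.default_rng(3)
        n = 300
        return pd.DataFrame(
            {
                "plot_id": [f"q{i}" for i in range(n)],
                "stratum": np.where(rng.random(n) < 0.7, "CA-OR", "WA"),
                "latitude": rng.uniform(33, 48, n),
                "elevation_m": rng.uniform(0, 2000, n),
                "mat_c": np.round(rng.uniform(0, 18, n), 3),
                "tmin_c": 0.0,
                "tmax_c": 0.0,
                "forested": True,
                "weight": 24.0,
            }
        )

    def test_identical_memberships_diff_zero_ci_contains_zero(self, wide_plots):
        m = _m(wide_plots, np.ones(len(wide_plots), dtype=bool))
        ps = percentile_shift(wide_plots, m, m, "mat_c", 0.05, n_boot=100, seed=1, min_plots=10)
        assert ps.diff == 0.0
        assert ps.ci_low <= 0.0 <= ps.ci_high

    def test_seedling_shift_equivariance(self, wide_plots):
        rng = np.random.default_rng(9)
        zs = rng.random(len(wide_plots)) < 0.5
        zt = rng.random(len(wide_plots)) < 0.5
        s = _m(wide_plots, zs)
        moved = wide_plots.copy()
        moved.loc[zs, "mat_c"] += 1.0  # shift only seedling plots' attribute
        # moving non-seedling plots too would contaminate q_mature; restrict
        # the check to disjoint membership
        disjoint_t = _m(wide_plots, zt & ~zs)
        base = percentile_shift(wide_plots, s, disjoint_t, "mat_c", 0.05, n_boot=10, seed=1, min_plots=10)
        shifted = percentile_shift(moved, s, disjoint_t, "mat_c", 0.05, n_boot=10, seed=1, min_plots=10)
        np.testing.assert_allclose(shifted.q_seedling, base.q_seedling + 1.0, rtol=1e-12)
        np.testing.assert_allclose(shifted.q_mature, base.q_mature, rtol=1e-12)

    def test_min_plots_floor_enforced(self, wide_plots):
        m = _m(wide_plots, np.ones(len(wide_plots), dtype=bool))
        with pytest.raises(rs.InsufficientDataError):
            percentile_shift(wide_plots, m, m, "mat_c", 0.05, n_boot=10, seed=1, min_plots=1000)

    def test_tiny_bootstrap_is_config_error(self, wide_plots):
        m = _m(wide_plots, np.ones(len(wide_plots), dtype=bool))
        with pytest.raises(rs.ConfigurationError):
            percentile_shift(wide_plots, m, m, "mat_c", 0.05, n_boot=1, seed=1, min_plots=10)

    def test_seeded_reproducibility(self, wide_plots):
        rng = np.random.default_rng(9)
        s = _m(wide_plots, rng.random(len(wide_plots)) < 0.6)
        t = _m(wide_plots, rng.random(len(wide_plots)) < 0.6)
        a = percentile_shift(wide_plots, s, t, "mat_c", 0.95, n_boot=50, seed=7, min_plots=10)
        b = percentile_shift(wide_plots, s, t, "mat_c", 0.95, n_boot=50, seed=7, min_plots=10)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)
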