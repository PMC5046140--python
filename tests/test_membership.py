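"""K-t membership evaluation, threshold inversion and fitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pinehab.grids import Raster, RasterHeader
from pinehab.membership import (
    MembershipParams,
    fit_best_family,
    fit_membership,
    fit_memberships_joint,
    kt_membership,
    membership,
    membership_thresholds,
    standardize_raster,
)


class TestKtEvaluation:
    def test_plateau_is_one(self, feb_temperature_params):
        assert kt_membership(6.5, feb_temperature_params) == 1.0

    def test_boundary_d_is_zero(self, feb_temperature_params):
        assert kt_membership(33.6, feb_temperature_params) == 0.0

    def test_falling_limb_midpoint_hand_value(self, feb_temperature_params):
        # ((33.6 - 20.8) / (33.6 - 8)) ** 13 = 0.5 ** 13
        assert kt_membership(20.8, feb_temperature_params) == pytest.approx(
            0.5**13, rel=1e-12
        )

    def test_rising_limb_midpoint_hand_value(self, april_precip_params):
        x = (-63.9 + 98.8) / 2
        assert kt_membership(x, april_precip_params) == pytest.approx(
            0.5**1.62, rel=1e-12
        )

    def test_degenerate_limb_steps_with_warning(self):
        p = MembershipParams(family="kt", a=0, b=0, c=1, d=2, k=2)
        with pytest.warns(UserWarning, match="degenerate"):
            assert kt_membership(0.5, p) == 1.0

    @settings(deadline=None, max_examples=50)
    @given(st.floats(-200, 200))
    def test_bounded_and_unit_on_plateau(self, x):
        p = MembershipParams(family="kt", a=-63.9, b=98.8, c=113.8, d=191.3, k=1.62)
        mu = kt_membership(x, p)
        assert 0.0 <= mu <= 1.0
        if p.b <= x <= p.c:
            assert mu == 1.0

    def test_monotone_on_limbs(self, april_precip_params):
        rising = np.linspace(-63.9, 98.8, 50)
        falling = np.linspace(113.8, 191.3, 50)
        mu_r = kt_membership(rising, april_precip_params)
        mu_f = kt_membership(falling, april_precip_params)
        assert (np.diff(mu_r) >= 0).all()
        assert (np.diff(mu_f) <= 0).all()


class TestThresholds:
    def test_cutoff_one_gives_plateau(self, feb_temperature_params):
        assert membership_thresholds(feb_temperature_params, 1.0) == (5.0, 8.0)

    def test_inverts_falling_limb_worked_example(self, feb_temperature_params):
        lo, hi = membership_thresholds(feb_temperature_params, 0.5**13)
        assert hi == pytest.approx(20.8, rel=1e-12)

    def test_cutoff_to_zero_approaches_support(self, feb_temperature_params):
        p = feb_temperature_params
        prev_lo, prev_hi = membership_thresholds(p, 1.0)
        for cutoff in (1e-3, 1e-6, 1e-9, 1e-12):
            lo, hi = membership_thresholds(p, cutoff)
            assert p.a < lo <= prev_lo and prev_hi <= hi < p.d
            # closed-form limb inversion
            root = cutoff ** (1 / p.k)
            assert lo == pytest.approx(p.a + (p.b - p.a) * root, rel=1e-12)
            prev_lo, prev_hi = lo, hi

    @settings(deadline=None, max_examples=50)
    @given(st.floats(0.01, 0.99))
    def test_mutually_inverse_with_membership(self, cutoff):
        p = MembershipParams(family="kt", a=-42.4, b=5, c=8, d=33.6, k=13)
        lo, hi = membership_thresholds(p, cutoff)
        assert kt_membership(lo, p) == pytest.approx(cutoff, rel=1e-9)
        assert kt_membership(hi, p) == pytest.approx(cutoff, rel=1e-9)


class TestStandardizeRaster:
    def test_plateau_constant_gives_one(self, feb_temperature_params):
        h = RasterHeader(n_cols=4, n_rows=4, x_origin=0, y_origin=0, cell_size=1)
        out = standardize_raster(Raster(h, np.full((4, 4), 6.0)), feb_temperature_params)
        np.testing.assert_array_equal(out.values, 1.0)

    def test_beyond_d_gives_zero(self, feb_temperature_params):
        h = RasterHeader(n_cols=4, n_rows=4, x_origin=0, y_origin=0, cell_size=1)
        out = standardize_raster(Raster(h, np.full((4, 4), 40.0)), feb_temperature_params)
        np.testing.assert_array_equal(out.values, 0.0)

    def test_matches_pointwise_evaluation(self, feb_temperature_params):
        h = RasterHeader(n_cols=10, n_rows=5, x_origin=0, y_origin=0, cell_size=1)
        rng = np.random.default_rng(3)
        vals = rng.uniform(-50, 40, (5, 10))
        vals[0, 0] = np.nan
        out = standardize_raster(Raster(h, vals), feb_temperature_params)
        idx = rng.integers(0, 5, 50), rng.integers(0, 10, 50)
        for i, j in zip(*idx):
            v = vals[i, j]
            if np.isnan(v):
                assert np.isnan(out.values[i, j])
            else:
                assert out.values[i, j] == kt_membership(float(v), feb_temperature_params)


class TestFitting:
    def test_noiseless_recovery_of_plateau(self):
        true = MembershipParams(family="kt", a=-10, b=20, c=40, d=80, k=2.0)
        rng = np.random.default_rng(0)
        x = rng.uniform(-20, 100, 400)
        y = kt_membership(x, true)
        fit = fit_membership(x, y, family="kt", n_bins=None)
        span = x.max() - x.min()
        assert abs(fit.params.b - true.b) < 0.01 * span
        assert abs(fit.params.c - true.c) < 0.01 * span

    def test_constant_indicator_plateau_covers_range(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 10, 50)
        fit = fit_membership(x, np.ones_like(x), family="kt")
        assert fit.params.b <= x.min() and fit.params.c >= x.max()
        assert fit.goodness == pytest.approx(0.0, abs=1e-12)

    def test_noisy_recovery_over_seeds(self):
        true = MembershipParams(family="kt", a=-10, b=20, c=40, d=80, k=2.0)
        errs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x = rng.uniform(-20, 100, 200)
            y = np.clip(kt_membership(x, true) + rng.normal(0, 0.05, 200), 0, None)
            fit = fit_membership(x, y, family="kt")
            span = x.max() - x.min()
            errs.append(max(abs(fit.params.b - true.b), abs(fit.params.c - true.c)) / span)
        assert np.mean(errs) < 0.05

    def test_too_few_points_error(self):
        with pytest.raises(ValueError):
            fit_membership([1, 2, 3], [0.1, 0.5, 1.0])

    def test_constant_factor_error(self):
        with pytest.raises(ValueError):
            fit_membership(np.ones(20), np.linspace(0, 1, 20))

    def test_true_params_no_better_than_fit_on_noiseless_data(self):
        """Optimality sanity: the returned fit's RSS <= the truth's RSS."""
        true = MembershipParams(family="kt", a=0, b=3, c=5, d=9, k=1.5)
        rng = np.random.default_rng(5)
        x = rng.uniform(-1, 10, 300)
        y = kt_membership(x, true)
        fit = fit_membership(x, y, family="kt", n_bins=None)
        rss_true = float(((kt_membership(x, true) - y) ** 2).sum())
        assert fit.goodness <= rss_true + 1e-9

    def test_best_family_picks_generator(self):
        """Data generated from a sigmoid is not attributed to K-t."""
        gen = MembershipParams(family="sigmoid-rise", alpha=5.0, beta=1.0)
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 10, 300)
        y = membership(x, gen)
        best = fit_best_family(x, y, n_bins=None)
        assert best.params.family == "sigmoid-rise"


class TestJointCalibration:
    def test_recovers_weights_and_plateaus_two_factors(self):
        p1 = MembershipParams(family="kt", a=-5, b=2, c=4, d=10, k=2)
        p2 = MembershipParams(family="kt", a=10, b=30, c=50, d=90, k=3)
        rng = np.random.default_rng(0)
        x1 = rng.uniform(-6, 12, 300)
        x2 = rng.uniform(5, 95, 300)
        y = 0.7 * kt_membership(x1, p1) + 0.3 * kt_membership(x2, p2)
        y += rng.normal(0, 0.02, 300)
        params, weights, rss = fit_memberships_joint(
            np.column_stack([x1, x2]), y, ("f1", "f2")
        )
        assert weights["f1"] == pytest.approx(0.7, abs=0.05)
        assert weights["f2"] == pytest.approx(0.3, abs=0.05)
        assert abs(params["f1"].b - 2) < 0.05 * 18
        assert abs(params["f2"].c - 50) < 0.05 * 90
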