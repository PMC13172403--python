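import numpy as np
import pandas as pd
import pytest

from tidalcarbon.core_io import CoreValidationError
from tidalcarbon.pb_dating import (
    PB210_LAMBDA,
    FalloutEstimate,
    accretion_summary,
    crs_classical,
    expected_unsupported,
    krige_fallout,
    phi_prior,
    screen_profile,
    unsupported_pb210,
)

from conftest import make_core


class TestUnsupported:
    def test_variable_radon_quadrature(self):
        core = make_core(n=4, pb210_total=[50.0] * 4, pb210_total_sd=[3.0] * 4,
                         ra226=[10.0] * 4, ra226_sd=[2.0] * 4)
        unsup, sd = unsupported_pb210(core, "variable_radon")
        assert unsup[0] == pytest.approx(40.0)
        assert sd[0] == pytest.approx(np.sqrt(9 + 4), abs=1e-4)

    def test_tail_background_mean_of_deepest_two(self):
        tot = [60.0, 40.0, 25.0, 18.0, 12.0, 8.0]
        core = make_core(n=6, pb210_total=tot, pb210_total_sd=[1.0] * 6)
        unsup, _ = unsupported_pb210(core, "tail_background")
        np.testing.assert_allclose(unsup, np.array(tot) - 10.0)

    def test_equilibrium_profile_near_zero(self):
        core = make_core(n=4, pb210_total=[10.0] * 4, pb210_total_sd=[1.0] * 4,
                         ra226=[10.0] * 4, ra226_sd=[1.0] * 4)
        unsup, _ = unsupported_pb210(core)
        np.testing.assert_allclose(unsup, 0.0, atol=1e-12)

    def test_no_radon_directs_to_fallback(self):
        core = make_core(n=4, pb210_total=[50.0, 30, 20, 10], pb210_total_sd=[1.0] * 4)
        with pytest.raises(CoreValidationError, match="tail_background"):
            unsupported_pb210(core, "variable_radon")


class TestScreenProfile:
    def test_clean_exponential_profile_unflagged(self, sim_core):
        core, _, _ = sim_core
        unsup, sd = unsupported_pb210(core)
        res = screen_profile(core, unsup, sd)
        assert not res.flag_low_activity and not res.flag_step_shape
        assert res.usable

    def test_step_profile_flagged(self):
        rng = np.random.default_rng(2)
        vals = np.array([40.0] * 5 + [5.0] * 5) * np.exp(rng.normal(0, 0.03, 10))
        core = make_core(n=10)
        res = screen_profile(core, vals, np.full(10, 1.0))
        assert res.flag_step_shape
        assert not res.usable

    def test_low_activity_flagged(self):
        core = make_core(n=8)
        unsup = np.full(8, 1.0)
        sd = np.full(8, 0.8)  # max activity < 3 x median sd
        res = screen_profile(core, unsup, sd)
        assert res.flag_low_activity

    def test_manual_override_precedes_flags(self):
        core = make_core(n=8)
        res = screen_profile(core, np.full(8, 1.0), np.full(8, 0.8), manual_override="include")
        assert res.flag_low_activity and res.usable


class TestKriging:
    points = [(34.0, -120.0, 4.8), (36.0, -121.0, 5.0), (38.0, -122.0, 5.1),
              (40.0, -123.0, 5.2), (42.0, -124.0, 5.3), (35.0, -118.0, 4.9)]

    def test_exact_interpolation_at_data_point(self):
        est = krige_fallout(self.points, (36.0, -121.0))
        assert est.mean_log == pytest.approx(5.0, abs=1e-6)
        assert est.se_log == pytest.approx(0.0, abs=1e-4)

    def test_constant_field_predicts_constant(self):
        pts = [(lat, lon, 5.0) for lat, lon, _ in self.points]
        est = krige_fallout(pts, (37.0, -121.5))
        assert est.mean_log == pytest.approx(5.0, abs=1e-9)

    def test_prediction_within_data_range(self):
        est = krige_fallout(self.points, (37.0, -121.5))
        assert 4.8 <= est.mean_log <= 5.3
        assert est.se_log >= 0

    def test_target_outside_bbox_rejected(self):
        with pytest.raises(ValueError, match="bounding box"):
            krige_fallout(self.points, (10.0, -121.0))

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            krige_fallout(self.points[:3], (36.0, -121.0))


class TestPhiPrior:
    def test_degenerate_lognormal(self):
        m, shape = phi_prior(FalloutEstimate(np.log(100.0), 0.0))
        assert m == pytest.approx(100.0)
        assert shape > 1e5

    def test_lognormal_moments(self):
        est = FalloutEstimate(4.6, 0.3)
        m, shape = phi_prior(est)
        m_expected = np.exp(4.6 + 0.045)
        v_expected = m_expected**2 * (np.exp(0.09) - 1)
        assert m == pytest.approx(m_expected)
        assert shape == pytest.approx(m_expected**2 / v_expected)

    def test_shape_conventions_differ_by_mean_factor(self):
        est = FalloutEstimate(4.6, 0.3)
        m, s_a = phi_prior(est, "mean2_over_var")
        _, s_b = phi_prior(est, "mean_over_var")
        assert s_a == pytest.approx(s_b * m)


class TestExpectedUnsupported:
    def test_total_inventory_limit(self):
        # t_top=0, t_bottom -> inf gives the whole inventory phi/lambda
        a = expected_unsupported(150.0, 0.0, 1e9, mass=1.0)
        assert a == pytest.approx(150.0 / PB210_LAMBDA, rel=1e-9)

    def test_one_half_life_halves(self):
        mass = 2.0
        phi = PB210_LAMBDA * mass
        assert expected_unsupported(phi, 0.0, 22.3, mass) == pytest.approx(0.5)

    def test_zero_supply(self):
        assert expected_unsupported(0.0, 0.0, 10.0, 1.0) == 0.0

    def test_conservation_over_complete_profile(self):
        # summed slice inventories equal phi/lambda to < 0.1%
        phi, mass = 150.0, 3.5
        edges = np.linspace(0, 60, 61)
        ages = edges * 2.86
        acts = expected_unsupported(phi, ages[:-1], ages[1:], mass)
        inventory = np.sum(acts * mass) + (phi / PB210_LAMBDA) * np.exp(-PB210_LAMBDA * ages[-1])
        assert inventory == pytest.approx(phi / PB210_LAMBDA, rel=1e-3)

    def test_inverted_ages_rejected(self):
        with pytest.raises(ValueError):
            expected_unsupported(100.0, 5.0, 5.0, 1.0)


class TestCrsClassical:
    def test_half_inventory_depth_is_one_half_life(self):
        # constant-age-slice synthetic profile: build activities so that the
        # cumulative inventory halves exactly at a known depth
        n = 30
        mass = np.full(n, 5.0)
        ages = np.arange(n + 1) * 2.0
        acts = expected_unsupported(100.0, ages[:-1], ages[1:], mass)
        core = make_core(n=n, dbd=[0.5] * n, pb210_total=acts, pb210_total_sd=0.01 * acts + 0.001)
        df = crs_classical(core, acts, 0.01 * acts + 1e-4, n_mc=50, seed=0)
        # truth: age at increment bottom i is 2(i+1) yr
        idx = np.searchsorted(df["age"].to_numpy(), 22.3)
        assert df["age"].iloc[idx] == pytest.approx(2.0 * (idx + 1), rel=0.02)

    def test_recovers_truth_on_simulated_core(self, sim_core):
        core, truth, ages = sim_core
        unsup, sd = unsupported_pb210(core)
        df = crs_classical(core, unsup, sd, seed=3)
        for _, row in df.iloc[3:18:4].iterrows():
            t_true = ages[int(row["depth"])]
            assert abs(row["age"] - t_true) < max(2 * row["age_sd"], 2.0)

    def test_exhausted_inventory_gives_inf(self):
        n = 8
        acts = np.array([40.0, 20.0, 10.0, 5.0, 0.0, 0.0, 0.0, 0.0])
        core = make_core(n=n, dbd=[0.5] * n, pb210_total=acts + 10, pb210_total_sd=[1.0] * n)
        df = crs_classical(core, acts, np.full(n, 1.0), n_mc=10, seed=0, extrapolate_tail=False)
        assert np.isfinite(df["age"].iloc[0])
        assert np.isinf(df["age"].iloc[-1])


class TestAccretionSummary:
    @staticmethod
    def uniform_ensemble(slowness, n_draws=3, depth=100):
        from tidalcarbon.pb_dating import AgeDepthEnsemble

        bounds = np.arange(depth + 1, dtype=float)
        draws = np.tile(bounds * slowness, (n_draws, 1))
        return AgeDepthEnsemble("E", bounds, draws, np.ones(n_draws), np.ones(n_draws),
                                np.ones((n_draws, 1)), 0, n_draws, 0.3, 0)

    def test_uniform_draws(self):
        mean, sd, cv = accretion_summary(self.uniform_ensemble(2.86))
        assert mean == pytest.approx(10 / 2.86, abs=1e-6)
        assert sd == 0.0 and cv == 0.0

    def test_two_draw_cv(self):
        from tidalcarbon.pb_dating import AgeDepthEnsemble

        bounds = np.arange(101, dtype=float)
        draws = np.vstack([bounds / 0.3, bounds / 0.4])  # 3 and 4 mm/yr
        ens = AgeDepthEnsemble("E", bounds, draws, np.ones(2), np.ones(2),
                               np.ones((2, 1)), 0, 2, 0.3, 0)
        mean, sd, cv = accretion_summary(ens)
        assert mean == pytest.approx(3.5)
        assert sd == pytest.approx(np.sqrt(0.5) / np.sqrt(2) * np.sqrt(2), abs=1e-6)  # 0.7071
        assert cv == pytest.approx(100 * 0.70710678 / 3.5, abs=1e-3)

    def test_zero_horizon_rejected(self):
        with pytest.raises(ValueError):
            accretion_summary(self.uniform_ensemble(2.86), horizon=0)

    def test_shallow_draw_uses_deepest_age(self):
        # deepest age 60 yr < horizon: rate falls back to depth/age at bottom
        ens = self.uniform_ensemble(0.6, depth=100)  # deepest age 60 yr
        mean, _, _ = accretion_summary(ens, horizon=100)
        assert mean == pytest.approx(100.0 / 60.0 * 10.0)
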