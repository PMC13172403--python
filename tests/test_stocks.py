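import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tidalcarbon.core_io import CoreValidationError, SoilCore
from tidalcarbon.stocks import (
    carbon_density,
    loi_to_oc,
    om_depth_trend,
    stock_to_1m,
    summarize_stocks,
)

from conftest import make_core
import pandas as pd


class TestLoiToOc:
    @pytest.mark.parametrize(
        "loi,oc", [(0.0, 0.0), (10.0, 4.25), (100.0, 65.0)]
    )
    def test_quadratic_conversion(self, loi, oc):
        assert loi_to_oc(loi) == pytest.approx(oc)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            loi_to_oc(120.0)
        with pytest.raises(ValueError):
            loi_to_oc(-1.0)

    @given(st.floats(0.1, 100))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_oc_bounded_and_superlinear(self, loi):
        oc = loi_to_oc(loi)
        assert oc <= 0.65 * loi + 1e-12
        # OC/LOI increases with LOI (positive curvature)
        if loi < 99:
            assert loi_to_oc(loi + 1) / (loi + 1) > oc / loi


class TestCarbonDensity:
    def test_products(self):
        assert carbon_density(1.0, 0.0) == 0.0
        assert carbon_density(0.5, 10.0) == pytest.approx(0.05)

    def test_chained_with_craft(self):
        assert carbon_density(0.8, loi_to_oc(20.0)) == pytest.approx(0.8 * 0.09)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            carbon_density(-0.1, 5.0)


def uniform_density_core(n=100, rho=0.03, core_id="U"):
    """Core with LOI/DBD chosen so carbon density is exactly rho everywhere."""
    # pick LOI = 10% -> OC = 4.25% ; dbd = rho*100/4.25
    loi = np.full(n, 0.10)
    dbd = np.full(n, rho * 100.0 / 4.25)
    return make_core(core_id=core_id, n=n, loi=loi, dbd=dbd)


class TestStockTo1m:
    def test_uniform_density_full_meter(self):
        res = stock_to_1m(uniform_density_core(100, 0.03))
        assert res.stock_1m == pytest.approx(30.0)
        assert not res.extrapolated

    def test_short_core_scaled_by_mean_density(self):
        res = stock_to_1m(uniform_density_core(90, 0.03))
        assert res.stock_1m == pytest.approx(30.0)
        assert res.extrapolated
        assert res.profile_depth == pytest.approx(90.0)

    def test_two_layer_weighted_mean(self):
        # 95 cm profile: rho 0.02 above 50 cm, 0.04 below
        loi = np.full(95, 0.10)
        dbd = np.where(np.arange(95) < 50, 0.02, 0.04) * 100.0 / 4.25
        core = make_core(n=95, loi=loi, dbd=dbd)
        res = stock_to_1m(core)
        expected = 100.0 * (50 * 0.02 + 45 * 0.04) / 95.0 * 10.0
        assert res.stock_1m == pytest.approx(expected)
        assert res.stock_1m == pytest.approx(29.47, abs=0.01)

    def test_straddling_increment_clipped_at_1m(self):
        data = pd.DataFrame({"depth_min": [0.0, 95.0], "depth_max": [95.0, 110.0],
                             "loi": [0.10, 0.10], "dry_bulk_density": [0.03 * 100 / 4.25] * 2})
        res = stock_to_1m(SoilCore("S", data))
        assert res.stock_1m == pytest.approx(30.0)
        assert res.profile_depth == 100.0

    def test_shallow_core_ineligible(self):
        with pytest.raises(CoreValidationError, match="90"):
            stock_to_1m(uniform_density_core(50, 0.03))

    def test_split_increment_invariance(self):
        # splitting each 2 cm increment into two 1 cm halves leaves the stock
        # unchanged to machine precision
        rng = np.random.default_rng(1)
        loi2 = rng.uniform(0.05, 0.3, 50)
        dbd2 = rng.uniform(0.3, 1.1, 50)
        coarse = SoilCore("C", pd.DataFrame({
            "depth_min": np.arange(0, 100, 2, dtype=float),
            "depth_max": np.arange(2, 102, 2, dtype=float),
            "loi": loi2, "dry_bulk_density": dbd2}))
        fine = SoilCore("F", pd.DataFrame({
            "depth_min": np.arange(100, dtype=float),
            "depth_max": np.arange(1, 101, dtype=float),
            "loi": np.repeat(loi2, 2), "dry_bulk_density": np.repeat(dbd2, 2)}))
        assert stock_to_1m(fine).stock_1m == pytest.approx(stock_to_1m(coarse).stock_1m, rel=1e-12)


class TestOmDepthTrend:
    def test_noise_free_line_recovered_exactly(self):
        mids = np.arange(100) + 0.5
        core = make_core(n=100, loi=(20.0 - 0.1 * mids) / 100.0)
        res = om_depth_trend(core)
        assert res.slope == pytest.approx(-0.1, abs=1e-10)
        assert res.classification == "decrease"
        assert res.p_value < 1e-10

    def test_constant_profile_classified_none(self):
        core = make_core(n=50, loi=[0.2] * 50)
        res = om_depth_trend(core)
        assert res.slope == pytest.approx(0.0, abs=1e-12)
        assert res.classification == "none"

    def test_noisy_slope_recovery_within_oracle_bound(self):
        rng = np.random.default_rng(42)
        mids = np.arange(100) + 0.5
        loi_pct = 20.0 - 0.13 * mids + rng.normal(0, 2, 100)
        core = make_core(n=100, loi=np.clip(loi_pct, 0.1, 99) / 100.0)
        res = om_depth_trend(core)
        # OLS slope se for sigma=2 over depths 0.5..99.5 is
        # 2/sqrt(sum((x-xbar)^2)) = 2/sqrt(83325) = 0.0069; +-0.04 is ~6 se
        assert res.slope == pytest.approx(-0.13, abs=0.04)
        assert res.classification == "decrease"

    def test_too_few_points(self):
        core = make_core(n=2, loi=[0.2, 0.1])
        with pytest.raises(CoreValidationError):
            om_depth_trend(core)


class TestSummarizeStocks:
    def test_dataset_mean_is_over_cores_not_sites(self):
        results = [stock_to_1m(uniform_density_core(100, r, core_id=f"c{i}"))
                   for i, r in enumerate([0.02, 0.02, 0.02, 0.04, 0.06])]
        sites = {"c0": "s1", "c1": "s1", "c2": "s1", "c3": "s2", "c4": "s3"}
        ds = summarize_stocks(results, group_by="dataset")
        # unweighted over 5 cores: mean rho = 0.032 -> 32 kg m-2
        assert ds["mean"].iloc[0] == pytest.approx(32.0)
        site = summarize_stocks(results, group_by="site", site_ids=sites)
        site_means = site.set_index("group")["mean"]
        assert np.mean(site_means) == pytest.approx((20 + 40 + 60) / 3)
        assert ds["mean"].iloc[0] != pytest.approx(np.mean(site_means))

    def test_single_core_identity(self):
        res = [stock_to_1m(uniform_density_core(100, 0.03))]
        ds = summarize_stocks(res)
        assert ds["mean"].iloc[0] == pytest.approx(30.0)
        assert ds["n"].iloc[0] == 1

    def test_order_invariance(self):
        results = [stock_to_1m(uniform_density_core(100, r, core_id=f"c{i}"))
                   for i, r in enumerate([0.01, 0.05, 0.03])]
        a = summarize_stocks(results)["mean"].iloc[0]
        b = summarize_stocks(results[::-1])["mean"].iloc[0]
        assert a == pytest.approx(b)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            summarize_stocks([])
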