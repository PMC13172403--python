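import numpy as np
import pandas as pd
import pytest

from tidalcarbon import core_io
from tidalcarbon.core_io import (
    CoreValidationError,
    ParseError,
    SchemaError,
    filter_loi_outliers,
    interpolate_gaps,
    join_core_metadata,
    read_depthseries,
    validate_core,
    write_depthseries,
)

from conftest import make_core


def write_csv(path, text):
    path.write_text(text)
    return path


class TestReadDepthseries:
    def test_basic_parse(self, tmp_path):
        p = write_csv(tmp_path / "d.csv",
                      "core_id,depth_min,depth_max,fraction_organic_matter\n"
                      "A,0,1,0.20\nA,1,2,0.18\n")
        cores = read_depthseries(p)
        assert len(cores) == 1 and len(cores[0]) == 2
        assert cores[0].data["loi"].tolist() == [0.20, 0.18]

    def test_dpm_per_g_dialect_converts_activities(self, tmp_path):
        p = write_csv(tmp_path / "d.csv",
                      "core_id,depth_min,depth_max,cs137_activity,cs137_activity_se\n"
                      "A,0,1,10,1\nA,1,2,1,0.1\n")
        (core,) = read_depthseries(p, unit_dialect="dpm/g")
        assert core.data["cs137"].iloc[0] == pytest.approx(166.6667, abs=1e-3)
        assert core.data["cs137_sd"].iloc[0] == pytest.approx(16.66667, abs=1e-4)

    def test_missing_required_column_names_it(self, tmp_path):
        p = write_csv(tmp_path / "d.csv", "core_id,depth_min,fraction_organic_matter\nA,0,0.2\n")
        with pytest.raises(SchemaError, match="depth_max"):
            read_depthseries(p)

    def test_non_numeric_cell_reports_row(self, tmp_path):
        p = write_csv(tmp_path / "d.csv",
                      "core_id,depth_min,depth_max,fraction_organic_matter\nA,0,1,oops\n")
        with pytest.raises(ParseError, match="line 2"):
            read_depthseries(p)

    def test_inverted_depths_rejected(self, tmp_path):
        p = write_csv(tmp_path / "d.csv", "core_id,depth_min,depth_max\nA,2,1\n")
        with pytest.raises(CoreValidationError):
            read_depthseries(p)

    def test_missing_cells_are_nan_not_zero(self, tmp_path):
        p = write_csv(tmp_path / "d.csv",
                      "core_id,depth_min,depth_max,cs137_activity,cs137_activity_se\n"
                      "A,0,1,,\nA,1,2,5,0.5\n")
        (core,) = read_depthseries(p)
        assert np.isnan(core.data["cs137"].iloc[0])

    def test_roundtrip_preserves_values_and_order(self, tmp_path):
        rng = np.random.default_rng(0)
        core = make_core(n=20, loi=rng.uniform(0.05, 0.4, 20),
                         dbd=rng.uniform(0.3, 1.2, 20),
                         cs137=rng.uniform(0, 30, 20), cs137_sd=rng.uniform(0.1, 2, 20))
        p = tmp_path / "rt.csv"
        write_depthseries([core], p)
        (back,) = read_depthseries(p)
        for col in ("depth_min", "depth_max", "loi", "dry_bulk_density", "cs137"):
            np.testing.assert_allclose(back.data[col], core.data[col], rtol=1e-5)


class TestJoinMetadata:
    def test_join_sets_metadata(self, tmp_path):
        p = write_csv(tmp_path / "c.csv",
                      "core_id,site_id,latitude,longitude,year,habitat,vegetation\n"
                      "T1,S1,38.1,-122.5,2015,mid,Salicornia pacifica\n")
        (core,) = join_core_metadata([make_core()], p)
        assert core.collection_year == 2015
        assert core.latitude == pytest.approx(38.1)
        assert core.habitat_zone == "mid"
        assert core.dominant_species == ["Salicornia pacifica"]

    def test_unmatched_core_warns_and_leaves_unset(self, tmp_path):
        p = write_csv(tmp_path / "c.csv", "core_id,site_id,latitude,longitude,year\nZZ,S,0,0,2015\n")
        core = make_core(collection_year=None)
        with pytest.warns(UserWarning, match="no metadata"):
            (joined,) = join_core_metadata([core], p)
        assert joined.collection_year is None

    def test_duplicate_metadata_rows_error(self, tmp_path):
        p = write_csv(tmp_path / "c.csv",
                      "core_id,site_id,latitude,longitude,year\nT1,S,0,0,2015\nT1,S,0,0,2016\n")
        with pytest.raises(SchemaError, match="duplicate"):
            join_core_metadata([make_core()], p)


class TestInterpolateGaps:
    def test_interior_linear_midpoint(self):
        core = make_core(n=3, dbd=[0.4, np.nan, 0.6], loi=[0.1, 0.1, 0.1])
        out = interpolate_gaps(core)
        assert out.data["dry_bulk_density"].tolist() == pytest.approx([0.4, 0.5, 0.6])
        assert out.data["dbd_interpolated"].tolist() == [False, True, False]

    def test_edges_extended_by_nearest(self):
        core = make_core(n=3, loi=[np.nan, 0.2, 0.3], dbd=[1, 1, 1])
        out = interpolate_gaps(core)
        assert out.data["loi"].tolist() == pytest.approx([0.2, 0.2, 0.3])

    def test_all_missing_errors(self):
        core = make_core(n=3, dbd=[np.nan] * 3, loi=[0.1, 0.2, 0.3])
        with pytest.raises(CoreValidationError, match="dry_bulk_density"):
            interpolate_gaps(core)

    def test_idempotent_and_preserves_observed(self):
        core = make_core(n=5, dbd=[0.4, np.nan, 0.6, np.nan, 0.8], loi=[0.1] * 5)
        once = interpolate_gaps(core)
        twice = interpolate_gaps(once)
        pd.testing.assert_frame_equal(once.data, twice.data)
        assert once.data["dry_bulk_density"].iloc[0] == 0.4


class TestLoiOutlierFilter:
    def test_high_outlier_removed(self):
        core = make_core(n=5, loi=[0.10, 0.11, 0.12, 0.11, 0.90])
        filtered, removed = filter_loi_outliers(core)
        # Q1=0.11, Q3=0.12 (linear-interpolated order statistics), so the
        # upper fence is 0.12 + 1.5*0.01 = 0.135
        assert removed == [4.0]
        assert np.isnan(filtered.data["loi"].iloc[4])
        assert filtered.data["loi"].iloc[:4].notna().all()

    def test_constant_loi_nothing_removed(self):
        core = make_core(n=6, loi=[0.2] * 6)
        _, removed = filter_loi_outliers(core)
        assert removed == []

    def test_fewer_than_four_values_noop_with_warning(self):
        core = make_core(n=3, loi=[0.1, 0.2, 0.9])
        with pytest.warns(UserWarning, match="fewer than 4"):
            filtered, removed = filter_loi_outliers(core)
        assert removed == []
        assert filtered.data["loi"].notna().all()

    def test_removed_set_invariant_under_row_permutation(self):
        rng = np.random.default_rng(5)
        loi = np.concatenate([rng.uniform(0.1, 0.15, 15), [0.8, 0.02]])
        core = make_core(n=17, loi=loi)
        _, removed = filter_loi_outliers(core)
        perm = rng.permutation(17)
        shuffled = make_core(n=17, loi=loi)
        shuffled.data = shuffled.data.iloc[perm].reset_index(drop=True)
        core2 = core_io.SoilCore("T1", shuffled.data.sort_values("depth_min"))
        _, removed2 = filter_loi_outliers(core2)
        assert sorted(removed) == sorted(removed2)


class TestValidateCore:
    def test_clean_core_empty_report(self):
        core = make_core(n=5, loi=[0.1] * 5, dbd=[0.5] * 5)
        report = validate_core(core)
        assert report.passed and not report.has_errors

    def test_loi_out_of_range_is_error(self):
        core = make_core(n=3, loi=[0.1, 1.4, 0.2])
        report = validate_core(core)
        assert any(r == "loi_range" and s == "error" for r, s, _, _ in report.entries)

    def test_depth_gap_is_warning_only(self):
        data = pd.DataFrame({"depth_min": [0.0, 10.0, 12.0], "depth_max": [10.0, 10.5, 13.0]})
        # gap between 10.5 and 12
        core = core_io.SoilCore("G", data)
        report = validate_core(core)
        sevs = {r: s for r, s, _, _ in report.entries}
        assert sevs.get("non_contiguous") == "warning"
        assert not report.has_errors

    def test_activity_without_sd_is_error(self):
        core = make_core(n=3, cs137=[1.0, 2.0, 3.0])
        report = validate_core(core)
        assert report.has_errors
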