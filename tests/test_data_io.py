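"""Reading, classification and windowing of group-sighting data."""

import datetime as dt

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from shapely.geometry import box

from firenet.data_io import (
    ConfigurationError,
    FireScar,
    GroupObservation,
    RowError,
    SightingSource,
    StudyWindow,
    Treatment,
    VegPlot,
    classify_treatment,
    lonlat_to_local_meters,
    read_sightings,
    read_veg_plots,
    slice_window,
    write_sightings,
)

SCAR = FireScar(polygons=(box(0, 0, 1000, 1000),), burn_date=dt.date(2013, 7, 5))


def sighting(x, y, members=("A",), gid="g1", day=1):
    return GroupObservation(
        group_id=gid, obs_date=dt.date(2013, 6, day), location=(x, y),
        members=frozenset(members),
    )


class TestReadSightings:
    def test_long_rows_sharing_group_key_merge_into_one_observation(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("group_id,date,individual\ng1,2013-05-20,A\ng1,2013-05-20,B\n")
        out = read_sightings(p)
        assert len(out) == 1
        assert out[0].members == frozenset({"A", "B"})

    def test_singleton_row_yields_singleton_group(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("group_id,date,individual\ng1,2013-05-20,A\n")
        (one,) = read_sightings(p)
        assert one.members == frozenset({"A"})

    def test_day_month_dates_take_configured_study_year(self, data_dir):
        out = {o.group_id: o for o in read_sightings(data_dir / "sightings_dates.csv", year=2014)}
        assert out["g2"].obs_date == dt.date(2014, 6, 13)
        assert out["g1"].obs_date == dt.date(2014, 6, 10)

    def test_missing_mapped_column_names_the_column(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("gid,date,individual\ng1,2013-05-20,A\n")
        with pytest.raises(ConfigurationError, match="group_id"):
            read_sightings(p)

    def test_unparseable_date_reports_row_index(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("group_id,date,individual\ng1,2013-05-20,A\ng2,nonsense,B\n")
        with pytest.raises(RowError, match="row 1"):
            read_sightings(p)

    def test_empty_file_gives_empty_list(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("group_id,date,individual\n")
        assert read_sightings(p) == []

    def test_wide_layout_with_delimited_member_list(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("group_id,date,members\ng1,2013-05-20,A;B;C\n")
        (one,) = read_sightings(p)
        assert one.members == frozenset({"A", "B", "C"})

    def test_write_read_round_trip_preserves_observations(self, tmp_path):
        original = [
            sighting(12.5, -7.25, ("A", "B"), gid="g1", day=2),
            sighting(0.0, 3.0, ("C",), gid="g2", day=5),
        ]
        write_sightings(original, tmp_path / "rt.csv")
        back = read_sightings(tmp_path / "rt.csv")
        assert sorted(back, key=lambda o: o.group_id) == sorted(
            original, key=lambda o: o.group_id
        )


class TestClassifyTreatment:
    def test_sighting_inside_scar_is_affected_at_distance_zero(self):
        a = classify_treatment([sighting(500, 500)], SCAR)
        assert a.treatment is Treatment.AFFECTED
        assert a.min_distance_m == 0.0

    def test_all_sightings_beyond_500m_are_unaffected(self):
        a = classify_treatment(
            [sighting(1600, 500), sighting(1800, 500)], SCAR
        )
        assert a.treatment is Treatment.UNAFFECTED

    def test_sightings_in_buffer_band_are_excluded(self):
        a = classify_treatment(
            [sighting(1050, 500), sighting(1300, 500)], SCAR
        )
        assert a.treatment is Treatment.EXCLUDED

    def test_straddling_zones_is_excluded(self):
        a = classify_treatment([sighting(500, 500), sighting(1700, 500)], SCAR)
        assert a.treatment is Treatment.EXCLUDED

    def test_empty_sighting_list_errors(self):
        with pytest.raises(ValueError):
            classify_treatment([], SCAR)

    @given(
        d1=st.floats(0, 2000, allow_nan=False),
        d2=st.floats(0, 2000, allow_nan=False),
        r_small=st.floats(50, 200),
        r_grow=st.floats(0, 200),
    )
    @settings(max_examples=100, deadline=None)
    def test_enlarging_affected_radius_never_flips_affected_to_unaffected(
        self, d1, d2, r_small, r_grow
    ):
        pts = [sighting(1000 + d1, 500, gid="a"), sighting(1000 + d2, 500, gid="b")]
        before = classify_treatment(pts, SCAR, r_small, 5000.0).treatment
        after = classify_treatment(pts, SCAR, r_small + r_grow, 5000.0).treatment
        if before is Treatment.AFFECTED:
            assert after is Treatment.AFFECTED


class TestSliceWindow:
    WINDOW = StudyWindow("pre", dt.date(2013, 5, 15), dt.date(2013, 6, 28))

    def test_bounds_are_inclusive(self):
        on_start = GroupObservation("g", dt.date(2013, 5, 15), (0, 0), frozenset("A"))
        on_end = GroupObservation("h", dt.date(2013, 6, 28), (0, 0), frozenset("A"))
        after = GroupObservation("i", dt.date(2013, 6, 29), (0, 0), frozenset("A"))
        assert slice_window([on_start, on_end, after], self.WINDOW) == [on_start, on_end]

    def test_hand_counted_2013_fixture(self, data_dir):
        season = read_sightings(data_dir / "sightings_2013_season.csv")
        kept = slice_window(season, self.WINDOW)
        assert sorted(o.group_id for o in kept) == ["s2", "s3", "s4"]

    def test_disjoint_windows_give_disjoint_slices(self, data_dir):
        season = read_sightings(data_dir / "sightings_2013_season.csv")
        post = StudyWindow("post", dt.date(2013, 7, 13), dt.date(2013, 8, 24))
        ids_pre = {o.group_id for o in slice_window(season, self.WINDOW)}
        ids_post = {o.group_id for o in slice_window(season, post)}
        assert not ids_pre & ids_post


class TestVegPlots:
    def test_valid_rows_parse(self, tmp_path):
        p = tmp_path / "v.csv"
        p.write_text("plot_type,period,grass_cover\nused,post,85\nrandom,pre,0\n")
        plots = read_veg_plots(p)
        assert plots[0] == VegPlot("used", "post", 85.0)

    def test_off_grain_value_errors_in_strict_mode(self, tmp_path):
        p = tmp_path / "v.csv"
        p.write_text("plot_type,period,grass_cover\nrandom,pre,37\n")
        with pytest.raises(RowError):
            read_veg_plots(p, strict=True)

    def test_off_grain_value_snaps_half_down_in_lenient_mode(self, tmp_path):
        p = tmp_path / "v.csv"
        p.write_text(
            "plot_type,period,grass_cover\nrandom,pre,37\nused,post,37.5\nused,pre,38\n"
        )
        plots = read_veg_plots(p, strict=False)
        assert [pl.grass_cover for pl in plots] == [35.0, 35.0, 40.0]

    def test_out_of_range_cover_rejected(self, tmp_path):
        p = tmp_path / "v.csv"
        p.write_text("plot_type,period,grass_cover\nused,pre,105\n")
        with pytest.raises(RowError):
            read_veg_plots(p, strict=False)


def test_lonlat_projection_meters_scale():
    # one degree of latitude is ~111.2 km; longitude shrinks by cos(lat)
    origin = (131.0, -13.0)
    x, y = lonlat_to_local_meters(131.0, -12.99, origin)
    assert x == 0.0
    assert y == pytest.approx(1112.0, rel=0.01)
    x, _ = lonlat_to_local_meters(131.01, -13.0, origin)
    assert x == pytest.approx(1112.0 * 0.9744, rel=0.01)
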