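"""CSV loading, identifier matching, spline interpolation and frame sampling."""
import io
import zipfile

import numpy as np
import pytest

from gemvis.fixtures import FixtureSpec, make_toy_map
from gemvis.timecourse import (
    TimecourseFormatError,
    TimeSeriesTable,
    build_interpolants,
    match_identifiers,
    read_timecourse_csv,
    sample_frames,
)

from oracles import natural_spline_oracle


CSV = b"metabolite,0,5,10\nglc__D_c,1.0,2.0,3.0\natp_c,5.0,4.0,\n"


class TestReadCsv:
    def test_shape_pass_through(self):
        table = read_timecourse_csv(CSV)
        assert table.n_times == 3
        assert set(table.series) == {"glc__D_c", "atp_c"}
        assert table.missing["atp_c"].tolist() == [False, False, True]

    def test_transposed_parses_identically(self):
        transposed = b"time,glc__D_c,atp_c\n0,1.0,5.0\n5,2.0,4.0\n10,3.0,\n"
        a = read_timecourse_csv(CSV, orientation="rows")
        b = read_timecourse_csv(transposed, orientation="columns")
        c = read_timecourse_csv(transposed, orientation="auto")
        for other in (b, c):
            assert np.array_equal(a.times, other.times)
            for mid in a.series:
                np.testing.assert_array_equal(a.series[mid], other.series[mid])

    @pytest.mark.parametrize("delim", [";", "\t"])
    def test_delimiter_sniffing(self, delim):
        text = CSV.replace(b",", delim.encode())
        table = read_timecourse_csv(text)
        assert table.n_times == 3

    def test_decimal_comma(self):
        text = b"metabolite;0;5\nglc__D_c;1,5;2,5\n"
        table = read_timecourse_csv(text, delimiter=";", decimal=",")
        assert table.series["glc__D_c"].tolist() == [1.5, 2.5]

    def test_duplicate_metabolite_rows_rejected(self):
        text = b"metabolite,0,5\nglc__D_c,1,2\nglc__D_c,3,4\n"
        with pytest.raises(TimecourseFormatError, match="glc__D_c"):
            read_timecourse_csv(text)

    def test_non_numeric_time_label_named(self):
        text = b"metabolite,0,day5\nglc__D_c,1,2\n"
        with pytest.raises(TimecourseFormatError, match="day5"):
            read_timecourse_csv(text)

    def test_unsorted_times_sorted_ascending(self):
        text = b"metabolite,10,0,5\nglc__D_c,3,1,2\n"
        table = read_timecourse_csv(text)
        assert table.times.tolist() == [0.0, 5.0, 10.0]
        assert table.series["glc__D_c"].tolist() == [1.0, 2.0, 3.0]

    def test_zip_wrapped_csv(self):
        buf = io.BytesIO()
        with zipfile.ZipFile(buf, "w") as zf:
            zf.writestr("data.csv", CSV)
        table = read_timecourse_csv(buf.getvalue())
        assert table.n_times == 3


class TestMatchIdentifiers:
    def test_exact_matches(self, toy_map):
        table = TimeSeriesTable(
            times=np.array([0.0, 1.0]),
            series={"met0_c": np.array([1.0, 2.0]), "met1_c": np.array([2.0, 1.0])},
        )
        report = match_identifiers(table, toy_map)
        assert report.matched == {"met0_c", "met1_c"}
        assert not report.data_only

    def test_compartment_suffix_fallback(self, toy_map):
        table = TimeSeriesTable(
            times=np.array([0.0, 1.0]), series={"met0": np.array([1.0, 2.0])}
        )
        on = match_identifiers(table, toy_map, strip_compartment=True)
        assert on.matched == {"met0"} and on.aliases["met0"] == "met0_c"
        off = match_identifiers(table, toy_map, strip_compartment=False)
        assert off.data_only == {"met0"}

    def test_constructed_overlap_count(self):
        m, _ = make_toy_map(FixtureSpec(n_metabolites=8, seed=2))
        ids = [n.bigg_id for n in m.metabolite_nodes()]
        k = 5
        series = {mid: np.array([1.0, 2.0]) for mid in ids[:k]}
        series.update({f"absent{i}": np.array([0.0, 1.0]) for i in range(3)})
        report = match_identifiers(
            TimeSeriesTable(times=np.array([0.0, 1.0]), series=series), m
        )
        assert len(report.matched) == k
        assert len(report.data_only) == 3
        assert len(report.map_only) == 8 - k


class TestInterpolation:
    def test_knot_fidelity(self, toy_table):
        interp = build_interpolants(toy_table, clamp_floor=None)
        for mid, vals in toy_table.series.items():
            ok = ~toy_table.missing[mid]
            got = interp(mid, toy_table.times[ok])
            err = np.abs(got - vals[ok]) / np.maximum(1.0, np.abs(vals[ok]))
            assert err.max() <= 1e-9

    def test_constant_series_stays_constant(self):
        table = TimeSeriesTable(
            times=np.array([0.0, 1.0, 2.0]), series={"a": np.array([5.0, 5.0, 5.0])}
        )
        interp = build_interpolants(table)
        grid = np.linspace(0.0, 2.0, 101)
        np.testing.assert_allclose(interp("a", grid), 5.0, rtol=0, atol=1e-12)

    def test_matches_textbook_tridiagonal_solve(self):
        # knots from v = (t+1)^2 plus an irregular extension
        t = np.array([0.0, 1.0, 2.0, 3.0, 4.5, 7.0])
        v = (t + 1.0) ** 2
        table = TimeSeriesTable(times=t, series={"a": v})
        interp = build_interpolants(table, clamp_floor=None)
        oracle = natural_spline_oracle(t, v)
        grid = np.linspace(0.0, 7.0, 301)
        np.testing.assert_allclose(interp("a", grid), oracle(grid), rtol=0, atol=1e-9)

    def test_clamping_removes_negative_undershoot(self):
        table = TimeSeriesTable(
            times=np.array([0.0, 1.0, 2.0, 3.0]),
            series={"a": np.array([0.0, 10.0, 0.0, 10.0])},
        )
        grid = np.linspace(0.0, 3.0, 1001)
        raw = build_interpolants(table, clamp_floor=None)("a", grid)
        assert raw.min() < 0.0  # the natural spline really undershoots
        clamped = build_interpolants(table, clamp_floor=0.0)("a", grid)
        assert clamped.min() >= 0.0

    def test_two_points_linear_three_points_quadratic(self):
        t2 = TimeSeriesTable(times=np.array([0.0, 2.0]), series={"a": np.array([1.0, 5.0])})
        interp2 = build_interpolants(t2)
        assert interp2("a", 1.0) == pytest.approx(3.0)
        t3 = TimeSeriesTable(
            times=np.array([0.0, 1.0, 2.0]), series={"a": np.array([1.0, 4.0, 9.0])}
        )
        interp3 = build_interpolants(t3)
        # unique quadratic through (t+1)^2 knots is (t+1)^2 itself
        assert interp3("a", 0.5) == pytest.approx(2.25, abs=1e-9)

    def test_no_extrapolation_boundary_hold(self):
        table = TimeSeriesTable(
            times=np.array([0.0, 1.0, 2.0, 3.0]),
            series={"a": np.array([2.0, 3.0, 1.0, 4.0])},
        )
        interp = build_interpolants(table)
        assert interp("a", -5.0) == pytest.approx(2.0)
        assert interp("a", 99.0) == pytest.approx(4.0)

    def test_missing_values_dropped_per_series(self):
        table = TimeSeriesTable(
            times=np.array([0.0, 1.0, 2.0, 3.0]),
            series={"a": np.array([1.0, np.nan, 3.0, 4.0])},
        )
        interp = build_interpolants(table)
        assert interp("a", 2.0) == pytest.approx(3.0, abs=1e-9)

    def test_single_point_held_constant(self):
        table = TimeSeriesTable(
            times=np.array([0.0, 1.0, 2.0]),
            series={"a": np.array([np.nan, 7.0, np.nan])},
        )
        interp = build_interpolants(table)
        np.testing.assert_allclose(interp("a", np.array([0.0, 2.0])), 7.0)

    def test_all_missing_series_excluded(self):
        table = TimeSeriesTable(
            times=np.array([0.0, 1.0]),
            series={"a": np.array([np.nan, np.nan]), "b": np.array([1.0, 2.0])},
        )
        interp = build_interpolants(table)
        assert interp.ids() == ["b"]

    def test_pchip_is_overshoot_free(self):
        table = TimeSeriesTable(
            times=np.array([0.0, 1.0, 2.0, 3.0]),
            series={"a": np.array([0.0, 10.0, 0.0, 10.0])},
        )
        interp = build_interpolants(table, method="pchip", clamp_floor=None)
        grid = np.linspace(0.0, 3.0, 1001)
        vals = interp("a", grid)
        assert vals.min() >= -1e-12 and vals.max() <= 10.0 + 1e-12

    def test_time_reversal_symmetry(self, toy_table):
        interp = build_interpolants(toy_table, clamp_floor=None)
        t = toy_table.times
        reversed_table = TimeSeriesTable(
            times=(t[-1] - t)[::-1].copy(),
            series={mid: vals[::-1].copy() for mid, vals in toy_table.series.items()},
        )
        rinterp = build_interpolants(reversed_table, clamp_floor=None)
        grid = np.linspace(t[0], t[-1], 57)
        for mid in toy_table.series:
            fwd = interp(mid, grid)
            bwd = rinterp(mid, t[-1] - grid)
            np.testing.assert_allclose(fwd, bwd, rtol=0, atol=1e-9)


class TestSampleFrames:
    def test_frame_count_arithmetic(self, toy_table):
        interp = build_interpolants(toy_table)
        times, ids, matrix = sample_frames(interp, duration_s=10.0, fps=30.0)
        assert matrix.shape == (300, len(ids))

    def test_boundary_frames_equal_knot_values(self, toy_table):
        interp = build_interpolants(toy_table, clamp_floor=None)
        times, ids, matrix = sample_frames(interp, duration_s=2.0, fps=10.0)
        for j, mid in enumerate(ids):
            ok = ~toy_table.missing[mid]
            assert matrix[0, j] == pytest.approx(toy_table.series[mid][ok][0], rel=1e-9)
            assert matrix[-1, j] == pytest.approx(toy_table.series[mid][ok][-1], rel=1e-9)

    def test_linear_series_linear_in_frame_index(self):
        table = TimeSeriesTable(
            times=np.array([0.0, 4.0, 10.0]), series={"a": np.array([1.0, 5.0, 11.0])}
        )
        interp = build_interpolants(table)
        _times, _ids, matrix = sample_frames(interp, duration_s=3.0, fps=17.0)
        n = matrix.shape[0]
        expected = 1.0 + 10.0 * np.arange(n) / (n - 1)
        np.testing.assert_allclose(matrix[:, 0], expected, rtol=0, atol=1e-9)

    def test_refining_fps_preserves_coinciding_frames(self, toy_table):
        interp = build_interpolants(toy_table)
        _t1, _i1, m1 = sample_frames(interp, duration_s=2.0, fps=10.0)  # 20 frames
        _t2, _i2, m2 = sample_frames(interp, duration_s=2.0, fps=29.5)  # 59 frames
        # frame grids share endpoints; interior coinciding times agree
        np.testing.assert_allclose(m1[0], m2[0], atol=1e-12)
        np.testing.assert_allclose(m1[-1], m2[-1], atol=1e-12)

    def test_nonnegative_with_default_clamp(self, toy_table):
        interp = build_interpolants(toy_table)  # clamp_floor=0 default
        _t, _ids, matrix = sample_frames(interp, duration_s=2.0, fps=25.0)
        assert matrix.min() >= 0.0

    def test_invalid_duration_rejected(self, toy_table):
        interp = build_interpolants(toy_table)
        with pytest.raises(ValueError):
            sample_frames(interp, duration_s=0.0, fps=10.0)
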