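"""Jump detection, nested pairing, distance conversion and error stats."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import phasemorph as pm
from phasemorph.jumps import PairingError

from conftest import make_profile


def _jump_tuples(jumps):
    return [(j.pixel_index, j.sign) for j in jumps]


class TestDetectJumps:
    def test_constant_profile_yields_nothing(self):
        assert pm.detect_jumps(make_profile(np.zeros(20))) == []
        assert pm.detect_jumps(make_profile(np.full(20, 3.0))) == []

    def test_two_isolated_spikes(self):
        prof = make_profile([0, 0, 10, 0, 0, -10, 0])
        got = pm.detect_jumps(prof, threshold_fraction=0.5)
        assert _jump_tuples(got) == [(2, 1), (5, -1)]
        assert got[0].magnitude == pytest.approx(10.0)

    def test_reference_phantom_row_has_four_jumps(self, center_row_profile):
        jumps = pm.detect_jumps(center_row_profile)
        assert [j.sign for j in jumps] == [1, 1, -1, -1]
        assert [j.pixel_index for j in jumps] == sorted(
            j.pixel_index for j in jumps
        )

    def test_padded_tail_is_never_a_jump(self):
        ramp = np.zeros(12)
        ramp[-2] = 8.0  # spike just before the padded terminal index
        prof = make_profile(ramp, padded_tail=True)
        jumps = pm.detect_jumps(prof)
        assert all(j.pixel_index < 11 for j in jumps)

    def test_threshold_fraction_validated(self, center_row_profile):
        for bad in (0.0, 1.0, -0.2):
            with pytest.raises(ValueError):
                pm.detect_jumps(center_row_profile, bad)

    def test_squared_profile_with_companion_signs(self, gx, grid, center_row_profile):
        sq = pm.modulus_squared(gx)
        sq_prof = pm.extract_profile(sq, pm.RowLine(grid.nearest_row(0.0)))
        got = pm.detect_jumps(sq_prof, signs_from=center_row_profile)
        want = pm.detect_jumps(center_row_profile)
        assert _jump_tuples(got) == _jump_tuples(want)


class TestPairJumps:
    @pytest.mark.parametrize(
        "indices,pairs",
        [
            # reported reference jump columns for the centre row and for
            # the offset traversal of the eccentric-sphere phantom
            ((28, 138, 221, 229), [(28, 229), (138, 221)]),
            ((35, 162, 196, 222), [(35, 222), (162, 196)]),
        ],
    )
    def test_nested_pairing_of_reference_columns(self, indices, pairs):
        m = len(indices) // 2
        jumps = [
            pm.JumpPoint(i, 1 if k < m else -1, 1.0) for k, i in enumerate(indices)
        ]
        got = pm.pair_jumps(jumps)
        assert [
            (left.pixel_index, right.pixel_index) for left, right in got.pairs
        ] == pairs

    def test_two_jumps_make_one_pair(self):
        got = pm.pair_jumps([pm.JumpPoint(3, 1, 1.0), pm.JumpPoint(9, -1, 1.0)])
        assert len(got) == 1

    @pytest.mark.parametrize(
        "signs", [(1, -1, 1, -1), (1, 1, -1), (-1, 1), (1, 1, 1, -1)]
    )
    def test_non_nested_signatures_fail(self, signs):
        jumps = [pm.JumpPoint(5 * (k + 1), s, 1.0) for k, s in enumerate(signs)]
        with pytest.raises(PairingError):
            pm.pair_jumps(jumps)


class TestPixelPairDistance:
    def test_reference_grid_conversions(self, grid):
        # one unit in the third decimal covers the printed table rounding
        assert pm.pixel_pair_distance(28, 229, grid) == pytest.approx(11.823, abs=1e-3)
        assert pm.pixel_pair_distance(162, 196, grid) == pytest.approx(2.000, abs=1e-9)

    def test_zero_and_exactness(self, grid):
        assert pm.pixel_pair_distance(40, 40, grid) == 0.0
        assert pm.pixel_pair_distance(0, 17, grid) == pytest.approx(1.0, abs=1e-12)

    def test_bounds_checked(self, grid):
        with pytest.raises(ValueError):
            pm.pixel_pair_distance(10, 255, grid)
        with pytest.raises(ValueError):
            pm.pixel_pair_distance(200, 100, grid)


class TestDistanceReport:
    def _pairs(self, spans):
        m = len(spans)
        jumps = [pm.JumpPoint(left, 1, 1.0) for left, _ in spans]
        jumps += [pm.JumpPoint(right, -1, 1.0) for _, right in reversed(spans)]
        return pm.pair_jumps(jumps)

    def test_reference_centre_row_rows(self, grid):
        report = pm.build_distance_report(self._pairs([(28, 229), (138, 221)]), grid.dx)
        assert [r.label for r in report.rows] == [
            "1-1",
            "2-2",
            "1-2 (left)",
            "1-2 (right)",
        ]
        got = [r.microns for r in report.rows]
        np.testing.assert_allclose(got, [11.823, 4.882, 6.471, 0.471], atol=1e-3)
        assert [r.pixels for r in report.rows] == [201, 83, 110, 8]

    def test_reference_offset_row_rows(self, grid):
        report = pm.build_distance_report(self._pairs([(35, 222), (162, 196)]), grid.dx)
        got = [r.microns for r in report.rows]
        np.testing.assert_allclose(got, [11.000, 2.000, 7.471, 1.529], atol=1e-3)

    def test_single_pair_has_no_gap_rows(self, grid):
        report = pm.build_distance_report(self._pairs([(10, 90)]), grid.dx)
        assert len(report.rows) == 1
        assert report.rows[0].kind == "diameter"

    def test_physical_equals_pixels_times_pitch_exactly(self, grid):
        report = pm.build_distance_report(self._pairs([(28, 229), (138, 221)]), grid.dx)
        for row in report.rows:
            assert row.microns == row.pixels * grid.dx


class TestErrorStats:
    def test_printed_reference_values(self):
        stats = pm.error_stats_from_values(
            [11.823, 4.882, 6.471, 0.471],
            [12.0, 5.0, 6.5, 0.5],
            [True, True, False, False],
        )
        assert stats.max_diameter_error_um == pytest.approx(0.177, abs=1e-9)
        assert round(stats.mean_relative_error_pct, 1) == 2.5

    def test_exact_match_gives_zero_errors(self):
        stats = pm.error_stats_from_values([12.0, 5.0], [12.0, 5.0], [True, True])
        assert stats.max_diameter_error_um == 0.0
        assert stats.mean_relative_error_pct == 0.0

    def test_max_error_ignores_gap_rows(self):
        stats = pm.error_stats_from_values(
            [11.9, 4.9, 5.0], [12.0, 5.0, 6.5], [True, True, False]
        )
        # the gap row has the largest absolute error but is not a diameter
        assert stats.max_diameter_error_um == pytest.approx(0.1)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            pm.error_stats_from_values([1.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            pm.error_stats_from_values([1.0], [0.0])


@settings(derandomize=True, max_examples=40, deadline=None)
@given(
    body_radius=st.floats(5.0, 6.5),
    radius_ratio=st.floats(0.2, 0.3),
    offset_frac=st.floats(0.0, 1.0),
)
def test_nested_phantom_jump_structure(body_radius, radius_ratio, offset_frac):
    """Rows crossing both discs give exactly 4 jumps (+, +, -, -); rows
    missing the nucleus give exactly 2; squared-profile detection agrees
    with the signed profile."""
    nucleus_radius = radius_ratio * body_radius
    ox = offset_frac * (body_radius - nucleus_radius - 0.45)
    grid = pm.nucleated_cell_grid()
    model = pm.nucleated_cell_model(
        body_radius=body_radius,
        nucleus_radius=nucleus_radius,
        nucleus_center=(ox, 0.0, 0.0),
    )
    gx = pm.forward_diff_gradient(pm.render_phase_map(model, grid), "x")

    through = pm.extract_profile(gx, pm.RowLine(grid.nearest_row(0.0)))
    jumps = pm.detect_jumps(through)
    assert [j.sign for j in jumps] == [1, 1, -1, -1]
    pairs = pm.pair_jumps(jumps)
    assert len(pairs) == 2

    sq_prof = pm.extract_profile(
        pm.modulus_squared(gx), pm.RowLine(grid.nearest_row(0.0))
    )
    sq_jumps = pm.detect_jumps(sq_prof, signs_from=through)
    assert _jump_tuples(sq_jumps) == _jump_tuples(jumps)

    missing = pm.extract_profile(
        gx, pm.RowLine(grid.nearest_row(nucleus_radius + 0.5))
    )
    assert [j.sign for j in pm.detect_jumps(missing)] == [1, -1]


def test_distance_stability_under_grid_refinement(cell_model):
    """Doubling the raster resolution moves every reported separation by
    at most one pixel of the coarse grid per boundary (two pitches)."""
    reports = {}
    for nx in (255, 510):
        grid = pm.nucleated_cell_grid(nx)
        gx = pm.forward_diff_gradient(pm.render_phase_map(cell_model, grid), "x")
        prof = pm.extract_profile(gx, pm.RowLine(grid.nearest_row(0.0)))
        pairs = pm.pair_jumps(pm.detect_jumps(prof))
        reports[nx] = pm.build_distance_report(pairs, prof.step_um)
    coarse_pitch = 15.0 / 255
    for a, b in zip(reports[255].rows, reports[510].rows):
        assert abs(a.microns - b.microns) <= 2 * coarse_pitch
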