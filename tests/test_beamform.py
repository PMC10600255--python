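import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import umi
from umi.beamform import (
    time_of_flight_planewave,
    time_of_flight_transducer,
    to_common_midpoint,
)


class TestTimesOfFlight:
    def test_on_axis(self):
        tau = time_of_flight_transducer([[0.0, 0.0]], [[0.0, 0.0, 30.0]], 1.5)
        assert tau == pytest.approx(20.0)

    def test_off_axis_example(self):
        # |u - r| = sqrt(100 + 900) mm at c0 = 1.5 mm/µs -> 21.082 µs
        tau = time_of_flight_transducer([[10.0, 0.0]], [[0.0, 0.0, 30.0]], 1.5)
        assert tau == pytest.approx(np.sqrt(1000.0) / 1.5, rel=1e-9)
        assert tau == pytest.approx(21.082, abs=1e-3)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        dx=st.floats(-5, 5), dy=st.floats(-5, 5),
        ux=st.floats(-8, 8), uy=st.floats(-8, 8),
        x=st.floats(-8, 8), y=st.floats(-8, 8), z=st.floats(1, 60),
    )
    def test_translation_invariance(self, dx, dy, ux, uy, x, y, z):
        a = time_of_flight_transducer([[ux, uy]], [[x, y, z]], 1.54)
        b = time_of_flight_transducer([[ux + dx, uy + dy]], [[x + dx, y + dy, z]], 1.54)
        assert np.isclose(a, b, rtol=1e-12)

    def test_planewave_normal(self):
        assert time_of_flight_planewave((0.0, 0.0), [[3.0, -2.0, 28.0]], 1.4) == pytest.approx(20.0)

    def test_planewave_oblique_example(self):
        # z cos(28 deg) / c0 at z = 40 mm, c0 = 1.4 mm/µs -> 25.22 µs
        tau = time_of_flight_planewave((28.0, 0.0), [[0.0, 0.0, 40.0]], 1.4)
        assert tau == pytest.approx(40.0 * np.cos(np.deg2rad(28.0)) / 1.4, rel=1e-9)
        assert tau == pytest.approx(25.22, abs=1e-2)

    def test_planewave_shift_linearity(self):
        t1 = time_of_flight_planewave((17.0, 0.0), [[1.0, 0.0, 30.0]], 1.5)
        t2 = time_of_flight_planewave((17.0, 0.0), [[3.5, 0.0, 30.0]], 1.5)
        assert t2 - t1 == pytest.approx(2.5 * np.sin(np.deg2rad(17.0)) / 1.5)

    def test_evanescent_rejected(self):
        with pytest.raises(ValueError):
            time_of_flight_planewave((80.0, 80.0), [[0.0, 0.0, 10.0]], 1.5)


class TestFocusedMatrix:
    def test_confocal_peak_at_scatterer(self, probe8, point_raw8, small_grid8):
        f = umi.beamform_focused_matrix(point_raw8, small_grid8, drho_max=6.0)
        img = umi.confocal_image(f)
        iz, iy, ix = np.unravel_index(np.argmax(img), img.shape)
        assert (small_grid8.z[iz], small_grid8.y[iy], small_grid8.x[ix]) == (15.0, 0.0, 0.0)
        # brightest voxel of its depth plane
        assert img[iz].max() == img.max()

    def test_oracle_equivalence(self, probe8):
        """Vectorized DAS equals the nested-loop reference to machine precision."""
        rng = np.random.default_rng(0)
        pos = np.column_stack(
            [rng.uniform(-1, 1, 5), rng.uniform(-1, 1, 5), rng.uniform(13.5, 16.5, 5)]
        )
        gam = rng.standard_normal(5) + 1j * rng.standard_normal(5)
        med = umi.simulate.MediumModel(pos, gam, ((-1, 1), (-1, 1), (13.5, 16.5)))
        raw = umi.simulate_acquisition(probe8, med, seed=2)
        grid = umi.ImagingGrid.regular((-1.0, 1.0), (-1.0, 1.0), (14.0, 16.0), pitch=1.0)
        fast = umi.beamform_focused_matrix(raw, grid, drho_max=5.0)
        slow = umi.reference_das(raw, grid, drho_max=5.0)
        err = np.abs(fast.data - slow.data).max() / np.abs(slow.data).max()
        assert err <= 1e-9

    def test_symmetry_transport(self, probe8, point_raw8, small_grid8):
        f = umi.beamform_focused_matrix(point_raw8, small_grid8, drho_max=6.0)
        assert f.symmetry_defect().max() <= 1e-9

    def test_drho_truncation(self, probe8, point_raw8, small_grid8):
        f = umi.beamform_focused_matrix(point_raw8, small_grid8, drho_max=1.0)
        pts = small_grid8.transverse_points()
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        assert np.all(f.data[:, d > 1.0 + 1e-9] == 0.0)

    def test_medium_shift_moves_peak(self, probe8):
        """Translating the medium moves the confocal peak accordingly."""
        t_span = (16.0, 26.0)
        raw_a = umi.simulate_acquisition(
            probe8, umi.point_target_medium((0.0, 0.0, 15.0)), seed=1, t_span=t_span
        )
        raw_b = umi.simulate_acquisition(
            probe8, umi.point_target_medium((0.5, -0.5, 15.0)), seed=1, t_span=t_span
        )
        grid = umi.ImagingGrid.regular((-1.5, 1.5), (-1.5, 1.5), (14.5, 15.5), pitch=0.5)
        for raw, exp in [(raw_a, (0.0, 0.0)), (raw_b, (0.5, -0.5))]:
            img = umi.confocal_image(umi.beamform_focused_matrix(raw, grid, drho_max=6.0))
            iz, iy, ix = np.unravel_index(np.argmax(img), img.shape)
            assert (grid.x[ix], grid.y[iy]) == exp

    def test_coverage_flags_unreachable_points(self, probe8):
        # at shallow depth, far off-axis points fall outside every cone
        grid = umi.ImagingGrid.regular((-8.0, 8.0), (0.0, 0.0), (2.0, 2.0), pitch=1.0)
        raw = umi.simulate_acquisition(
            probe8, umi.point_target_medium((0.0, 0.0, 15.0)), seed=1, t_span=(0.0, 25.0)
        )
        f = umi.beamform_focused_matrix(raw, grid, drho_max=20.0)
        assert not f.coverage.all()
        assert f.coverage[0, np.argmin(np.abs(grid.x))]

    def test_band_selection_validates(self, probe8, point_raw8, small_grid8):
        with pytest.raises(ValueError):
            umi.beamform_focused_matrix(
                point_raw8, small_grid8, band=(2.9, 2.95)
            )

    def test_time_axis_coverage_checked(self, probe8, point_raw8):
        grid = umi.ImagingGrid.regular((-1.0, 1.0), (-1.0, 1.0), (60.0, 62.0), pitch=1.0)
        with pytest.raises(ValueError, match="time axis"):
            umi.beamform_focused_matrix(point_raw8, grid)


class TestCommonMidpoint:
    def test_confocal_sheet_equals_diagonal(self, speckle12):
        f = speckle12["focused"]
        cm = to_common_midpoint(f)
        diag = np.diagonal(f.data, axis1=1, axis2=2).reshape(
            f.data.shape[0], f.grid.ny, f.grid.nx
        )
        assert np.array_equal(cm.confocal(), diag)

    def test_relabelling_matches_matrix_entries(self, speckle12):
        f = speckle12["focused"]
        cm = to_common_midpoint(f)
        grid = f.grid
        # R_M(drho, r_m) == R(rho_m - drho/2, rho_m + drho/2, z)
        val = cm.value((1.0, -0.5), (0.5, 0.25, 20.0))
        p_in = np.argmin(
            np.linalg.norm(grid.transverse_points() - [0.0, 0.5], axis=1)
        )
        p_out = np.argmin(
            np.linalg.norm(grid.transverse_points() - [1.0, 0.0], axis=1)
        )
        iz = np.argmin(np.abs(grid.z - 20.0))
        assert val == f.data[iz, p_in, p_out]

    def test_reciprocal_symmetry_in_midpoint_basis(self, speckle12):
        cm = to_common_midpoint(speckle12["focused"])
        a = cm.value((1.0, 0.5), (0.0, 0.0, 20.0))
        b = cm.value((-1.0, -0.5), (0.0, 0.0, 20.0))
        assert a == pytest.approx(b, rel=1e-9)

    def test_round_trip_identity(self, speckle12):
        f = speckle12["focused"]
        cm = to_common_midpoint(f)
        back = cm.to_focused(f)
        assert np.allclose(back.data[:, f.pair_mask], f.data[:, f.pair_mask])


@pytest.fixture(scope="module")
def pw_raw(probe8):
    angles = np.array(
        [(tx, ty) for tx in (-12, -6, 0, 6, 12) for ty in (-12, -6, 0, 6, 12)],
        dtype=float,
    )
    med = umi.point_target_medium((0.0, 1.0, 15.0))
    return umi.simulate_acquisition(
        probe8, med, basis="planewave", seed=1, angles_deg=angles
    )


class TestLinearArrayEmulation:

    def test_3d_planewave_confocal_peak(self, pw_raw):
        grid = umi.ImagingGrid.regular((-1.5, 1.5), (-0.5, 2.5), (14.0, 16.0), pitch=0.5)
        img = umi.confocal_image(umi.beamform_focused_matrix(pw_raw, grid, drho_max=5.0))
        iz, iy, ix = np.unravel_index(np.argmax(img), img.shape)
        assert (grid.z[iz], grid.y[iy], grid.x[ix]) == (15.0, 1.0, 0.0)

    def test_emulated_2d_peak_matches_3d(self, pw_raw):
        f2 = umi.emulate_linear_array(
            pw_raw,
            focus_line=(0.0, 15.0),
            grid_y=np.arange(-0.5, 2.51, 0.5),
            grid_z=np.arange(14.0, 16.01, 0.5),
            axis="y",
            drho_max=5.0,
        )
        img = umi.confocal_image(f2)
        iz, iy, _ = np.unravel_index(np.argmax(img), img.shape)
        assert (f2.grid.z[iz], f2.grid.y[iy]) == (15.0, 1.0)

    def test_requires_planewave_basis(self, point_raw8):
        with pytest.raises(ValueError):
            umi.emulate_linear_array(
                point_raw8, (0.0, 15.0), np.arange(-1, 1.1, 0.5), np.array([15.0])
            )
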