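import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import umi
from umi.beamform import FocusedReflectionMatrix
from umi.grids import ImagingGrid
from umi.metrics import (
    PatchSpec,
    antisymmetry_rate,
    decompose_rpsf,
    diffraction_limit,
    local_rpsf,
    resolution_3db,
    scattering_rates,
)


def matrix_fixture(data, pitch=0.5, half=3.5):
    """Wrap a raw per-depth matrix as a FocusedReflectionMatrix."""
    data = np.atleast_3d(data)
    if data.shape[0] != 1:
        data = data[None] if data.ndim == 2 else data
    n = int(np.sqrt(data.shape[1]))
    grid = ImagingGrid.regular((-half, half), (-half, half), (10.0, 10.0), pitch=pitch)
    assert grid.n_transverse == data.shape[1]
    return FocusedReflectionMatrix(
        grid=grid,
        data=data,
        drho_max=2 * half + 1,
        pair_mask=np.ones(data.shape[1:], bool),
        coverage=np.ones(data.shape[:2], bool),
    )


class TestDiffractionLimit:
    def test_shallow_limit_is_half_wavelength(self):
        assert diffraction_limit(1e-9, 0.5, 16.0) == pytest.approx(0.25, rel=1e-4)

    def test_reference_value(self):
        # lambda 0.513 mm, aperture 16 mm, z 40 mm -> 1.308 mm
        assert diffraction_limit(40.0, 0.513, 16.0) == pytest.approx(1.308, abs=2e-3)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(z=st.floats(1.0, 100.0), dz=st.floats(0.1, 20.0))
    def test_monotone_in_depth(self, z, dz):
        assert diffraction_limit(z + dz, 0.5, 16.0) > diffraction_limit(z, 0.5, 16.0)

    def test_rejects_nonpositive_depth(self):
        with pytest.raises(ValueError):
            diffraction_limit(0.0, 0.5, 16.0)


class TestResolution:
    def test_gaussian_closed_form(self):
        # isotropic Gaussian amplitude with std sigma -> radius sigma*sqrt(2 ln 2)
        off = np.arange(-10, 10.05, 0.1)
        sigma = 1.3
        amp = np.exp(-(off[None, :] ** 2 + off[:, None] ** 2) / (2 * sigma**2))
        r, flag = resolution_3db(amp**2, off, off)
        assert not flag
        assert r == pytest.approx(sigma * np.sqrt(2 * np.log(2)), rel=0.03)

    def test_single_pixel_peak(self):
        off = np.arange(-2, 2.5, 0.5)
        prof = np.zeros((9, 9))
        prof[4, 4] = 1.0
        r, flag = resolution_3db(prof, off, off)
        assert r == pytest.approx(np.sqrt(0.25 / np.pi))
        assert not flag

    def test_plateau_flagged(self):
        off = np.arange(-2, 2.5, 0.5)
        r, flag = resolution_3db(np.ones((9, 9)), off, off)
        assert flag

    def test_background_excluded_by_connectivity(self):
        off = np.arange(-5, 5.5, 0.5)
        prof = np.full((21, 21), 0.2)  # amplitude 0.45: below half max
        prof[9:12, 9:12] = 0.5  # amplitude 0.71: above
        prof[10, 10] = 1.0
        # an isolated far blob above half max must not count
        prof[1, 1] = 0.6
        r, _ = resolution_3db(prof, off, off)
        assert r == pytest.approx(np.sqrt(9 * 0.25 / np.pi), rel=1e-6)


class TestDecomposition:
    def test_delta_plus_plateau(self):
        off = np.arange(-10, 10.5, 0.5)
        prof = np.full((41, 41), 0.2)
        prof[20, 20] = 1.0
        alpha_b, contrast, flag = decompose_rpsf(prof, off, off, delta_rho0=0.3)
        assert alpha_b == pytest.approx(0.2)
        assert contrast == pytest.approx(4.0)
        assert not flag

    def test_zero_background_capped(self):
        off = np.arange(-10, 10.5, 0.5)
        prof = np.zeros((41, 41))
        prof[20, 20] = 1.0
        alpha_b, contrast, flag = decompose_rpsf(prof, off, off, delta_rho0=0.3)
        assert alpha_b == 0.0 and flag and contrast >= 1e6

    def test_half_background_gives_unit_contrast(self):
        off = np.arange(-10, 10.5, 0.5)
        prof = np.full((41, 41), 0.5)
        prof[20, 20] = 1.0
        alpha_b, contrast, _ = decompose_rpsf(prof, off, off, delta_rho0=0.3)
        assert contrast == pytest.approx(1.0)

    def test_empty_annulus_flagged(self):
        off = np.arange(-1, 1.5, 0.5)
        prof = np.ones((5, 5))
        _, _, flag = decompose_rpsf(prof, off, off, delta_rho0=10.0)
        assert flag


class TestLocalRPSF:
    def test_uniform_field_gives_uniform_rpsf(self):
        n = 81  # 9x9 grid
        f = matrix_fixture(np.full((1, n, n), 2.0 + 0j), half=2.0)
        rm = local_rpsf(f, PatchSpec.single(f.grid))
        assert np.allclose(rm.rpsf[0][np.isfinite(rm.rpsf[0])], 4.0)

    def test_speckle_peak_at_zero_offset(self, speckle12):
        rm = local_rpsf(speckle12["focused"], PatchSpec.single(speckle12["grid"]))
        a = np.argmin(np.abs(rm.offsets_y))
        b = np.argmin(np.abs(rm.offsets_x))
        assert np.nanargmax(rm.rpsf[0]) == np.ravel_multi_index((a, b), rm.rpsf[0].shape)

    def test_low_midpoint_patches_flagged(self, speckle12):
        tiny = PatchSpec(np.array([[0.0, 0.0, 20.0]]), w_rho=0.6, w_z=0.6)
        rm = local_rpsf(speckle12["focused"], tiny, min_midpoints=10)
        assert rm.low_confidence[0]

    def test_unaberrated_speckle_width_tracks_diffraction(self, speckle12):
        """Mean RPSF −3 dB radius within 25% of the diffraction limit."""
        geom = speckle12["geometry"]
        rm = local_rpsf(speckle12["focused"], PatchSpec.single(speckle12["grid"]))
        r, flag = resolution_3db(rm.rpsf[0], rm.offsets_x, rm.offsets_y)
        rho0 = diffraction_limit(20.0, geom.wavelength, float(np.mean(geom.aperture)))
        assert not flag
        assert abs(r / rho0 - 1.0) <= 0.25


class TestAntisymmetry:
    def test_symmetric_zero(self):
        rng = np.random.default_rng(1)
        m = rng.standard_normal((225, 225)) + 1j * rng.standard_normal((225, 225))
        f = matrix_fixture((m + m.T)[None] / 2)
        beta = antisymmetry_rate(f, PatchSpec.single(f.grid), delta_rho0=0.01)
        assert beta[0] <= 1e-12

    def test_antisymmetric_one(self):
        rng = np.random.default_rng(2)
        m = rng.standard_normal((225, 225)) + 1j * rng.standard_normal((225, 225))
        f = matrix_fixture((m - m.T)[None] / 2)
        beta = antisymmetry_rate(f, PatchSpec.single(f.grid), delta_rho0=0.01)
        assert beta[0] >= 1.0 - 1e-12

    def test_iid_half(self):
        betas = []
        for k in range(20):
            rng = np.random.default_rng(100 + k)
            m = rng.standard_normal((225, 225)) + 1j * rng.standard_normal((225, 225))
            f = matrix_fixture(m[None])
            betas.append(
                antisymmetry_rate(f, PatchSpec.single(f.grid), delta_rho0=0.01)[0]
            )
        assert np.mean(betas) == pytest.approx(0.5, abs=0.02)

    def test_invariant_under_global_scaling(self):
        rng = np.random.default_rng(3)
        m = rng.standard_normal((225, 225)) + 1j * rng.standard_normal((225, 225))
        f1 = matrix_fixture(m[None])
        f2 = matrix_fixture((m * (3.0 - 4.0j))[None])
        p = PatchSpec.single(f1.grid)
        b1 = antisymmetry_rate(f1, p, delta_rho0=0.01)
        b2 = antisymmetry_rate(f2, p, delta_rho0=0.01)
        assert b1[0] == pytest.approx(b2[0], rel=1e-12)


class TestScatteringRates:
    @pytest.mark.parametrize(
        "beta,alpha_b,expected",
        [
            (0.5, 0.4, (0.0, 0.4)),  # pure noise background
            (0.0, 0.4, (0.4, 0.0)),  # pure multiple scattering
            (0.25, 0.5, (0.25, 0.25)),
        ],
    )
    def test_split(self, beta, alpha_b, expected):
        assert scattering_rates(beta, alpha_b) == pytest.approx(expected)

    def test_beta_above_half_clipped(self):
        a_m, a_n = scattering_rates(0.6, 0.4)
        assert a_m == 0.0 and a_n == pytest.approx(0.4)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(beta=st.floats(0, 0.5), alpha_b=st.floats(0, 1))
    def test_rates_sum_to_one(self, beta, alpha_b):
        a_m, a_n = scattering_rates(beta, alpha_b)
        assert (1.0 - alpha_b) + a_m + a_n == pytest.approx(1.0)
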