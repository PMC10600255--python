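import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import umi
from umi.aberration import (
    ConvergenceError,
    CorrectionSchedule,
    CorrectionStep,
    apply_correction,
    confocal_filter,
    distortion,
    iterative_phase_reversal,
    local_correlation,
    propagator,
    reciprocity_product,
    remove_tilt,
    run_multiscale,
    stitch_laws,
)
from umi.beamform import time_of_flight_transducer


def speckle_like_correlation(n, seed, corr_len=5.0, noise=0.0):
    """Hermitian correlation matrix with a hidden phase law: diag(t) M diag(t)*
    with M a real positive kernel — the structure local D-matrix
    correlations take in speckle."""
    rng = np.random.default_rng(seed)
    phase = np.cumsum(rng.standard_normal(n)) * 0.3
    t = np.exp(1j * phase)
    idx = np.arange(n)
    m = np.exp(-np.abs(idx[:, None] - idx[None, :]) / corr_len)
    c = np.outer(t, t.conj()) * m
    if noise:
        w = rng.standard_normal((n, n)) + 1j * rng.standard_normal((n, n))
        h = (w + w.conj().T) / 2
        c = c + noise * h / np.sqrt(n)
    return c, t


def circ_corr(a, b):
    return float(np.abs(np.mean(a * np.conj(b))))


class TestPropagator:
    def test_transducer_on_axis_modulus(self, probe12, speckle12):
        g = propagator("transducer", speckle12["grid"], probe12)
        # element right above a grid point: |G| = 1/(4 pi z)
        pts = speckle12["grid"].transverse_points()
        u = probe12.element_positions
        d2 = ((pts[:, None] - u[None, :]) ** 2).sum(-1)
        p, e = np.unravel_index(np.argmin(d2), d2.shape)
        z = speckle12["grid"].z[0]
        expected = z / (4 * np.pi * (d2[p, e] + z**2))
        assert abs(g.matrix[0, p, e]) == pytest.approx(expected, rel=1e-9)

    def test_fourier_dc_column_is_one(self, probe12, speckle12):
        g = propagator("fourier", speckle12["grid"], probe12)
        k0 = np.argmin(np.hypot(g.channels[:, 0], g.channels[:, 1]))
        assert np.allclose(g.matrix[0, :, k0], 1.0)
        assert np.allclose(np.abs(g.matrix), 1.0)

    def test_transducer_phase_gradient_matches_ray_delay(self, probe12, speckle12):
        """d(arg G)/dz equals the ray-delay rate −2π f_c dτ/dz."""
        grid = speckle12["grid"]
        g = propagator("transducer", grid, probe12)
        p = grid.n_transverse // 2
        e = probe12.n_elements // 2
        pt = grid.transverse_points()[p]
        tau = lambda z: time_of_flight_transducer(
            [probe12.element_positions[e]], [[pt[0], pt[1], z]],
            probe12.reference_sound_speed,
        )
        dtau = float(tau(grid.z[1]) - tau(grid.z[0]))
        # compare modulo 2*pi (the conjugated-propagation phase convention)
        mismatch = np.angle(
            (g.matrix[1, p, e] / g.matrix[0, p, e])
            * np.exp(+2j * np.pi * 3.0 * dtau)
        )
        assert abs(mismatch) < 1e-6


class TestDistortion:
    def test_zero_matrix_gives_zero_distortion(self, probe12, speckle12):
        f = speckle12["focused"].with_data(np.zeros_like(speckle12["focused"].data))
        g = propagator("transducer", f.grid, probe12)
        d = distortion(f, g, "out")
        assert np.all(d.data == 0)

    def test_unaberrated_guide_star_phase_flat(self, probe12):
        med = umi.point_target_medium((0.0, 0.0, 20.0))
        raw = umi.simulate_acquisition(probe12, med, seed=1)
        grid = umi.ImagingGrid.regular((-3, 3), (-3, 3), (19.5, 20.5), pitch=0.5)
        f = umi.beamform_focused_matrix(raw, grid, drho_max=8.0)
        g = propagator("transducer", grid, probe12)
        d = distortion(f, g, "out")
        p0 = grid.n_transverse // 2
        row = d.data[1, p0]
        w = np.abs(row)
        resid = np.angle(row * np.exp(-1j * np.angle(np.sum(row))))
        assert np.sqrt(np.average(resid**2, weights=w**2)) < 0.2

    def test_guide_star_reveals_screen(self, guide_star12):
        """arg D(u, r) tracks the screen phase near the bright target."""
        geo = guide_star12["geometry"]
        f = guide_star12["focused"]
        g = propagator("transducer", f.grid, geo)
        d = distortion(f, g, "out")
        p0 = f.grid.n_transverse // 2
        row = d.data[1, p0]
        truth = np.exp(1j * guide_star12["screen"].screen_phase)
        cc = np.abs(np.sum(row * np.conj(truth)) / np.sum(np.abs(row)))
        assert cc > 0.75

    def test_sides_transpose_consistent(self, probe12, speckle12):
        f = speckle12["focused"]
        g = propagator("transducer", f.grid, probe12)
        d_in = distortion(f, g, "in")
        d_out_t = distortion(f.transpose(), g, "out")
        assert np.allclose(d_in.data, d_out_t.data)


class TestLocalCorrelation:
    def test_single_point_rank_one(self, probe12, speckle12):
        f = speckle12["focused"]
        g = propagator("transducer", f.grid, probe12)
        d = distortion(f, g, "out")
        # a 2-point patch, checked against the explicit outer-product sum
        c, n = local_correlation(d, np.array([0.0, 0.0, 18.5]), 1.1, 0.6)
        rows = []
        pts = f.grid.transverse_points()
        sel = (np.abs(pts[:, 0]) < 0.55) & (np.abs(pts[:, 1]) < 0.55)
        expect = sum(np.outer(r, r.conj()) for r in d.data[0][sel]) / sel.sum()
        assert np.allclose(c, expect)

    def test_hermitian_nonneg_diagonal(self, probe12, speckle12):
        f = speckle12["focused"]
        g = propagator("transducer", f.grid, probe12)
        d = distortion(f, g, "out")
        c, _ = local_correlation(d, np.array([0.0, 0.0, 20.0]), 4.0, 2.0)
        assert np.allclose(c, c.conj().T)
        assert np.all(c.diagonal().real >= 0)

    def test_empty_patch_rejected(self, probe12, speckle12):
        f = speckle12["focused"]
        g = propagator("transducer", f.grid, probe12)
        d = distortion(f, g, "out")
        with pytest.raises(ValueError):
            local_correlation(d, np.array([100.0, 100.0, 20.0]), 1.0, 1.0)


class TestIPR:
    def test_rank_one_exact(self):
        rng = np.random.default_rng(5)
        t = np.exp(1j * rng.uniform(-np.pi, np.pi, 64))
        c = np.outer(t, t.conj())
        est, n_iter, conv = iterative_phase_reversal(c)
        assert conv and n_iter <= 2
        assert circ_corr(est, t) == pytest.approx(1.0, abs=1e-9)

    def test_identity_returns_flat(self):
        est, n_iter, conv = iterative_phase_reversal(np.eye(32, dtype=complex))
        assert conv
        assert np.allclose(est, 1.0)

    def test_zero_matrix_flagged(self):
        est, _, conv = iterative_phase_reversal(np.zeros((16, 16), complex))
        assert not conv
        assert np.allclose(est, 1.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_fixed_point_residual(self, seed):
        c, _ = speckle_like_correlation(96, seed, noise=0.3)
        est, _, conv = iterative_phase_reversal(c, tol=1e-4, max_iter=500)
        assert conv
        resid = np.exp(1j * np.angle(c @ est))
        assert np.max(np.abs(np.angle(resid * np.conj(est)))) <= 1e-4

    def test_unit_modulus_always(self):
        c, _ = speckle_like_correlation(48, 7, noise=1.0)
        est, _, _ = iterative_phase_reversal(c)
        assert np.allclose(np.abs(est), 1.0)

    @pytest.mark.parametrize("seed", [3, 4, 5, 6])
    def test_agrees_with_svd_oracle(self, seed):
        """IPR and the leading eigenvector extract the same phase law."""
        c, t = speckle_like_correlation(128, seed, noise=0.2)
        est, _, _ = iterative_phase_reversal(c, tol=1e-5, max_iter=500)
        w, v = np.linalg.eigh(c)
        sv = np.exp(1j * np.angle(v[:, -1]))
        assert circ_corr(est, sv) >= 0.99

    def test_active_mask_respected(self):
        c, t = speckle_like_correlation(32, 9)
        active = np.ones(32, bool)
        active[::5] = False
        est, _, _ = iterative_phase_reversal(c, active=active)
        assert np.allclose(est[~active], 1.0)


class TestReciprocity:
    def test_equal_laws_give_one(self):
        t = np.exp(1j * np.linspace(0, 3, 50))
        p, bias = reciprocity_product(t, t)
        assert p == pytest.approx(1.0)
        assert bias == pytest.approx(0.0, abs=1e-12)

    def test_independent_random_laws_small(self):
        rng = np.random.default_rng(0)
        a = np.exp(1j * rng.uniform(-np.pi, np.pi, 1024))
        b = np.exp(1j * rng.uniform(-np.pi, np.pi, 1024))
        p, _ = reciprocity_product(a, b)
        assert p < 0.1

    def test_global_phase_invariance(self):
        rng = np.random.default_rng(1)
        a = np.exp(1j * rng.uniform(-np.pi, np.pi, 64))
        b = np.exp(1j * rng.uniform(-np.pi, np.pi, 64))
        p1, _ = reciprocity_product(a, b)
        p2, _ = reciprocity_product(a * np.exp(1j * 0.7), b)
        assert p1 == pytest.approx(p2, rel=1e-12)


class TestTiltRemoval:
    def test_pure_ramp_removed(self, probe12):
        pos = probe12.element_positions
        law = np.exp(1j * (0.8 * pos[:, 0] - 0.5 * pos[:, 1]))
        out = remove_tilt(law, pos, probe12.live)
        assert np.std(np.angle(out[probe12.live])) < 1e-6

    def test_structure_preserved(self, probe12):
        pos = probe12.element_positions
        rng = np.random.default_rng(2)
        base = np.exp(1j * 0.4 * np.sin(pos[:, 0] * 2.0))
        law = base * np.exp(1j * (0.3 * pos[:, 0] + 0.2))
        out = remove_tilt(law, pos, probe12.live)
        base_dt = remove_tilt(base, pos, probe12.live)
        assert circ_corr(out[probe12.live], base_dt[probe12.live]) > 0.999


class TestCorrectionOperator:
    def test_flat_law_identity_fourier(self, probe12, speckle12):
        f = speckle12["focused"]
        g = propagator("fourier", f.grid, probe12)
        flat = np.ones(g.n_channels, complex)
        out = apply_correction(f, flat, g, side="out")
        rel = np.abs(out.data - f.data).max() / np.abs(f.data).max()
        assert rel <= 1e-9

    def test_phase_composition_fourier(self, probe12, speckle12):
        # a full pair mask makes successive corrections compose exactly
        src = speckle12["focused"]
        f = umi.beamform.FocusedReflectionMatrix(
            grid=src.grid,
            data=src.data.copy(),
            drho_max=100.0,
            pair_mask=np.ones_like(src.pair_mask),
            coverage=src.coverage,
            geometry=src.geometry,
        )
        g = propagator("fourier", f.grid, probe12)
        rng = np.random.default_rng(3)
        t1 = np.exp(1j * rng.uniform(-1, 1, g.n_channels))
        t2 = np.exp(1j * rng.uniform(-1, 1, g.n_channels))
        a = apply_correction(apply_correction(f, t1, g, "out"), t2, g, "out")
        b = apply_correction(f, t1 * t2, g, "out")
        assert np.allclose(a.data, b.data, atol=1e-9 * np.abs(f.data).max())

    def test_truth_conjugation_raises_confocal_peak(self, guide_star12):
        """Compensating the true screen during beamforming restores focus."""
        raw = guide_star12["raw"]
        f = guide_star12["focused"]
        geo = guide_star12["geometry"]
        law = np.exp(1j * guide_star12["screen"].screen_phase)
        law_map = np.broadcast_to(
            law[:, None], (geo.n_elements, f.grid.n_transverse)
        )
        corr = umi.beamform_focused_matrix(
            raw, f.grid, drho_max=f.drho_max, law_in=law_map, law_out=law_map
        )
        peak = lambda m: np.abs(np.diagonal(m.data, axis1=1, axis2=2)).max()
        assert peak(corr) > 2.0 * peak(f)


class TestConfocalFilter:
    def test_diagonal_unchanged(self, speckle12):
        f = speckle12["focused"]
        out = confocal_filter(f, width=2.0)
        assert np.allclose(
            np.diagonal(out.data, axis1=1, axis2=2),
            np.diagonal(f.data, axis1=1, axis2=2),
        )

    def test_gaussian_attenuation_at_width(self, speckle12):
        f = speckle12["focused"]
        out = confocal_filter(f, width=1.0)
        pts = f.grid.transverse_points()
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        sel = np.isclose(d, 1.0) & (np.abs(f.data[0]) > 0)
        ratio = out.data[0][sel] / f.data[0][sel]
        assert np.allclose(ratio, np.exp(-0.5))

    def test_default_width_tracks_diffraction_limit(self, speckle12):
        out = confocal_filter(speckle12["focused"])
        assert "confocal_filter" in out.provenance[-1]


class TestSchedule:
    def test_growing_patches_rejected(self):
        with pytest.raises(ValueError):
            CorrectionSchedule(
                (
                    CorrectionStep(w_rho=8.0, w_z=3.0),
                    CorrectionStep(w_rho=10.0, w_z=3.0),
                )
            )

    def test_bad_threshold_rejected(self):
        with pytest.raises(ValueError):
            CorrectionSchedule(
                (
                    CorrectionStep(w_rho=8.0, w_z=3.0),
                    CorrectionStep(w_rho=8.0, w_z=3.0, threshold=1.5),
                )
            )


class TestMultiscale:
    def test_null_case_leaves_image_unchanged(self, probe12, speckle12_deep):
        """Flat true aberration: estimated laws flat, image change < 1%."""
        f = speckle12_deep["focused"]
        raw = speckle12_deep["raw"]
        sched = CorrectionSchedule(
            (CorrectionStep(n_patches=(1, 1), w_rho=9.0, w_z=8.0, threshold=0.5),)
        )
        res = run_multiscale(f, sched, probe12, raw=raw, n_subbands=6)
        est = res.history[0][0]
        live = probe12.live
        for law in (est.t_in, est.t_out):
            assert np.sqrt(np.mean(np.angle(law[live]) ** 2)) < 0.1
        img0 = umi.confocal_image(f)
        img1 = umi.confocal_image(res.corrected)
        assert np.abs(np.sqrt(img1) - np.sqrt(img0)).max() <= 0.01 * np.sqrt(img0).max()

    def test_unaccepted_first_step_raises(self, probe12, speckle12):
        sched = CorrectionSchedule(
            (CorrectionStep(n_patches=(1, 1), w_rho=9.0, w_z=4.0, threshold=1.0 - 1e-12),)
        )
        f = speckle12["focused"]
        noisy = f.with_data(
            f.data
            + (0.3 * np.abs(f.data).mean())
            * np.random.default_rng(0).standard_normal(f.data.shape)
        )
        with pytest.raises(ConvergenceError):
            run_multiscale(noisy, sched, probe12)

    def test_stitching_blends_overlapping_patches(self, probe12, speckle12):
        f = speckle12["focused"]
        ests, _ = (
            [],
            None,
        )
        from umi.aberration import TransmissionEstimate

        n_c = probe12.n_elements
        mk = lambda center, phase: TransmissionEstimate(
            center=np.array(center),
            t_in=np.exp(1j * phase) * np.ones(n_c),
            t_out=np.exp(1j * phase) * np.ones(n_c),
            p_inout=1.0,
            n_iter_in=1,
            n_iter_out=1,
            converged=True,
            accepted=True,
            n_points=10,
            w_rho=8.0,
            w_z=4.0,
        )
        # two overlapping patches with different constant laws
        ests = [mk([-2.0, 0.0, 20.0], 0.0), mk([2.0, 0.0, 20.0], np.pi / 2)]
        law = stitch_laws(ests, f.grid, "out")
        pts = f.grid.transverse_points()
        in_y = np.abs(pts[:, 1]) < 3.9  # strictly inside the patch windows
        only_left = (pts[:, 0] < -2.0) & (pts[:, 0] > -5.9) & in_y
        overlap = (np.abs(pts[:, 0]) < 1.9) & in_y
        assert np.allclose(np.angle(law[4][only_left]), 0.0)
        # blended region carries the circular mean of the two phases
        assert np.allclose(np.angle(law[4][overlap]), np.pi / 4, atol=1e-6)


class TestScheduleFactories:
    def test_surface_layer_schedule(self):
        s = CorrectionSchedule.surface_layer()
        assert [st.n_patches for st in s.steps] == [(1, 1), (2, 2), (4, 4)]
        assert [st.w_rho for st in s.steps] == [16.0, 12.0, 8.0]
        assert all(st.w_z == 3.0 and st.basis == "transducer" for st in s.steps)

    def test_layered_medium_schedule(self):
        s = CorrectionSchedule.layered_medium()
        assert len(s.steps) == 6
        assert s.steps[0].n_patches == (1, 1) and s.steps[-1].n_patches == (6, 6)
        assert all(
            st.w_z == 5.5 and st.basis == "fourier" and st.confocal_filter
            for st in s.steps
        )
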