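"""Synthetic acquisition generator with a known ground-truth aberrator.

The generator produces raw reflection matrices in complex baseband (IQ)
form under the single-scattering (Born) approximation: each trace is a sum
over point scatterers of band-limited echoes, seen through a thin phase
screen at the probe plane.  Two further components can be injected to
emulate experimental nuisance terms:

* a *multiple-scattering surrogate* — a time-resolved random matrix that is
  exactly symmetric under element exchange (reciprocal), band-limited by
  the pulse and decaying exponentially in time;
* *electronic noise* — iid complex Gaussian samples, non-reciprocal.

These two terms reproduce the symmetry structure that downstream
estimators exploit (the anti-symmetry rate beta), not the physics of
multiple scattering itself.

Units: mm / µs / MHz; sound speed in mm/µs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from umi import _kernels
from umi.geometry import ProbeGeometry

__all__ = [
    "PulseSpec",
    "AberratorModel",
    "MediumModel",
    "RawReflectionMatrix",
    "make_phase_screen",
    "sample_speckle_medium",
    "point_target_medium",
    "plane_wave_delays",
    "simulate_acquisition",
    "calibrated_mixture",
]


@dataclass(frozen=True)
class PulseSpec:
    """Gaussian-envelope tone burst at the probe centre frequency.

    The −6 dB fractional bandwidth sets the envelope width: a Gaussian
    envelope ``exp(-t^2 / (2 sigma_t^2))`` has a −6 dB spectral full width
    ``Δf = sqrt(2 ln 2) / (pi sigma_t)``.
    """

    central_frequency: float = 3.0  # MHz
    fractional_bandwidth: float = 0.8
    support_sigmas: float = 4.0  # envelope truncation

    @property
    def bandwidth(self) -> float:
        return self.fractional_bandwidth * self.central_frequency

    @property
    def sigma_t(self) -> float:
        """Envelope standard deviation in µs."""
        return np.sqrt(2.0 * np.log(2.0)) / (np.pi * self.bandwidth)

    @property
    def half_support(self) -> float:
        """Half duration (µs) outside which the envelope is treated as 0."""
        return self.support_sigmas * self.sigma_t

    def envelope(self, t: np.ndarray) -> np.ndarray:
        return np.exp(-np.asarray(t) ** 2 / (2.0 * self.sigma_t**2))


@dataclass(frozen=True)
class AberratorModel:
    """Thin phase screen at the probe plane plus nuisance-term weights.

    ``screen_phase`` holds the phase phi(u) in radians per element; the
    screen transmittance is ``T(u) = exp(i phi(u))`` (unit modulus: the
    screen is lossless and acts identically on every propagation angle).
    ``rms_delay`` is the equivalent time-delay spread in ns:
    ``rms(phi) = 2 pi f_c tau_rms``.
    """

    screen_phase: np.ndarray  # (n_el,) radians
    correlation_length: float  # mm
    rms_delay: float  # ns
    ms_background_weight: float = 0.0
    noise_weight: float = 0.0
    ms_decay: float = 10.0  # µs, decay constant of the MS surrogate envelope

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "screen_phase", np.asarray(self.screen_phase, dtype=float)
        )

    @property
    def transmittance(self) -> np.ndarray:
        return np.exp(1j * self.screen_phase)

    def with_weights(self, ms: float, noise: float) -> "AberratorModel":
        return replace(self, ms_background_weight=ms, noise_weight=noise)


@dataclass(frozen=True)
class MediumModel:
    """Point-scatterer medium: positions (mm) and complex reflectivities."""

    scatterer_positions: np.ndarray  # (n, 3)
    reflectivities: np.ndarray  # (n,) complex
    bounds: tuple[tuple[float, float], tuple[float, float], tuple[float, float]]
    speckle_density: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        pos = np.atleast_2d(np.asarray(self.scatterer_positions, dtype=float))
        gam = np.atleast_1d(np.asarray(self.reflectivities, dtype=complex))
        if pos.shape != (len(gam), 3):
            raise ValueError("positions must be (n, 3) matching reflectivities")
        for k, (lo, hi) in enumerate(self.bounds):
            if pos.size and (pos[:, k].min() < lo or pos[:, k].max() > hi):
                raise ValueError("scatterer outside the stated field of view")
        object.__setattr__(self, "scatterer_positions", pos)
        object.__setattr__(self, "reflectivities", gam)

    @property
    def n_scatterers(self) -> int:
        return len(self.reflectivities)

    def combine(self, other: "MediumModel") -> "MediumModel":
        """Union of two scatterer sets (Born linearity fixture)."""
        b = tuple(
            (min(a[0], c[0]), max(a[1], c[1]))
            for a, c in zip(self.bounds, other.bounds)
        )
        return MediumModel(
            np.vstack([self.scatterer_positions, other.scatterer_positions]),
            np.concatenate([self.reflectivities, other.reflectivities]),
            b,  # type: ignore[arg-type]
            self.speckle_density,
            self.rng_seed,
        )


@dataclass
class RawReflectionMatrix:
    """Complex-baseband channel data over an illumination basis.

    ``data[i_in, u_out, k]`` is the IQ sample at time ``t0 + k / f_s`` of
    the trace for illumination ``i_in`` (a transmit element, or a plane
    wave) received on element ``u_out``.
    """

    data: np.ndarray  # (n_in, n_out, n_t) complex64
    t0: float  # µs
    dt: float  # µs  (1 / f_s)
    demodulation_frequency: float  # MHz
    basis: str  # "transducer" | "planewave"
    geometry: ProbeGeometry
    angles_deg: np.ndarray | None = None  # (n_in, 2) for the plane-wave basis
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.basis not in ("transducer", "planewave"):
            raise ValueError(f"unknown illumination basis {self.basis!r}")
        if self.basis == "planewave" and self.angles_deg is None:
            raise ValueError("plane-wave basis requires an angle table")
        if not np.all(np.isfinite(self.data.view(np.float32) if self.data.dtype == np.complex64 else self.data)):
            raise ValueError("raw data contains non-finite values")

    @property
    def n_illuminations(self) -> int:
        return self.data.shape[0]

    @property
    def n_receivers(self) -> int:
        return self.data.shape[1]

    @property
    def time_axis(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.data.shape[2])

    def __add__(self, other: "RawReflectionMatrix") -> "RawReflectionMatrix":
        if (
            self.data.shape != other.data.shape
            or self.t0 != other.t0
            or self.dt != other.dt
            or self.basis != other.basis
        ):
            raise ValueError("incompatible acquisitions")
        return replace(self, data=self.data + other.data, truth={})

    def scaled(self, factor: float) -> "RawReflectionMatrix":
        return replace(self, data=(self.data * factor).astype(self.data.dtype))


# ---------------------------------------------------------------------------
# ground-truth building blocks


def make_phase_screen(
    geometry: ProbeGeometry,
    correlation_length: float,
    rms_delay: float,
    seed: int = 0,
    ms_background_weight: float = 0.0,
    noise_weight: float = 0.0,
) -> AberratorModel:
    """Smooth random phase screen with a prescribed rms time-delay spread.

    White Gaussian noise drawn per element is smoothed with a Gaussian
    kernel of width ``sigma = correlation_length / 2`` (so the screen
    autocorrelation falls to 1/e at a lag of ``correlation_length``), the
    mean over live elements is removed, and the result is rescaled so that
    ``rms(phi) = 2 pi f_c tau_rms`` exactly.  ``rms_delay`` is in ns.
    """
    if correlation_length < geometry.pitch:
        raise ValueError(
            "correlation_length below the element pitch is unresolvable"
        )
    if rms_delay < 0:
        raise ValueError("rms_delay must be non-negative")
    n = geometry.n_elements
    live = geometry.live
    phi = np.zeros(n)
    if rms_delay > 0:
        rng = np.random.default_rng(seed)
        white = rng.standard_normal(n)
        pos = geometry.element_positions
        d2 = ((pos[:, None, :] - pos[None, :, :]) ** 2).sum(-1)
        sig = correlation_length / 2.0
        kern = np.exp(-d2 / (2.0 * sig**2))
        phi = kern @ white
        phi -= phi[live].mean()
        target = 2.0 * np.pi * geometry.central_frequency * rms_delay * 1e-3
        cur = np.sqrt(np.mean(phi[live] ** 2))
        phi = phi * (target / cur) if cur > 0 else phi
    phi[~live] = 0.0
    return AberratorModel(
        screen_phase=phi,
        correlation_length=correlation_length,
        rms_delay=rms_delay,
        ms_background_weight=ms_background_weight,
        noise_weight=noise_weight,
    )


def sample_speckle_medium(
    bounds: tuple[tuple[float, float], ...],
    density: float,
    seed: int = 0,
    geometry: ProbeGeometry | None = None,
    cell_volume: float | None = None,
) -> MediumModel:
    """Uniform random sub-resolution scatterers with circular-Gaussian
    reflectivities (fully developed speckle).

    ``density`` is the expected number of scatterers per resolution cell;
    the cell volume defaults to ``(lambda_c / 2)^3`` computed from
    ``geometry``.  The scatterer count is Poisson distributed with mean
    ``density * volume / cell_volume``.  Because the reflectivities are
    circular Gaussian, any linear functional of the medium is itself
    circular Gaussian, so speckle statistics are exact at any density.
    """
    if density <= 0:
        raise ValueError("density must be positive")
    bounds = tuple((float(lo), float(hi)) for lo, hi in bounds)
    vol = float(np.prod([hi - lo for lo, hi in bounds]))
    if vol <= 0:
        raise ValueError("empty field-of-view bounds")
    if cell_volume is None:
        if geometry is None:
            raise ValueError("pass geometry or cell_volume to set the cell size")
        cell_volume = (geometry.wavelength / 2.0) ** 3
    rng = np.random.default_rng(seed)
    n = int(rng.poisson(density * vol / cell_volume))
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    pos = lo + (hi - lo) * rng.random((n, 3))
    gamma = (rng.standard_normal(n) + 1j * rng.standard_normal(n)) / np.sqrt(2.0)
    return MediumModel(pos, gamma, bounds, speckle_density=density, rng_seed=seed)


def point_target_medium(
    position: tuple[float, float, float], reflectivity: complex = 1.0 + 0j
) -> MediumModel:
    """Single bright scatterer (guide-star fixture)."""
    p = np.asarray(position, dtype=float)
    bounds = tuple((p[k] - 1e-6, p[k] + 1e-6) for k in range(3))
    return MediumModel(p[None, :], np.array([reflectivity]), bounds)  # type: ignore[arg-type]


def plane_wave_delays(theta_deg: tuple[float, float], geometry: ProbeGeometry) -> np.ndarray:
    """Per-element transmit delays (µs) steering a plane wave.

    ``dtau(theta, u) = (u_x sin theta_x + u_y sin theta_y) / c_0``.
    """
    tx, ty = (np.deg2rad(a) for a in theta_deg)
    if abs(theta_deg[0]) >= 90 or abs(theta_deg[1]) >= 90:
        raise ValueError("steering angles must satisfy |theta| < 90 degrees")
    u = geometry.element_positions
    return (u[:, 0] * np.sin(tx) + u[:, 1] * np.sin(ty)) / geometry.reference_sound_speed


# ---------------------------------------------------------------------------
# acquisition


def _element_factors(
    geometry: ProbeGeometry, medium: MediumModel, screen: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """One-way delays and complex element factors for every (element, scatterer).

    The factor bundles the screen transmittance, the hard directivity-cone
    apodization, the obliquity-weighted spherical spreading
    ``z / (4 pi d^2)`` and the baseband carrier phase
    ``exp(-2 i pi f_c tau)``.  Dead elements get a zero factor.
    """
    u = geometry.element_positions
    r = medium.scatterer_positions
    c0 = geometry.reference_sound_speed
    dx = u[:, 0, None] - r[None, :, 0]
    dy = u[:, 1, None] - r[None, :, 1]
    z = r[None, :, 2]
    d = np.sqrt(dx**2 + dy**2 + z**2)
    tau = d / c0
    cone = (z / d) >= np.cos(np.deg2rad(geometry.directivity_limit))
    amp = np.where(cone, z / (4.0 * np.pi * d**2), 0.0)
    amp[geometry.dead_element_mask, :] = 0.0
    cfac = amp * screen[:, None] * np.exp(
        -2j * np.pi * geometry.central_frequency * tau
    )
    return tau, cfac


def _time_axis(
    geometry: ProbeGeometry,
    medium: MediumModel,
    pulse: PulseSpec,
    t_span: tuple[float, float] | None,
) -> tuple[float, int]:
    if t_span is not None:
        t0, t1 = t_span
    else:
        z_lo = medium.bounds[2][0]
        ap = geometry.aperture
        span = [max(abs(b) for b in medium.bounds[k]) + ap[k] / 2 for k in (0, 1)]
        z_hi = medium.bounds[2][1]
        d_max = np.sqrt(span[0] ** 2 + span[1] ** 2 + z_hi**2)
        c0 = geometry.reference_sound_speed
        t0 = max(0.0, 2.0 * z_lo / c0 - pulse.half_support - 4.0)
        t1 = 2.0 * d_max / c0 + pulse.half_support + 4.0
    dt = 1.0 / geometry.sampling_frequency
    if t_span is not None:
        n_t = int(round((t1 - t0) / dt)) + 1
    else:
        n_t = int(np.ceil((t1 - t0) / dt)) + 1
    return float(t0), n_t


def _ms_surrogate(
    shape: tuple[int, int, int],
    t0: float,
    dt: float,
    onset: float,
    decay: float,
    pulse: PulseSpec,
    rng: np.random.Generator,
    symmetric: bool,
) -> np.ndarray:
    """Unit-rms reciprocal multiple-scattering surrogate.

    A complex Gaussian random matrix, symmetrized over the element pair,
    band-limited along time by the pulse envelope and weighted by a decaying
    exponential starting at ``onset``.
    """
    w = (
        rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
    ) / np.sqrt(2.0)
    if symmetric:
        w = (w + w.swapaxes(0, 1)) / np.sqrt(2.0)
    n_k = int(np.ceil(3 * pulse.sigma_t / dt))
    tk = dt * np.arange(-n_k, n_k + 1)
    kern = pulse.envelope(tk)
    kern /= np.sqrt((kern**2).sum())
    from scipy.ndimage import convolve1d

    w = convolve1d(w.real, kern, axis=-1, mode="constant") + 1j * convolve1d(
        w.imag, kern, axis=-1, mode="constant"
    )
    t = t0 + dt * np.arange(shape[2])
    env = np.where(t >= onset, np.exp(-(t - onset) / decay), 0.0)
    w *= env
    rms = np.sqrt(np.mean(np.abs(w) ** 2))
    return w / rms if rms > 0 else w


def simulate_acquisition(
    geometry: ProbeGeometry,
    medium: MediumModel,
    aberrator: AberratorModel | None = None,
    basis: str = "transducer",
    pulse: PulseSpec | None = None,
    seed: int = 0,
    angles_deg: np.ndarray | None = None,
    t_span: tuple[float, float] | None = None,
) -> RawReflectionMatrix:
    """Simulate a raw reflection matrix under the Born approximation.

    The single-scattering part of each trace is
    ``sum_s gamma_s T(u_in) T(u_out) g_in g_out env(t - tau_in - tau_out)
    exp(-2 i pi f_c (tau_in + tau_out))`` with ``g`` the obliquity-weighted
    spherical spreading inside the directivity cone.  In the plane-wave
    basis the transmit leg is the coherent per-element sum evaluated at the
    centre frequency, with the pulse envelope pinned at the geometric
    plane-wave arrival time (narrowband thin-screen approximation).

    The multiple-scattering surrogate and noise components are scaled
    relative to the per-sample rms of the single-scattering part;
    :func:`calibrated_mixture` offers a calibrated alternative.  The
    surrogate requires the transducer basis (its reciprocity bookkeeping is
    defined on element pairs).
    """
    pulse = pulse or PulseSpec(
        geometry.central_frequency, geometry.fractional_bandwidth
    )
    if aberrator is None:
        aberrator = AberratorModel(
            np.zeros(geometry.n_elements), geometry.pitch, 0.0
        )
    if basis == "planewave" and aberrator.ms_background_weight > 0:
        raise ValueError(
            "the multiple-scattering surrogate is defined in the transducer basis"
        )
    screen = aberrator.transmittance
    t0, n_t = _time_axis(geometry, medium, pulse, t_span)
    dt = 1.0 / geometry.sampling_frequency
    fc = geometry.central_frequency
    n_support = int(np.ceil(pulse.half_support / dt))

    if basis == "transducer":
        n_in = geometry.n_elements
        shape = (n_in, geometry.n_elements, n_t)
        sig = np.zeros(shape, dtype=np.complex128)
        if medium.n_scatterers:
            tau, cfac = _element_factors(geometry, medium, screen)
            _kernels.accumulate_born_transducer(
                sig,
                medium.reflectivities.astype(np.complex128),
                tau,
                cfac,
                t0,
                dt,
                pulse.sigma_t,
                n_support,
            )
        angles = None
    elif basis == "planewave":
        if angles_deg is None:
            raise ValueError("plane-wave basis requires angles_deg")
        angles = np.atleast_2d(np.asarray(angles_deg, dtype=float))
        n_in = len(angles)
        shape = (n_in, geometry.n_elements, n_t)
        sig = np.zeros(shape, dtype=np.complex128)
        if medium.n_scatterers:
            tau, cfac = _element_factors(geometry, medium, screen)
            r = medium.scatterer_positions
            c0 = geometry.reference_sound_speed
            sin_t = np.sin(np.deg2rad(angles))
            cos_t = np.sqrt(1.0 - (sin_t**2).sum(axis=1))
            tau_pw = (
                r[None, :, 0] * sin_t[:, 0, None]
                + r[None, :, 1] * sin_t[:, 1, None]
                + r[None, :, 2] * cos_t[:, None]
            ) / c0
            # transmit leg: coherent element sum at f_c, envelope pinned at tau_pw
            dtau_el = (
                geometry.element_positions[:, 0, None] * sin_t[None, :, 0]
                + geometry.element_positions[:, 1, None] * sin_t[None, :, 1]
            ) / c0  # (n_el, n_a)
            # A[a, s] = sum_u cfac[u, s] * exp(-2i pi f_c (dtau[u, a] - tau_pw[a, s]))
            ph_el = np.exp(-2j * np.pi * fc * dtau_el)  # (n_el, n_a)
            # cfac already carries exp(-2i pi f_c tau(u, s)); referencing the
            # sum to the geometric arrival tau_pw leaves the net transmit
            # factor A_tx * exp(-2i pi f_c tau_pw).
            a_tx = (
                np.einsum("us,ua->as", cfac, ph_el)
                * np.exp(+2j * np.pi * fc * tau_pw)
                / geometry.n_live
            )
            b = medium.reflectivities[None, :] * a_tx * np.exp(-2j * np.pi * fc * tau_pw)
            _kernels.accumulate_born_planewave(
                sig, b, tau_pw, cfac, tau, t0, dt, pulse.sigma_t, n_support
            )
    else:
        raise ValueError(f"unknown basis {basis!r}")

    truth: dict = {
        "screen_phase": aberrator.screen_phase.copy(),
        "scatterer_positions": medium.scatterer_positions.copy(),
        "reflectivities": medium.reflectivities.copy(),
        "ms_weight": aberrator.ms_background_weight,
        "noise_weight": aberrator.noise_weight,
    }
    rng = np.random.default_rng(seed)
    sig_rms = np.sqrt(np.mean(np.abs(sig) ** 2)) or 1.0
    if aberrator.ms_background_weight > 0:
        onset = 2.0 * medium.bounds[2][0] / geometry.reference_sound_speed
        ms = _ms_surrogate(
            shape, t0, dt, onset, aberrator.ms_decay, pulse, rng, symmetric=True
        )
        sig = sig + aberrator.ms_background_weight * sig_rms * ms
    if aberrator.noise_weight > 0:
        noise = (
            rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
        ) / np.sqrt(2.0)
        sig = sig + aberrator.noise_weight * sig_rms * noise
    out = sig.astype(np.complex64)
    if not np.all(np.isfinite(out.view(np.float32))):
        raise FloatingPointError("simulation produced non-finite samples")
    return RawReflectionMatrix(
        data=out,
        t0=t0,
        dt=dt,
        demodulation_frequency=fc,
        basis=basis,
        geometry=geometry,
        angles_deg=angles,
        truth=truth,
    )


def calibrated_mixture(
    geometry: ProbeGeometry,
    medium: MediumModel,
    aberrator: AberratorModel,
    grid,
    alpha_ms: float,
    alpha_noise: float,
    seed: int = 0,
    pulse: PulseSpec | None = None,
    drho_max: float = 10.0,
    descan_factor: float = 6.0,
) -> RawReflectionMatrix:
    """Acquisition whose nuisance components are calibrated in the focused domain.

    The raw-data weights of :func:`simulate_acquisition` fix energy ratios
    in the channel domain, but the scattering-rate decomposition is defined
    on the *normalized RPSF*: ``alpha_B`` is the de-scanned background
    level relative to the confocal peak.  This helper therefore simulates
    the three components separately, beamforms each on ``grid`` with the
    full aperture (no directivity-cone apodization, so the noise plateau
    is spatially uniform), measures each component's confocal level and
    de-scanned background level, and solves for the surrogate and noise
    scales that make the mixture's background fractions equal ``alpha_ms``
    and ``alpha_noise``.  The symmetric surrogate's own confocal
    enhancement (the coherent doubling a reciprocal random matrix shows on
    the monostatic diagonal) is part of the accounting.  The returned
    acquisition is their sum; recovering the rates from it is a genuine
    end-to-end estimation problem.
    """
    from umi.beamform import beamform_focused_matrix
    from umi.metrics import PatchSpec, diffraction_limit, local_rpsf

    if alpha_ms <= 0 or alpha_noise <= 0 or alpha_ms + alpha_noise >= 1:
        raise ValueError("component weights must be > 0 and sum below 1")
    pulse = pulse or PulseSpec(
        geometry.central_frequency, geometry.fractional_bandwidth
    )
    base = simulate_acquisition(
        geometry, medium, aberrator.with_weights(0.0, 0.0), "transducer", pulse, seed
    )
    t_span = (base.t0, base.t0 + base.dt * (base.data.shape[2] - 1))
    empty = MediumModel(
        np.zeros((0, 3)), np.zeros(0, dtype=complex), medium.bounds
    )
    rng = np.random.default_rng(seed)
    sub = rng.integers(0, 2**31 - 1, size=2)
    ms_only = simulate_acquisition(
        geometry,
        empty,
        aberrator.with_weights(1.0, 0.0),
        "transducer",
        pulse,
        int(sub[0]),
        t_span=t_span,
    )
    noise_only = simulate_acquisition(
        geometry,
        empty,
        aberrator.with_weights(0.0, 1.0),
        "transducer",
        pulse,
        int(sub[1]),
        t_span=t_span,
    )

    rho0 = float(
        np.mean(
            [
                diffraction_limit(
                    z, geometry.wavelength, float(np.mean(geometry.aperture))
                )
                for z in grid.z
            ]
        )
    )
    center = np.array(
        [
            [
                (grid.x[0] + grid.x[-1]) / 2,
                (grid.y[0] + grid.y[-1]) / 2,
                (grid.z[0] + grid.z[-1]) / 2,
            ]
        ]
    )
    span_z = grid.z[-1] - grid.z[0] + (grid.z[1] - grid.z[0] if grid.nz > 1 else 1.0)
    patch = PatchSpec(
        center,
        w_rho=(grid.x[-1] - grid.x[0]) / 2.0,
        w_z=span_z,
    )

    def levels(raw):
        f = beamform_focused_matrix(
            raw, grid, drho_max=drho_max, apodization="none"
        )
        rm = local_rpsf(f, patch)
        prof = rm.rpsf[0]
        a = int(np.argmin(np.abs(rm.offsets_y)))
        b = int(np.argmin(np.abs(rm.offsets_x)))
        rr = np.hypot(rm.offsets_x[None, :], rm.offsets_y[:, None])
        annulus = (rr > descan_factor * rho0) & (rr <= drho_max) & np.isfinite(prof)
        if not annulus.any():
            raise ValueError(
                "de-scanned annulus is empty: enlarge drho_max or image shallower"
            )
        return float(prof[a, b]), float(np.median(prof[annulus]))

    peak_ss, bg_ss = levels(base)
    peak_ms, bg_ms = levels(ms_only)
    peak_n, bg_n = levels(noise_only)
    r_m = peak_ms / bg_ms  # confocal enhancement of the reciprocal surrogate
    r_n = peak_n / bg_n

    alpha_b = alpha_ms + alpha_noise
    f_n = alpha_noise / alpha_b
    denom = 1.0 - alpha_b * ((1.0 - f_n) * r_m + f_n * r_n)
    if denom <= 0:
        raise ValueError(
            "requested background fraction is unreachable: the nuisance "
            "components' confocal enhancement exceeds the budget"
        )
    bg_target = alpha_b * (peak_ss - bg_ss * r_m) / denom
    y = f_n * bg_target  # noise plateau target
    x = bg_target * (1.0 - f_n) - bg_ss  # surrogate plateau target
    if x <= 0 or y <= 0:
        raise ValueError(
            "single-scattering background already exceeds the requested "
            "multiple-scattering level; increase alpha_ms or shrink the medium"
        )
    s_ms = np.sqrt(x / bg_ms)
    s_n = np.sqrt(y / bg_n)
    out = base + ms_only.scaled(s_ms) + noise_only.scaled(s_n)
    out.truth = {
        **base.truth,
        "ms_weight": alpha_ms,
        "noise_weight": alpha_noise,
        "ms_scale": float(s_ms),
        "noise_scale": float(s_n),
        "apodization": "none",
    }
    return out
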