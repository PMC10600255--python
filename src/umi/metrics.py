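"""Local focusing quality: RPSF maps, resolution, contrast, scattering rates.

In the speckle regime the local average of the de-scanned intensity — the
reflection point spread function (RPSF) — behaves as the incoherent
convolution of the input and output point spread functions, so its width
and background level quantify the focusing quality at every point of the
volume without a guide star.  The normalized RPSF decomposes into a
confocal peak (single scattering, rate ``alpha_S``), a diffuse halo
(multiple scattering, ``alpha_M``) and a flat plateau (electronic noise,
``alpha_N``).  Multiple scattering is reciprocal and noise is not, so the
degree of anti-symmetry ``beta`` of the focused matrix on its de-scanned
support splits the incoherent background between the two.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from umi.beamform import CommonMidpointField, FocusedReflectionMatrix, to_common_midpoint

__all__ = [
    "SHALLOW_LAYER_WINDOW",
    "LAYERED_MEDIUM_WINDOW",
    "DEPTH_PROFILE_WINDOW",
    "PatchSpec",
    "RPSFMap",
    "ScatteringRates",
    "diffraction_limit",
    "local_rpsf",
    "resolution_3db",
    "decompose_rpsf",
    "antisymmetry_rate",
    "scattering_rates",
]


# standard RPSF window presets (w_rho, w_z) in mm: fine windows for mapping
# a shallow aberrating layer, wider ones for layered media, and a laterally
# wide window for rate-vs-depth profiles
SHALLOW_LAYER_WINDOW = (3.2, 3.0)
LAYERED_MEDIUM_WINDOW = (4.0, 5.5)
DEPTH_PROFILE_WINDOW = (20.0, 5.5)


@dataclass(frozen=True)
class PatchSpec:
    """Box windows over which local averages are taken.

    ``centers`` is (n, 3) in mm; ``w_rho`` and ``w_z`` are the transverse
    and axial full extents.  A point belongs to the window when
    ``|x - x_p| < w_rho / 2``, ``|y - y_p| < w_rho / 2`` and
    ``|z - z_p| < w_z / 2``.
    """

    centers: np.ndarray
    w_rho: float
    w_z: float

    def __post_init__(self) -> None:
        c = np.atleast_2d(np.asarray(self.centers, dtype=float))
        if c.shape[1] != 3:
            raise ValueError("centers must be (n, 3)")
        if self.w_rho <= 0 or self.w_z <= 0:
            raise ValueError("window extents must be positive")
        object.__setattr__(self, "centers", c)

    @property
    def n_patches(self) -> int:
        return len(self.centers)

    @classmethod
    def single(cls, grid, w_z: float | None = None) -> "PatchSpec":
        """One window covering the whole grid."""
        cx = (grid.x[0] + grid.x[-1]) / 2
        cy = (grid.y[0] + grid.y[-1]) / 2
        cz = (grid.z[0] + grid.z[-1]) / 2
        w_rho = max(grid.x[-1] - grid.x[0], grid.y[-1] - grid.y[0]) + grid.pitch
        wz = w_z or (grid.z[-1] - grid.z[0] + grid.pitch)
        return cls(np.array([[cx, cy, cz]]), w_rho, wz)

    @classmethod
    def tile(
        cls,
        grid,
        n_transverse: tuple[int, int],
        w_rho: float,
        w_z: float,
        overlap: float = 0.5,
    ) -> "PatchSpec":
        """Overlapping patch grid: ``n_transverse = (kx, ky)`` patches per
        axis, axial centres stepped by ``w_z * (1 - overlap)``."""
        kx, ky = n_transverse

        def centers_1d(lo, hi, k, w):
            if k == 1:
                return np.array([(lo + hi) / 2.0])
            return np.linspace(lo + w / 2, hi - w / 2, k)

        cx = centers_1d(grid.x[0], grid.x[-1], kx, min(w_rho, grid.x[-1] - grid.x[0]))
        cy = centers_1d(grid.y[0], grid.y[-1], ky, min(w_rho, grid.y[-1] - grid.y[0]))
        step = max(w_z * (1.0 - overlap), 1e-9)
        span_z = grid.z[-1] - grid.z[0]
        n_z = max(1, int(np.floor(span_z / step)) + 1) if span_z > w_z else 1
        cz = (
            np.array([(grid.z[0] + grid.z[-1]) / 2.0])
            if n_z == 1
            else np.linspace(grid.z[0] + w_z / 2, grid.z[-1] - w_z / 2, n_z)
        )
        centers = np.array(
            [[x, y, z] for z in cz for y in cy for x in cx], dtype=float
        )
        return cls(centers, w_rho, w_z)

    def member_depths(self, z_axis: np.ndarray, p: int) -> np.ndarray:
        return np.abs(z_axis - self.centers[p, 2]) < self.w_z / 2


@dataclass
class RPSFMap:
    """Patchwise de-scanned intensity profiles and derived metrics."""

    rpsf: np.ndarray  # (n_patches, n_oy, n_ox) mean intensity
    offsets_x: np.ndarray
    offsets_y: np.ndarray
    patches: PatchSpec
    n_midpoints: np.ndarray  # (n_patches,) midpoints averaged at Δρ = 0
    low_confidence: np.ndarray  # (n_patches,) bool

    def amplitude(self, p: int) -> np.ndarray:
        """RPSF in amplitude (sqrt of intensity), as usually displayed."""
        return np.sqrt(self.rpsf[p])

    def normalized(self, p: int) -> np.ndarray:
        """Profile normalized to 1 at Δρ = 0 (canonical for decomposition)."""
        a = int(np.argmin(np.abs(self.offsets_y)))
        b = int(np.argmin(np.abs(self.offsets_x)))
        peak = self.rpsf[p, a, b]
        return self.rpsf[p] / peak if peak > 0 else self.rpsf[p]


@dataclass(frozen=True)
class ScatteringRates:
    """Single/multiple scattering and noise rates with contrast."""

    alpha_s: float
    alpha_m: float
    alpha_n: float
    beta: float
    contrast: float
    flagged: bool = False

    @property
    def alpha_b(self) -> float:
        return self.alpha_m + self.alpha_n


def diffraction_limit(z: float, wavelength: float, aperture: float) -> float:
    """Diffraction-limited transverse resolution (mm) at depth ``z``:
    ``delta_rho_0 = lambda_c / (2 sin(arctan(aperture / (2 z))))``."""
    z = np.asarray(z, dtype=float)
    if np.any(z <= 0):
        raise ValueError("depth must be positive")
    half_angle = np.arctan(aperture / (2.0 * z))
    return wavelength / (2.0 * np.sin(half_angle))


def local_rpsf(
    cmp: CommonMidpointField | FocusedReflectionMatrix,
    patches: PatchSpec,
    min_midpoints: int = 10,
) -> RPSFMap:
    """Patchwise average of the de-scanned intensity.

    ``RPSF(drho, r_p) = < |R_M(drho, r_m)|² >`` over midpoints ``r_m``
    inside the patch window.  Midpoint membership is evaluated per offset
    (``rho_m = rho_anchor + drho / 2``), so the averaging window tracks the
    midpoint exactly as the separation grows.
    """
    cm = cmp if isinstance(cmp, CommonMidpointField) else to_common_midpoint(cmp)
    inten = np.abs(cm.data) ** 2  # NaN outside valid support
    n_oy, n_ox = len(cm.offsets_y), len(cm.offsets_x)
    out = np.full((patches.n_patches, n_oy, n_ox), np.nan)
    counts = np.zeros(patches.n_patches, dtype=int)
    mx = cm.midpoint_x()  # (n_ox, nx)
    my = cm.midpoint_y()  # (n_oy, ny)
    for p in range(patches.n_patches):
        xp, yp, _ = patches.centers[p]
        sel_z = patches.member_depths(cm.grid.z, p)
        if not sel_z.any():
            continue
        in_x = np.abs(mx - xp) < patches.w_rho / 2  # (n_ox, nx)
        in_y = np.abs(my - yp) < patches.w_rho / 2  # (n_oy, ny)
        sub = inten[sel_z]  # (nzp, n_oy, n_ox, ny, nx)
        w = in_y[None, :, None, :, None] & in_x[None, None, :, None, :]
        masked = np.where(w, sub, np.nan)
        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            out[p] = np.nanmean(masked, axis=(0, 3, 4))
        a = int(np.argmin(np.abs(cm.offsets_y)))
        b = int(np.argmin(np.abs(cm.offsets_x)))
        counts[p] = int(
            np.isfinite(np.where(w, sub, np.nan)[:, a, b]).sum()
        )
    return RPSFMap(
        rpsf=out,
        offsets_x=cm.offsets_x,
        offsets_y=cm.offsets_y,
        patches=patches,
        n_midpoints=counts,
        low_confidence=counts < min_midpoints,
    )


def resolution_3db(
    profile: np.ndarray,
    offsets_x: np.ndarray,
    offsets_y: np.ndarray,
) -> tuple[float, bool]:
    """Equivalent −3 dB radius of an RPSF intensity profile.

    The half-maximum area is measured on the *amplitude* profile (−3 dB in
    amplitude), restricted to the connected region containing the peak, and
    converted to the radius of the disc of equal area:
    ``delta_rho = sqrt(A / pi)``.  Returns ``(radius_mm, flagged)`` where
    the flag marks profiles without a usable peak (plateau-dominated).
    """
    amp = np.sqrt(np.asarray(profile, dtype=float))
    finite = np.isfinite(amp)
    if not finite.any():
        return np.nan, True
    peak = np.nanmax(amp)
    if peak <= 0:
        return np.nan, True
    above = finite & (amp >= peak / 2.0)
    labels, _ = ndimage.label(above)
    iy, ix = np.unravel_index(np.nanargmax(np.where(finite, amp, -np.inf)), amp.shape)
    region = labels == labels[iy, ix]
    dx = float(np.mean(np.diff(offsets_x))) if len(offsets_x) > 1 else 1.0
    dy = float(np.mean(np.diff(offsets_y))) if len(offsets_y) > 1 else 1.0
    area = region.sum() * dx * dy
    # plateau: the region touches the profile boundary on every side
    edge = (
        region[0, :].any()
        and region[-1, :].any()
        and region[:, 0].any()
        and region[:, -1].any()
    )
    return float(np.sqrt(area / np.pi)), bool(edge)


def decompose_rpsf(
    profile: np.ndarray,
    offsets_x: np.ndarray,
    offsets_y: np.ndarray,
    delta_rho0: float,
    descan_factor: float = 6.0,
    contrast_cap: float = 1e6,
) -> tuple[float, float, bool]:
    """Split a normalized RPSF into confocal peak and incoherent background.

    ``alpha_B`` is the median normalized intensity over the de-scanned
    annulus ``|drho| > descan_factor * delta_rho0`` (robust to residual
    peak leakage); ``alpha_S = 1 - alpha_B``; the contrast is
    ``F = alpha_S / alpha_B``.  Returns ``(alpha_b, contrast, flagged)``.
    """
    prof = np.asarray(profile, dtype=float)
    a = int(np.argmin(np.abs(offsets_y)))
    b = int(np.argmin(np.abs(offsets_x)))
    peak = prof[a, b]
    if not np.isfinite(peak) or peak <= 0:
        return np.nan, 0.0, True
    norm = prof / peak
    rr = np.hypot(offsets_x[None, :], offsets_y[:, None])
    annulus = (rr > descan_factor * delta_rho0) & np.isfinite(norm)
    if not annulus.any():
        return np.nan, 0.0, True
    alpha_b = float(np.median(norm[annulus]))
    if alpha_b >= 1.0:
        return alpha_b, 0.0, True
    if alpha_b <= 0.0:
        return 0.0, contrast_cap, True
    return alpha_b, min((1.0 - alpha_b) / alpha_b, contrast_cap), False


def antisymmetry_rate(
    f: FocusedReflectionMatrix,
    patches: PatchSpec,
    delta_rho0: np.ndarray | float,
    descan_factor: float = 6.0,
) -> np.ndarray:
    """Local degree of anti-symmetry ``beta`` of the focused matrix.

    Projects each depth slice onto its anti-symmetric subspace
    ``R_A = (R - R^T) / 2`` and measures the energy fraction over the
    de-scanned support ``|drho| > descan_factor * delta_rho0(z)`` inside
    each patch window.  Reciprocal contributions (single and multiple
    scattering) give ``beta = 0``; non-reciprocal noise splits evenly, so
    pure noise gives ``beta = 1/2``.
    """
    rho0 = np.broadcast_to(np.asarray(delta_rho0, dtype=float), f.grid.z.shape)
    cm = to_common_midpoint(f)
    anti = f.with_data((f.data - f.data.swapaxes(1, 2)) / 2.0)
    cm_a = to_common_midpoint(anti)
    i_full = np.abs(cm.data) ** 2
    i_anti = np.abs(cm_a.data) ** 2
    rr = np.hypot(cm.offsets_x[None, :], cm.offsets_y[:, None])
    mx = cm.midpoint_x()
    my = cm.midpoint_y()
    betas = np.full(patches.n_patches, np.nan)
    for p in range(patches.n_patches):
        xp, yp, _ = patches.centers[p]
        sel_z = np.flatnonzero(patches.member_depths(f.grid.z, p))
        if sel_z.size == 0:
            continue
        in_x = np.abs(mx - xp) < patches.w_rho / 2
        in_y = np.abs(my - yp) < patches.w_rho / 2
        num = 0.0
        den = 0.0
        for iz in sel_z:
            descan = rr > descan_factor * rho0[iz]
            w = (
                descan[:, :, None, None]
                & in_y[:, None, :, None]
                & in_x[None, :, None, :]
            )
            vals_full = i_full[iz][w]
            vals_anti = i_anti[iz][w]
            ok = np.isfinite(vals_full)
            num += np.nansum(vals_anti[ok])
            den += np.nansum(vals_full[ok])
        betas[p] = num / den if den > 0 else np.nan
    return betas


def scattering_rates(beta: float, alpha_b: float) -> tuple[float, float]:
    """Split the incoherent background via the anti-symmetry degree.

    ``alpha_M = (1 - 2 beta) alpha_B`` (reciprocal part) and
    ``alpha_N = 2 beta alpha_B`` (non-reciprocal part).  ``beta`` above 1/2
    is a sampling fluctuation of a noise-dominated background: alpha_M is
    clipped at zero.
    """
    beta_eff = min(float(beta), 0.5)
    alpha_m = (1.0 - 2.0 * beta_eff) * alpha_b
    alpha_n = 2.0 * beta_eff * alpha_b
    return alpha_m, alpha_n
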