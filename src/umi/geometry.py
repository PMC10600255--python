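"""Probe geometry for matrix-array (2D) and linear (1D) transducer probes.

Units are mm / µs / MHz throughout the package, so the speed of sound is
expressed in mm/µs (1540 m/s = 1.54 mm/µs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ProbeGeometry", "matrix_probe"]


@dataclass(frozen=True)
class ProbeGeometry:
    """A rectangular grid of transducer elements in the z = 0 plane.

    Parameters
    ----------
    element_positions : (N, 2) float array
        Element centres ``(u_x, u_y)`` in mm.
    pitch : float
        Inter-element pitch in mm (identical along both axes).
    central_frequency : float
        Centre frequency ``f_c`` in MHz.
    fractional_bandwidth : float
        −6 dB fractional bandwidth (e.g. ``0.8`` for 80%).
    sampling_frequency : float
        Baseband (IQ) sampling frequency ``f_s`` in MHz.
    directivity_limit : float
        Element directivity half-angle ``theta_max`` in degrees; focal
        points outside this cone do not contribute to the synthetic
        aperture of an element.
    reference_sound_speed : float
        Homogeneous model speed ``c_0`` in mm/µs.
    dead_element_mask : (N,) bool array
        True for elements that are disconnected (transmit and receive
        nothing).
    """

    element_positions: np.ndarray
    pitch: float
    central_frequency: float
    fractional_bandwidth: float = 0.8
    sampling_frequency: float = 6.0
    directivity_limit: float = 28.0
    reference_sound_speed: float = 1.54
    dead_element_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        pos = np.asarray(self.element_positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 2:
            raise ValueError("element_positions must have shape (N, 2)")
        object.__setattr__(self, "element_positions", pos)
        if self.pitch <= 0:
            raise ValueError("pitch must be positive")
        if not 0.0 < self.directivity_limit < 90.0:
            raise ValueError("directivity_limit must lie in (0, 90) degrees")
        if self.reference_sound_speed <= 0:
            raise ValueError("reference_sound_speed must be positive")
        # positions must be unique at a fraction of the pitch
        quant = np.round(pos / (0.01 * self.pitch)).astype(np.int64)
        if len(np.unique(quant, axis=0)) != len(pos):
            raise ValueError("element positions are not unique")
        if self.dead_element_mask is None:
            mask = np.zeros(len(pos), dtype=bool)
        else:
            mask = np.asarray(self.dead_element_mask, dtype=bool)
            if mask.shape != (len(pos),):
                raise ValueError("dead_element_mask must have shape (N,)")
        object.__setattr__(self, "dead_element_mask", mask)

    # -- derived quantities -------------------------------------------------
    @property
    def n_elements(self) -> int:
        return len(self.element_positions)

    @property
    def live(self) -> np.ndarray:
        """Boolean mask of connected elements."""
        return ~self.dead_element_mask

    @property
    def n_live(self) -> int:
        return int(self.live.sum())

    @property
    def aperture(self) -> tuple[float, float]:
        """Physical aperture ``(Δu_x, Δu_y)`` in mm.

        Includes the element footprint: span of the centres plus one pitch.
        """
        pos = self.element_positions
        return (
            float(pos[:, 0].max() - pos[:, 0].min() + self.pitch),
            float(pos[:, 1].max() - pos[:, 1].min() + self.pitch),
        )

    @property
    def wavelength(self) -> float:
        """Centre wavelength λ_c = c_0 / f_c in mm."""
        return self.reference_sound_speed / self.central_frequency

    @property
    def bandwidth(self) -> float:
        """−6 dB bandwidth in MHz."""
        return self.fractional_bandwidth * self.central_frequency

    @property
    def axial_resolution(self) -> float:
        """Pulse-limited axial resolution c_0 / (2 Δf) in mm."""
        return self.reference_sound_speed / (2.0 * self.bandwidth)


def matrix_probe(
    n_x: int = 32,
    n_y: int = 32,
    pitch: float = 0.5,
    central_frequency: float = 3.0,
    fractional_bandwidth: float = 0.8,
    sampling_frequency: float = 6.0,
    directivity_limit: float = 28.0,
    reference_sound_speed: float = 1.54,
    n_dead: int = 0,
    block_rows: int | None = None,
    gap_rows: int = 1,
    seed: int = 0,
) -> ProbeGeometry:
    """Build a fully populated matrix probe centred on the origin.

    The default parameters reproduce a 3 MHz, 0.5 mm pitch matrix array
    with 80% fractional bandwidth sampled at f_s = 2 f_c = 6 MHz and a 28°
    directivity cone.  ``block_rows`` inserts ``gap_rows`` inactive row
    pitches between blocks of rows along y (matrix arrays wired in banks
    often leave such mechanical gaps), which stretches the y aperture
    without adding elements.  ``n_dead`` marks that many randomly chosen
    elements as dead (reproducible via ``seed``).
    """
    ux = (np.arange(n_x) - (n_x - 1) / 2.0) * pitch
    row_idx = np.arange(n_y, dtype=float)
    if block_rows:
        row_idx = row_idx + gap_rows * (np.arange(n_y) // block_rows)
    uy = (row_idx - row_idx.mean()) * pitch
    gx, gy = np.meshgrid(ux, uy, indexing="xy")
    pos = np.column_stack([gx.ravel(), gy.ravel()])
    dead = np.zeros(len(pos), dtype=bool)
    if n_dead:
        rng = np.random.default_rng(seed)
        dead[rng.choice(len(pos), size=n_dead, replace=False)] = True
    return ProbeGeometry(
        element_positions=pos,
        pitch=pitch,
        central_frequency=central_frequency,
        fractional_bandwidth=fractional_bandwidth,
        sampling_frequency=sampling_frequency,
        directivity_limit=directivity_limit,
        reference_sound_speed=reference_sound_speed,
        dead_element_mask=dead,
    )
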