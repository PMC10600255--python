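"""Imaging grids: voxel centres for the focused basis."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ImagingGrid"]


@dataclass(frozen=True)
class ImagingGrid:
    """Rectangular voxel grid on which the focused matrix is built.

    ``x`` and ``y`` are transverse coordinates (mm), ``z`` the depths (mm,
    z > 0 into the medium, probe plane at z = 0).  Coordinates are voxel
    centres.  Transverse points are flattened row-major in ``(y, x)`` order:
    ``p = iy * nx + ix``.
    """

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray

    def __post_init__(self) -> None:
        for name in ("x", "y", "z"):
            v = np.atleast_1d(np.asarray(getattr(self, name), dtype=float))
            if v.size > 1 and not np.all(np.diff(v) > 0):
                raise ValueError(f"{name} axis must be strictly increasing")
            object.__setattr__(self, name, v)
        if np.any(self.z <= 0):
            raise ValueError("depths must be positive (probe plane is z = 0)")

    @classmethod
    def regular(
        cls,
        x_span: tuple[float, float],
        y_span: tuple[float, float],
        z_span: tuple[float, float],
        pitch: float = 0.5,
        dz: float | None = None,
    ) -> "ImagingGrid":
        """Regular grid with transverse ``pitch`` and axial step ``dz`` (mm)."""
        if pitch <= 0:
            raise ValueError("pitch must be positive")
        dz = pitch if dz is None else dz
        mk = lambda lo, hi, d: lo + d * np.arange(int(round((hi - lo) / d)) + 1)
        return cls(mk(*x_span, pitch), mk(*y_span, pitch), mk(*z_span, dz))

    @property
    def nx(self) -> int:
        return self.x.size

    @property
    def ny(self) -> int:
        return self.y.size

    @property
    def nz(self) -> int:
        return self.z.size

    @property
    def n_transverse(self) -> int:
        return self.nx * self.ny

    @property
    def pitch(self) -> float:
        """Transverse voxel pitch (mm); requires a regular transverse grid."""
        ax = self.x if self.nx > 1 else self.y
        if ax.size < 2:
            return 0.0
        d = np.diff(ax)
        if not np.allclose(d, d[0]):
            raise ValueError("grid is not regular")
        return float(d[0])

    def transverse_points(self) -> np.ndarray:
        """(n_transverse, 2) array of (x, y) voxel centres, (y, x) row-major."""
        gx, gy = np.meshgrid(self.x, self.y, indexing="xy")
        return np.column_stack([gx.ravel(), gy.ravel()])

    def shift(self, dx: float = 0.0, dy: float = 0.0, dz: float = 0.0) -> "ImagingGrid":
        return ImagingGrid(self.x + dx, self.y + dy, self.z + dz)
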