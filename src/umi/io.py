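"""HDF5 container I/O for acquisitions and focused matrices.

Layout (version 1):

* ``/geometry`` — element positions, pitch, frequencies, directivity,
  sound speed, dead-element mask;
* ``/acquisition`` — illumination basis tag, angle table (plane-wave
  basis), time axis origin/step, demodulation frequency;
* ``/data`` — complex samples stored as interleaved float32 pairs with
  dimension labels (illumination, element, time);
* ``/truth`` — optional ground truth (screen phase, scatterer table) for
  synthetic fixtures.

Complex arrays are stored as float32 pairs (matching IQ acquisition
precision); computation uses float64 upstream.
"""

from __future__ import annotations

import numpy as np

from umi.beamform import FocusedReflectionMatrix
from umi.geometry import ProbeGeometry
from umi.grids import ImagingGrid
from umi.simulate import RawReflectionMatrix

__all__ = [
    "ContainerError",
    "read_acquisition",
    "write_acquisition",
    "read_focused",
    "write_focused",
]

FORMAT_VERSION = 1


class ContainerError(ValueError):
    """Malformed or unsupported container file."""


def _to_pairs(arr: np.ndarray) -> np.ndarray:
    out = np.empty(arr.shape + (2,), dtype=np.float32)
    out[..., 0] = arr.real
    out[..., 1] = arr.imag
    return out


def _from_pairs(ds) -> np.ndarray:
    arr = np.asarray(ds)
    return (arr[..., 0] + 1j * arr[..., 1]).astype(np.complex64)


def write_acquisition(raw: RawReflectionMatrix, path: str) -> None:
    """Write a raw reflection matrix to an HDF5 container (lossless for
    the complex64 data)."""
    import h5py

    geo = raw.geometry
    with h5py.File(path, "w") as h5:
        h5.attrs["format"] = "umi-acquisition"
        h5.attrs["version"] = FORMAT_VERSION
        g = h5.create_group("geometry")
        g.create_dataset("element_positions", data=geo.element_positions)
        g.create_dataset("dead_element_mask", data=geo.dead_element_mask)
        for k in (
            "pitch",
            "central_frequency",
            "fractional_bandwidth",
            "sampling_frequency",
            "directivity_limit",
            "reference_sound_speed",
        ):
            g.attrs[k] = getattr(geo, k)
        a = h5.create_group("acquisition")
        a.attrs["basis"] = raw.basis
        a.attrs["t0"] = raw.t0
        a.attrs["dt"] = raw.dt
        a.attrs["demodulation_frequency"] = raw.demodulation_frequency
        if raw.angles_deg is not None:
            a.create_dataset("angles_deg", data=raw.angles_deg)
        d = h5.create_dataset("data", data=_to_pairs(raw.data))
        d.attrs["dims"] = ["illumination", "element", "time", "iq"]
        if raw.truth:
            t = h5.create_group("truth")
            for k, v in raw.truth.items():
                arr = np.asarray(v)
                if np.iscomplexobj(arr):
                    t.create_dataset(k, data=_to_pairs(arr.astype(np.complex64)))
                    t[k].attrs["complex"] = True
                else:
                    t.create_dataset(k, data=arr)


def read_acquisition(path: str) -> RawReflectionMatrix:
    """Read an acquisition container back into a :class:`RawReflectionMatrix`."""
    import h5py

    try:
        h5 = h5py.File(path, "r")
    except OSError as exc:
        raise ContainerError(f"not a readable HDF5 container: {exc}") from exc
    with h5:
        if h5.attrs.get("format") != "umi-acquisition":
            raise ContainerError("missing or wrong container format tag")
        if int(h5.attrs.get("version", -1)) > FORMAT_VERSION:
            raise ContainerError("container version not supported")
        if "geometry" not in h5:
            raise ContainerError("missing /geometry group")
        if "data" not in h5 or "acquisition" not in h5:
            raise ContainerError("missing /data or /acquisition group")
        g = h5["geometry"]
        geo = ProbeGeometry(
            element_positions=np.asarray(g["element_positions"]),
            pitch=float(g.attrs["pitch"]),
            central_frequency=float(g.attrs["central_frequency"]),
            fractional_bandwidth=float(g.attrs["fractional_bandwidth"]),
            sampling_frequency=float(g.attrs["sampling_frequency"]),
            directivity_limit=float(g.attrs["directivity_limit"]),
            reference_sound_speed=float(g.attrs["reference_sound_speed"]),
            dead_element_mask=np.asarray(g["dead_element_mask"], dtype=bool),
        )
        a = h5["acquisition"]
        angles = np.asarray(a["angles_deg"]) if "angles_deg" in a else None
        truth = {}
        if "truth" in h5:
            for k, ds in h5["truth"].items():
                if ds.attrs.get("complex", False):
                    truth[k] = _from_pairs(ds)
                else:
                    truth[k] = np.asarray(ds)
        return RawReflectionMatrix(
            data=_from_pairs(h5["data"]),
            t0=float(a.attrs["t0"]),
            dt=float(a.attrs["dt"]),
            demodulation_frequency=float(a.attrs["demodulation_frequency"]),
            basis=str(a.attrs["basis"]),
            geometry=geo,
            angles_deg=angles,
            truth=truth,
        )


def write_focused(f: FocusedReflectionMatrix, path: str) -> None:
    """Write a focused matrix: per-depth groups ``/focused/z_{k}`` plus the
    coverage mask and grid axes."""
    import h5py

    with h5py.File(path, "w") as h5:
        h5.attrs["format"] = "umi-focused"
        h5.attrs["version"] = FORMAT_VERSION
        h5.attrs["drho_max"] = f.drho_max
        h5.attrs["provenance"] = [str(p) for p in f.provenance]
        g = h5.create_group("grid")
        for ax in ("x", "y", "z"):
            g.create_dataset(ax, data=getattr(f.grid, ax))
        foc = h5.create_group("focused")
        for k in range(f.data.shape[0]):
            foc.create_dataset(f"z_{k}", data=_to_pairs(f.data[k].astype(np.complex64)))
        h5.create_dataset("coverage", data=f.coverage)
        h5.create_dataset("pair_mask", data=f.pair_mask)


def read_focused(path: str) -> FocusedReflectionMatrix:
    import h5py

    try:
        h5 = h5py.File(path, "r")
    except OSError as exc:
        raise ContainerError(f"not a readable HDF5 container: {exc}") from exc
    with h5:
        if h5.attrs.get("format") != "umi-focused":
            raise ContainerError("missing or wrong container format tag")
        grid = ImagingGrid(
            np.asarray(h5["grid/x"]),
            np.asarray(h5["grid/y"]),
            np.asarray(h5["grid/z"]),
        )
        nz = grid.nz
        data = np.stack(
            [_from_pairs(h5[f"focused/z_{k}"]).astype(complex) for k in range(nz)]
        )
        return FocusedReflectionMatrix(
            grid=grid,
            data=data,
            drho_max=float(h5.attrs["drho_max"]),
            pair_mask=np.asarray(h5["pair_mask"], dtype=bool),
            coverage=np.asarray(h5["coverage"], dtype=bool),
            provenance=[str(p) for p in h5.attrs.get("provenance", [])],
        )
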