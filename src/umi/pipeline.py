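"""End-to-end workbench: configuration, pipeline orchestration, reports.

``run_pipeline`` ties the stages together — synthetic acquisition (or a
container on disk), focused beamforming, RPSF / scattering-rate metrics,
multi-scale aberration correction — and leaves a set of artifacts plus a
provenance log in the output directory.  Everything is deterministic under
the configured seeds.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from umi import io as uio
from umi.aberration import (
    ConvergenceError,
    CorrectionSchedule,
    CorrectionStep,
    run_multiscale,
)
from umi.beamform import beamform_focused_matrix, confocal_image
from umi.geometry import matrix_probe
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
from umi.simulate import make_phase_screen, sample_speckle_medium, simulate_acquisition

__all__ = [
    "ConfigError",
    "RunConfig",
    "ProvenanceLog",
    "run_pipeline",
    "render_report",
    "render_rpsf_mosaic",
]


class ConfigError(ValueError):
    """Invalid run configuration."""


@dataclass
class RunConfig:
    """Validated pipeline configuration.

    See ``RunConfig.example()`` for the schema; all physical quantities
    are mm / µs / MHz (rms screen delay in ns).
    """

    probe: dict
    grid: dict
    seed: int = 0
    simulate: dict | None = None
    input_path: str | None = None
    beamform: dict = field(default_factory=dict)
    metrics: dict = field(default_factory=dict)
    schedule: list | None = None
    output_dir: str = "umi_out"

    def __post_init__(self) -> None:
        if self.simulate is None and self.input_path is None:
            raise ConfigError("need either a 'simulate' block or an 'input_path'")
        for span in ("x", "y", "z"):
            if span not in self.grid:
                raise ConfigError(f"grid block must give a '{span}' span")
        if self.schedule is not None:
            for s in self.schedule:
                if s.get("w_rho", 0) <= 0 or s.get("w_z", 0) <= 0:
                    raise ConfigError("schedule steps need positive w_rho / w_z")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        import yaml

        with open(path) as fh:
            try:
                doc = yaml.safe_load(fh)
            except yaml.YAMLError as exc:
                raise ConfigError(f"unparsable config: {exc}") from exc
        if not isinstance(doc, dict):
            raise ConfigError("config must be a mapping")
        known = {
            "probe",
            "grid",
            "seed",
            "simulate",
            "input_path",
            "beamform",
            "metrics",
            "schedule",
            "output_dir",
        }
        unknown = set(doc) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        try:
            return cls(**doc)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    @classmethod
    def example(cls) -> "RunConfig":
        """Small demo configuration (12×12 probe, 2D speckle slab)."""
        return cls(
            probe={"n_x": 12, "n_y": 12, "pitch": 0.5},
            grid={"x": [-4.0, 4.0], "y": [-4.0, 4.0], "z": [18.5, 21.5], "pitch": 0.5},
            seed=1,
            simulate={
                "medium": {
                    "bounds": [[-5.0, 5.0], [-5.0, 5.0], [18.0, 22.0]],
                    "density": 0.055,
                },
                "screen": {"correlation_length": 2.0, "rms_delay_ns": 60.0},
                "noise_weight": 0.5,
            },
            beamform={"drho_max": 8.0},
            metrics={"patches": [2, 2], "w_rho": 4.0, "w_z": 3.0},
            schedule=[
                {"n_patches": [1, 1], "w_rho": 9.0, "w_z": 4.0, "threshold": 0.5},
                {"n_patches": [1, 1], "w_rho": 9.0, "w_z": 4.0, "threshold": 0.5},
            ],
        )


@dataclass
class ProvenanceLog:
    """Per-stage parameters, content hashes and timings."""

    version: str = ""
    stages: list = field(default_factory=list)

    def add(self, stage: str, params: dict, arrays: dict, t0: float) -> None:
        hashes = {
            k: hashlib.sha256(np.ascontiguousarray(v).tobytes()).hexdigest()[:16]
            for k, v in arrays.items()
        }
        self.stages.append(
            {
                "stage": stage,
                "params": params,
                "sha256": hashes,
                "seconds": round(time.time() - t0, 3),
            }
        )

    def dump(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump({"version": self.version, "stages": self.stages}, fh, indent=2)


def _metric_table(f, geometry, patches: PatchSpec) -> list[dict]:
    """Per-patch metric rows: centre, resolution, contrast, rates."""
    rho0_z = np.array(
        [
            diffraction_limit(z, geometry.wavelength, float(np.mean(geometry.aperture)))
            for z in f.grid.z
        ]
    )
    rm = local_rpsf(f, patches)
    betas = antisymmetry_rate(f, patches, delta_rho0=rho0_z)
    rows = []
    for p in range(patches.n_patches):
        rho0 = float(
            diffraction_limit(
                patches.centers[p, 2],
                geometry.wavelength,
                float(np.mean(geometry.aperture)),
            )
        )
        res, res_flag = resolution_3db(rm.rpsf[p], rm.offsets_x, rm.offsets_y)
        alpha_b, contrast, dec_flag = decompose_rpsf(
            rm.rpsf[p], rm.offsets_x, rm.offsets_y, rho0
        )
        beta = float(betas[p]) if np.isfinite(betas[p]) else float("nan")
        if np.isfinite(alpha_b) and np.isfinite(beta):
            a_m, a_n = scattering_rates(beta, alpha_b)
            a_s = 1.0 - alpha_b
        else:
            a_m = a_n = a_s = float("nan")
        rows.append(
            {
                "x": patches.centers[p, 0],
                "y": patches.centers[p, 1],
                "z": patches.centers[p, 2],
                "delta_rho_3db": res,
                "delta_rho_0": rho0,
                "contrast": contrast,
                "alpha_s": a_s,
                "alpha_m": a_m,
                "alpha_n": a_n,
                "beta": beta,
                "flagged": bool(res_flag or dec_flag),
            }
        )
    return rows


def _write_table(rows: list[dict], path: Path) -> None:
    if not rows:
        path.write_text("")
        return
    cols = list(rows[0])
    lines = ["\t".join(cols)]
    for r in rows:
        lines.append(
            "\t".join(
                f"{r[c]:.6g}" if isinstance(r[c], float) else str(r[c]) for c in cols
            )
        )
    path.write_text("\n".join(lines) + "\n")


def run_pipeline(config: RunConfig) -> dict:
    """Run simulate → beamform → metrics → correct and write artifacts.

    Returns a dict of in-memory artifacts (raw, focused matrices, metric
    tables, correction history, provenance log); files are written under
    ``config.output_dir``.
    """
    from umi import __version__

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = ProvenanceLog(version=__version__)
    artifacts: dict = {"output_dir": str(out)}

    geometry = matrix_probe(**config.probe)
    gcfg = config.grid
    grid = ImagingGrid.regular(
        tuple(gcfg["x"]),
        tuple(gcfg["y"]),
        tuple(gcfg["z"]),
        pitch=gcfg.get("pitch", 0.5),
        dz=gcfg.get("dz"),
    )

    # --- acquisition -------------------------------------------------------
    t0 = time.time()
    if config.simulate is not None:
        sim = config.simulate
        med_cfg = sim["medium"]
        medium = sample_speckle_medium(
            tuple(tuple(b) for b in med_cfg["bounds"]),
            med_cfg.get("density", 0.05),
            seed=med_cfg.get("seed", config.seed),
            geometry=geometry,
        )
        scr = sim.get("screen", {})
        aberrator = make_phase_screen(
            geometry,
            scr.get("correlation_length", 2.0),
            scr.get("rms_delay_ns", 0.0),
            seed=scr.get("seed", config.seed),
            ms_background_weight=sim.get("ms_weight", 0.0),
            noise_weight=sim.get("noise_weight", 0.0),
        )
        raw = simulate_acquisition(
            geometry,
            medium,
            aberrator,
            basis=sim.get("basis", "transducer"),
            seed=config.seed,
            angles_deg=sim.get("angles_deg"),
        )
        uio.write_acquisition(raw, str(out / "acquisition.h5"))
    else:
        raw = uio.read_acquisition(config.input_path)
        geometry = raw.geometry
    log.add("acquisition", {"simulated": config.simulate is not None},
            {"data": raw.data}, t0)
    artifacts["raw"] = raw

    # --- beamforming -------------------------------------------------------
    t0 = time.time()
    bf = config.beamform
    focused = beamform_focused_matrix(
        raw,
        grid,
        drho_max=bf.get("drho_max", 10.0),
        apodization=bf.get("apodization", "cone"),
    )
    uio.write_focused(focused, str(out / "focused_before.h5"))
    log.add("beamform", dict(bf), {"data": focused.data}, t0)
    artifacts["focused_before"] = focused
    artifacts["confocal_before"] = confocal_image(focused)

    # --- metrics (before) --------------------------------------------------
    t0 = time.time()
    m = config.metrics
    patches = PatchSpec.tile(
        grid,
        tuple(m.get("patches", [2, 2])),
        m.get("w_rho", 4.0),
        m.get("w_z", 3.0),
    )
    table_before = _metric_table(focused, geometry, patches)
    _write_table(table_before, out / "metrics_before.tsv")
    log.add("metrics", dict(m), {}, t0)
    artifacts["metrics_before"] = table_before

    # --- correction --------------------------------------------------------
    if config.schedule:
        t0 = time.time()
        steps = tuple(
            CorrectionStep(
                n_patches=tuple(s.get("n_patches", [1, 1])),
                w_rho=s["w_rho"],
                w_z=s["w_z"],
                basis=s.get("basis", "transducer"),
                confocal_filter=s.get("confocal_filter", False),
                threshold=s.get("threshold", 0.9),
            )
            for s in config.schedule
        )
        result = run_multiscale(
            focused,
            CorrectionSchedule(steps),
            geometry,
            raw=raw if raw.basis == "transducer" else None,
        )
        corrected = result.corrected
        uio.write_focused(corrected, str(out / "focused_after.h5"))
        table_after = _metric_table(corrected, geometry, patches)
        _write_table(table_after, out / "metrics_after.tsv")
        p_summary = [
            {
                "step": k,
                "n_patches": len(ests),
                "accepted": int(sum(e.accepted for e in ests)),
                "p_median": float(np.median([e.p_inout for e in ests])),
                "p_min": float(min(e.p_inout for e in ests)),
                "p_max": float(max(e.p_inout for e in ests)),
            }
            for k, ests in enumerate(result.history)
        ]
        log.add("correct", {"steps": len(steps)}, {"data": corrected.data}, t0)
        artifacts.update(
            focused_after=corrected,
            confocal_after=confocal_image(corrected),
            metrics_after=table_after,
            correction_history=result.history,
            p_summary=p_summary,
        )
        with open(out / "p_inout.json", "w") as fh:
            json.dump(p_summary, fh, indent=2)

    log.dump(out / "provenance.json")
    artifacts["provenance"] = log
    report = render_report(artifacts)
    (out / "report.txt").write_text(report)
    artifacts["report"] = report
    return artifacts


def render_report(artifacts: dict) -> str:
    """Human-readable summary assembled from the metric tables.

    Values are quoted verbatim from the tables — nothing is recomputed.
    """
    lines = ["ultrasound matrix imaging — run report", "=" * 40]

    def table_block(rows, title):
        lines.append("")
        lines.append(title)
        lines.append(
            f"{'z':>6} {'d_rho(-3dB)':>12} {'d_rho_0':>8} {'contrast':>9} "
            f"{'a_S':>6} {'a_M':>6} {'a_N':>6} {'beta':>6}"
        )
        for r in rows:
            lines.append(
                f"{r['z']:6.1f} {r['delta_rho_3db']:12.3f} {r['delta_rho_0']:8.3f} "
                f"{r['contrast']:9.3g} {r['alpha_s']:6.3f} {r['alpha_m']:6.3f} "
                f"{r['alpha_n']:6.3f} {r['beta']:6.3f}"
            )

    if "metrics_before" in artifacts:
        table_block(artifacts["metrics_before"], "metrics before correction")
    if "metrics_after" in artifacts:
        table_block(artifacts["metrics_after"], "metrics after correction")
    if "p_summary" in artifacts:
        lines.append("")
        lines.append("reciprocity convergence (per correction step)")
        for s in artifacts["p_summary"]:
            lines.append(
                f"  step {s['step']}: {s['accepted']}/{s['n_patches']} patches "
                f"accepted, P_in/out median {s['p_median']:.3f} "
                f"[{s['p_min']:.3f}, {s['p_max']:.3f}]"
            )
    if not any(k in artifacts for k in ("metrics_before", "metrics_after")):
        lines.append("(no metric tables in artifacts)")
    return "\n".join(lines) + "\n"


def render_rpsf_mosaic(rpsf_map, path: str, shape: tuple[int, int] | None = None):
    """Save a mosaic of per-patch RPSF amplitude maps (requires matplotlib).

    One panel per patch, laid out on ``shape = (rows, cols)`` (default: a
    near-square arrangement matching the patch count).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = rpsf_map.patches.n_patches
    if shape is None:
        cols = int(np.ceil(np.sqrt(n)))
        shape = (int(np.ceil(n / cols)), cols)
    fig, axes = plt.subplots(
        *shape, figsize=(2.2 * shape[1], 2.2 * shape[0]), squeeze=False
    )
    extent = [
        rpsf_map.offsets_x[0],
        rpsf_map.offsets_x[-1],
        rpsf_map.offsets_y[0],
        rpsf_map.offsets_y[-1],
    ]
    for p in range(shape[0] * shape[1]):
        ax = axes[p // shape[1]][p % shape[1]]
        if p < n:
            ax.imshow(rpsf_map.amplitude(p), extent=extent, origin="lower")
            cx, cy, cz = rpsf_map.patches.centers[p]
            ax.set_title(f"({cx:g}, {cy:g}, {cz:g}) mm", fontsize=7)
        ax.set_xticks([])
        ax.set_yticks([])
    fig.suptitle("local RPSF amplitude vs separation", fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return path
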