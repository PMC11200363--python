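"""Experiment orchestration: scenario batches and mesh-convergence studies."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import ScenarioConfig, preset, PRESET_NAMES
from .coupling import FSIRunner, attach_acoustics, metrics_record, SimulationResult
from .meshing import generate_mesh, refine_mesh, write_vtk
from .metrics import (MetricsRecord, build_comparison_report, save_report)

log = logging.getLogger("sinuflow")

MM = 1.0e-3


@dataclass
class ExperimentManifest:
    """A batch of scenarios to run with common settings."""

    scenarios: list[str | ScenarioConfig] = field(
        default_factory=lambda: list(PRESET_NAMES))
    outdir: str | Path = "sinuflow_out"
    cycles: int | None = None        # None -> each scenario's configured cycles
    h_max: float | None = None       # mm, overrides scenario meshes if set
    mesh_levels: int = 1
    seed: int = 0                    # reserved for randomized perturbation tests
    version: str = __version__

    def resolve(self) -> list[ScenarioConfig]:
        out = []
        for sc in self.scenarios:
            cfg = preset(sc) if isinstance(sc, str) else sc
            if self.h_max is not None:
                cfg = cfg.replace()  # deep copy
                cfg.solver.h_max = self.h_max
            out.append(cfg.validate())
        return out


def run_scenario(config: ScenarioConfig, cycles: int | None = None,
                 outdir: Path | None = None,
                 export_fields: bool = False) -> tuple[SimulationResult, MetricsRecord]:
    """Geometry -> mesh -> FSI -> acoustics -> metrics for one scenario."""
    t0 = time.time()
    runner = FSIRunner(config)
    res = runner.run(cycles=cycles)
    res = attach_acoustics(runner, res)
    rec = metrics_record(res)
    log.info("%s finished in %.1f s: Pavg=%.2f Pa Davg=%.3f um SPL=%.2f dB",
             config.name, time.time() - t0, rec.Pavg, rec.Davg, rec.SPLavg)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / f"{config.name}_metrics.json").write_text(
            json.dumps(rec.to_dict(), indent=1))
        hist = pd.DataFrame({
            "t_s": res.times, "max_speed_m_s": res.max_speed,
            "cfl": res.cfl, "reynolds": res.reynolds,
            "Pavg_sswd_Pa": res.pavg_sswd, "Davg_sswd_um": res.davg_sswd * 1e6,
            "subiterations": res.subiterations,
            "residual_d": res.residual_d, "residual_t": res.residual_t,
        })
        hist.to_csv(outdir / f"{config.name}_history.csv", index=False)
        if export_fields:
            pd_data = {}
            if res.fluid_final is not None:
                vel = np.zeros((res.mesh.num_nodes, 2))
                vel[runner.fluid.nodes] = res.fluid_final.u
                prs = np.zeros(res.mesh.num_nodes)
                prs[runner.fluid.nodes] = res.fluid_final.p
                pd_data = {"velocity": vel, "pressure": prs}
            write_vtk(res.mesh, outdir / f"{config.name}_fields.vtk",
                      point_data=pd_data)
    return res, rec


def run_experiment(manifest: ExperimentManifest) -> pd.DataFrame:
    """Run every scenario of a manifest and assemble the comparison report.

    A failing scenario is logged and skipped; the others continue.  The
    report pairs ``<scenario>_pre`` / ``<scenario>_post`` runs.
    """
    outdir = Path(manifest.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records: dict[str, MetricsRecord] = {}
    for cfg in manifest.resolve():
        try:
            _, rec = run_scenario(cfg, cycles=manifest.cycles, outdir=outdir)
            records[cfg.name] = rec
        except Exception:
            log.exception("scenario %s failed; continuing", cfg.name)
    pairs = {}
    for name, rec in records.items():
        if rec.phase == "pre" and f"{rec.scenario}_post" in records:
            pairs[rec.scenario] = (rec, records[f"{rec.scenario}_post"])
    report = build_comparison_report(pairs)
    save_report(report, outdir / "comparison")
    (outdir / "manifest.json").write_text(json.dumps({
        "scenarios": [c if isinstance(c, str) else c.name
                      for c in manifest.scenarios],
        "cycles": manifest.cycles, "h_max": manifest.h_max,
        "seed": manifest.seed, "version": manifest.version}, indent=1))
    return report


def save_result_h5(res: SimulationResult, path: str | Path) -> None:
    """Checkpoint the run histories to a hierarchical HDF5 container."""
    import h5py

    with h5py.File(path, "w") as h5:
        h5.attrs["scenario"] = res.config.name
        h5.attrs["dt"] = res.dt
        h5.attrs["n_per_cycle"] = res.n_per_cycle
        h5.attrs["cycles"] = res.cycles
        g = h5.create_group("history")
        for name in ("times", "max_speed", "cfl", "reynolds", "pavg_sswd",
                     "davg_sswd", "subiterations", "residual_d", "residual_t",
                     "fluid_work", "solid_energy"):
            g.create_dataset(name, data=getattr(res, name))
        s = h5.create_group("sswd")
        s.create_dataset("displacement", data=res.sswd_disp)
        s.create_dataset("nodes", data=res.sswd_nodes)
        if res.fluid_final is not None:
            f = h5.create_group("fluid_final")
            f.create_dataset("u", data=res.fluid_final.u)
            f.create_dataset("p", data=res.fluid_final.p)


def load_result_h5(path: str | Path) -> dict:
    """Load a history checkpoint written by :func:`save_result_h5`."""
    import h5py

    out: dict = {}
    with h5py.File(path, "r") as h5:
        out.update({k: h5.attrs[k] for k in h5.attrs})
        out["history"] = {k: np.asarray(v) for k, v in h5["history"].items()}
        out["sswd_displacement"] = np.asarray(h5["sswd"]["displacement"])
        out["sswd_nodes"] = np.asarray(h5["sswd"]["nodes"])
        if "fluid_final" in h5:
            out["fluid_u"] = np.asarray(h5["fluid_final"]["u"])
            out["fluid_p"] = np.asarray(h5["fluid_final"]["p"])
    return out


def mesh_convergence_study(config: ScenarioConfig, levels: int = 2,
                           cycles: int = 1, h_base: float | None = None,
                           threshold: float = 5.0) -> pd.DataFrame:
    """Nested-refinement convergence of the two acceptance metrics.

    Runs the scenario on ``levels`` meshes (uniform midpoint refinements of
    the base mesh), tracking the cycle-averaged Davg on the SSWD patch and
    SPLavg at the tympanum; reports the relative change (%) between
    successive levels and whether the finest pair meets the threshold.
    The time-average over the last cycle is the refinement monitor (the
    peak-moment sample, also reported, is a noisy single-instant probe of
    an unsteady flow).
    """
    if levels < 2:
        raise ValueError("need at least two mesh levels")
    from .geometry import build_geometry

    geom = build_geometry(config)
    h0 = (h_base if h_base is not None else config.solver.h_max) * MM
    mesh = generate_mesh(geom, h0, config.solver.n_layers)
    # all levels advance with the finest level's automatic time step, so
    # the inter-level change isolates the spatial discretization error
    meshes = [mesh]
    for _ in range(levels - 1):
        meshes.append(refine_mesh(meshes[-1]))
    probe = FSIRunner(config, mesh=meshes[-1], geom=geom)
    dt_common, _ = probe.determine_dt()
    rows = []
    for lvl in range(levels):
        mesh = meshes[lvl]
        runner = FSIRunner(config, mesh=mesh, geom=geom)
        res = runner.run(cycles=cycles, dt=dt_common)
        res = attach_acoustics(runner, res)
        i = res.peak_index()
        lc = res.last_cycle()
        rows.append({
            "level": lvl, "h_m": mesh.h, "triangles": len(mesh.triangles),
            "Davg_um": float(np.mean(res.davg_sswd[lc])) * 1e6,
            "Davg_peak_um": float(res.davg_sswd[i]) * 1e6,
            "SPLavg_dB": float(res.spl_avg),
        })
    df = pd.DataFrame(rows)
    dD = np.full(len(df), np.nan)
    dS = np.full(len(df), np.nan)
    for k in range(1, len(df)):
        dD[k] = 100.0 * abs(df.Davg_um[k] - df.Davg_um[k - 1]) / abs(df.Davg_um[k])
        dS[k] = 100.0 * abs(df.SPLavg_dB[k] - df.SPLavg_dB[k - 1]) / abs(df.SPLavg_dB[k])
    df["dDavg_pct"] = dD
    df["dSPL_pct"] = dS
    df["accepted"] = (df.dDavg_pct < threshold) & (df.dSPL_pct < threshold)
    if len(df) >= 3:
        both = df.dDavg_pct.values[1:] + df.dSPL_pct.values[1:]
        if np.any(np.diff(both) > 0):
            log.warning("non-monotone convergence across levels")
    return df
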