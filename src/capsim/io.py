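"""Configuration files and run outputs.

Configs are TOML by default (flat, diff-able) with YAML accepted; unknown
keys fail fast through the pydantic schema.  Run outputs are plain text:
canonical JSON metric summaries (byte-stable under a fixed seed),
trajectory and event-log CSVs, and legacy-ASCII VTK snapshots of the flow
field for heat-map rendering.
"""

from __future__ import annotations

import json
import tomllib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .flow import FlowField
from .simulation import SimulationConfig


# ----------------------------------------------------------------------
# config round-trip
# ----------------------------------------------------------------------

def load_config(path: str | Path) -> SimulationConfig:
    """Read a TOML (or YAML) simulation config, validating every key."""
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        data = yaml.safe_load(path.read_text())
    else:
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
    return SimulationConfig(**(data or {}))


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    if isinstance(v, str):
        return json.dumps(v)
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    raise TypeError(f"cannot serialise {type(v)} to TOML")


def dump_config_toml(config: SimulationConfig) -> str:
    """Serialise a config to TOML (scalars and one level of tables)."""
    data = config.model_dump()
    lines: list[str] = []
    tables: list[str] = []

    def emit(prefix: str, node: dict) -> None:
        scalars = {k: v for k, v in node.items()
                   if not isinstance(v, dict) and v is not None}
        subs = {k: v for k, v in node.items() if isinstance(v, dict)}
        if prefix:
            tables.append(f"[{prefix}]")
            for k, v in scalars.items():
                tables.append(f"{k} = {_toml_value(v)}")
            tables.append("")
        else:
            for k, v in scalars.items():
                lines.append(f"{k} = {_toml_value(v)}")
        for k, v in subs.items():
            emit(f"{prefix}.{k}" if prefix else k, v)

    emit("", data)
    return "\n".join(lines + [""] + tables)


def save_config(config: SimulationConfig, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(config.model_dump(), sort_keys=False))
    else:
        path.write_text(dump_config_toml(config))


# ----------------------------------------------------------------------
# run outputs
# ----------------------------------------------------------------------

def metrics_json(summary: dict) -> str:
    """Canonical (byte-stable) JSON for a metrics summary."""
    return json.dumps(summary, sort_keys=True, indent=1,
                      allow_nan=True, default=float)


def write_trajectories_csv(path: str | Path, trajectory: np.ndarray,
                           dt: float, statuses: np.ndarray | None = None) -> None:
    """Trajectory CSV: time_s, id, x_nm, y_nm, z_nm[, status]."""
    n_t, n_p, _ = trajectory.shape
    t = np.repeat(np.arange(n_t) * dt, n_p)
    ids = np.tile(np.arange(n_p), n_t)
    flat = trajectory.reshape(-1, 3)
    df = pd.DataFrame({
        "time_s": t, "id": ids,
        "x_nm": flat[:, 0], "y_nm": flat[:, 1], "z_nm": flat[:, 2],
    })
    if statuses is not None:
        df["status"] = np.tile(statuses, n_t)
    df.to_csv(path, index=False)


def write_rbc_profile_csv(path: str | Path, rbc, n_points: int = 64) -> None:
    """Export a cell boundary profile as an (r_nm, z_nm) CSV polyline."""
    prof = rbc.boundary_profile(n_points)
    pd.DataFrame(prof, columns=["r_nm", "z_nm"]).to_csv(path, index=False)


def write_event_log_csv(path: str | Path, ledger) -> None:
    pd.DataFrame(ledger.events,
                 columns=["time_s", "particle_id", "pore_id", "event"]
                 ).to_csv(path, index=False)


def write_vtk(field: FlowField, path: str | Path) -> None:
    """Legacy-ASCII VTK snapshot of the (r, z) field for heat maps.

    Point data: velocity (v_r, v_z, 0) in um/s, pressure in Pa, and the
    per-point dispersion factor.
    """
    mesh = field.mesh
    n = mesh.n_nodes
    with np.errstate(invalid="ignore", divide="ignore"):
        df = np.where(field.v_z != 0.0,
                      np.abs(field.v_r) / field.v_z, 0.0)
    out = [
        "# vtk DataFile Version 3.0",
        "capsim axisymmetric flow field (r z plane, lengths nm)",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {n} float",
    ]
    for r, z in mesh.nodes:
        out.append(f"{r:.6g} {z:.6g} 0")
    ne = mesh.n_elements
    out.append(f"CELLS {ne} {4 * ne}")
    for tri in mesh.elements:
        out.append(f"3 {tri[0]} {tri[1]} {tri[2]}")
    out.append(f"CELL_TYPES {ne}")
    out.extend(["5"] * ne)
    out.append(f"POINT_DATA {n}")
    out.append("VECTORS velocity float")
    for vr, vz in zip(field.v_r, field.v_z):
        out.append(f"{vr:.6g} {vz:.6g} 0")
    out.append("SCALARS pressure float 1")
    out.append("LOOKUP_TABLE default")
    out.extend(f"{p:.6g}" for p in field.pressure)
    out.append("SCALARS dispersion_factor float 1")
    out.append("LOOKUP_TABLE default")
    out.extend(f"{v:.6g}" for v in df)
    Path(path).write_text("\n".join(out) + "\n")


def write_run_outputs(result, out_dir: str | Path) -> None:
    """Standard run directory: config copy, run log, metrics JSON, event
    log CSV, VTK flow field, and trajectories when recorded."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_config(result.config, out / "config.toml")
    sim = result.sim
    (out / "run.log").write_text("\n".join([
        f"seed: {result.config.seed}",
        f"haematocrit: {result.config.haematocrit}",
        f"n_rbcs: {len(sim.rbcs)}",
        f"rbc_speed_um_s: {sim.rbc_speed!r}",
        f"n_particles: {len(result.state.radii)}",
        f"n_fenestrations: {len(sim.fenestrations)}",
        f"steps: {result.state.step_index}",
        f"time_s: {result.state.time!r}",
        "",
    ]))
    (out / "metrics.json").write_text(metrics_json(result.metrics_summary()))
    write_event_log_csv(out / "events.csv", result.state.ledger)
    write_vtk(result.sim.flow, out / "flow_field.vtk")
    if result.sim.trajectory:
        write_trajectories_csv(out / "trajectories.csv",
                               result.trajectory_array(),
                               result.config.time.dt_s,
                               statuses=result.state.status)
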