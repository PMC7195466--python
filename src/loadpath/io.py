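"""Readers and writers for every artifact type (TSV + JSON, lossless).

Every file opens with a ``#``-prefixed header block carrying the tool
version, the study config hash and seed where applicable, the unit
conventions (lengths in A, energies in kcal/mol, harmonic bias
V = k|x - c|^2), and the row count.  Reads validate the schema: a missing
column or a truncated body raises :class:`SchemaError` naming the problem,
never a silent partial load.  Numeric values are written with 17 significant
digits, so write -> read round-trips are exact.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
from pathlib import Path as FilePath
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .dynamics import Trajectory
from .ensembles import RMSFTable
from .fixtures import CoordinateEnsemble, KineticsDataset
from .free_energy import GridSpec, PMFGrid
from .kinetics import MMFit
from .pathways import BarrierReport, Minimum, Path
from .reus import ExchangeLog, WindowSamples

__all__ = [
    "SchemaError",
    "write_trajectory", "read_trajectory",
    "write_window_samples", "read_window_samples",
    "write_exchange_log",
    "write_pmf", "read_pmf",
    "write_path", "read_path",
    "write_barrier_report", "read_barrier_report",
    "write_kinetics", "read_kinetics",
    "write_mmfit", "read_mmfit",
    "write_ensemble", "read_ensemble",
    "write_rmsf_table",
    "file_sha256",
]

_UNITS_NOTE = "lengths A; energies kcal/mol; bias convention V = k*|x-c|^2"


class SchemaError(ValueError):
    """An artifact file does not match its declared schema."""


def _header_lines(meta: dict[str, Any], n_rows: int) -> list[str]:
    lines = [f"# loadpath {__version__}", f"# units: {_UNITS_NOTE}"]
    for key, value in meta.items():
        lines.append(f"# {key}: {json.dumps(value)}")
    lines.append(f"# rows: {n_rows}")
    return lines


def _write_tsv(path, df: pd.DataFrame, meta: dict[str, Any]) -> None:
    path = FilePath(path)
    buf = _io.StringIO()
    df.to_csv(buf, sep="\t", index=False, float_format="%.17g")
    body = buf.getvalue()
    header = "\n".join(_header_lines(meta, len(df)))
    path.write_text(header + "\n" + body)


def _read_tsv(path, required: list[str]) -> tuple[pd.DataFrame, dict[str, Any]]:
    path = FilePath(path)
    meta: dict[str, Any] = {}
    with path.open() as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if not line.startswith("#"):
            body_start = i
            break
        stripped = line[1:].strip()
        if ":" in stripped:
            key, _, val = stripped.partition(":")
            try:
                meta[key.strip()] = json.loads(val.strip())
            except json.JSONDecodeError:
                meta[key.strip()] = val.strip()
    else:
        raise SchemaError(f"{path}: no table body found")
    df = pd.read_csv(
        _io.StringIO("".join(lines[body_start:])),
        sep="\t",
        float_precision="round_trip",
    )
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    declared = meta.get("rows")
    if declared is None:
        raise SchemaError(f"{path}: header lacks a row count")
    if int(declared) != len(df):
        raise SchemaError(
            f"{path}: declared {declared} rows but found {len(df)} (truncated?)"
        )
    return df, meta


def file_sha256(path) -> str:
    return hashlib.sha256(FilePath(path).read_bytes()).hexdigest()


# --- trajectories -----------------------------------------------------------

def write_trajectory(path, traj: Trajectory, extra_meta: dict | None = None) -> None:
    d = traj.positions.shape[1]
    df = pd.DataFrame({"time": traj.times})
    for k in range(d):
        df[f"cv_{k + 1}"] = traj.positions[:, k]
    df["bias_energy"] = traj.bias_energies
    meta = {
        "type": "trajectory",
        "seed": traj.seed,
        "dt": traj.dt,
        "friction": traj.friction,
        "kT": traj.kT,
        "stride": traj.stride,
        "dim": d,
        **(extra_meta or {}),
    }
    _write_tsv(path, df, meta)


def read_trajectory(path) -> Trajectory:
    df, meta = _read_tsv(path, ["time", "cv_1", "bias_energy"])
    d = int(meta.get("dim", 1))
    cols = [f"cv_{k + 1}" for k in range(d)]
    for c in cols:
        if c not in df.columns:
            raise SchemaError(f"{path}: missing required column {c!r}")
    return Trajectory(
        times=df["time"].to_numpy(),
        positions=df[cols].to_numpy(),
        bias_energies=df["bias_energy"].to_numpy(),
        seed=int(meta["seed"]),
        dt=float(meta["dt"]),
        friction=float(meta["friction"]),
        kT=float(meta["kT"]),
        stride=int(meta["stride"]),
        metadata=meta,
    )


# --- window samples + exchange log -----------------------------------------

def write_window_samples(path, ws: WindowSamples, extra_meta: dict | None = None) -> None:
    rows = []
    for w, (xs, reps, ts) in enumerate(zip(ws.samples, ws.replica_ids, ws.times)):
        for x, r, t in zip(xs, reps, ts):
            rows.append((w, int(r), float(t), *[float(v) for v in x]))
    d = ws.samples[0].shape[1]
    cols = ["window_id", "replica_id", "time"] + [f"cv_{k + 1}" for k in range(d)]
    df = pd.DataFrame(rows, columns=cols)
    meta = {"type": "window_samples", "kT": ws.kT, "dim": d, **ws.metadata,
            **(extra_meta or {})}
    _write_tsv(path, df, meta)


def read_window_samples(path) -> WindowSamples:
    df, meta = _read_tsv(path, ["window_id", "replica_id", "time", "cv_1"])
    d = int(meta.get("dim", 1))
    cols = [f"cv_{k + 1}" for k in range(d)]
    n_windows = int(df["window_id"].max()) + 1
    samples, reps, times = [], [], []
    for w in range(n_windows):
        sub = df[df["window_id"] == w]
        samples.append(sub[cols].to_numpy())
        reps.append(sub["replica_id"].to_numpy(dtype=int))
        times.append(sub["time"].to_numpy())
    return WindowSamples(
        samples=samples,
        replica_ids=reps,
        times=times,
        exchange_log=ExchangeLog(n_edges=n_windows),
        kT=float(meta["kT"]),
        metadata=meta,
    )


def write_exchange_log(path, log: ExchangeLog, extra_meta: dict | None = None) -> None:
    df = pd.DataFrame(log.records, columns=["sweep", "edge", "accepted"])
    meta = {
        "type": "exchange_log",
        "attempts": log.attempts.tolist(),
        "accepts": log.accepts.tolist(),
        **(extra_meta or {}),
    }
    _write_tsv(path, df, meta)


# --- PMF grids ---------------------------------------------------------------

def write_pmf(path, pmf: PMFGrid, extra_meta: dict | None = None) -> None:
    nx, ny = pmf.grid.shape
    ii, jj = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    df = pd.DataFrame(
        {
            "i": ii.ravel(),
            "j": jj.ravel(),
            "free_energy": pmf.values.ravel(),
            "count": pmf.counts.ravel(),
        }
    )
    meta = {
        "type": "pmf",
        "origin": list(pmf.grid.origin),
        "spacing": list(pmf.grid.spacing),
        "shape": list(pmf.grid.shape),
        "kT": pmf.kT,
        **{k: v for k, v in pmf.metadata.items() if _jsonable(v)},
        **(extra_meta or {}),
    }
    _write_tsv(path, df, meta)


def read_pmf(path) -> PMFGrid:
    df, meta = _read_tsv(path, ["i", "j", "free_energy", "count"])
    shape = tuple(int(v) for v in meta["shape"])
    grid = GridSpec(
        origin=tuple(float(v) for v in meta["origin"]),
        spacing=tuple(float(v) for v in meta["spacing"]),
        shape=shape,  # type: ignore[arg-type]
    )
    values = np.full(shape, np.nan)
    counts = np.zeros(shape, dtype=int)
    values[df["i"].to_numpy(), df["j"].to_numpy()] = df["free_energy"].to_numpy()
    counts[df["i"].to_numpy(), df["j"].to_numpy()] = df["count"].to_numpy()
    return PMFGrid(grid=grid, values=values, counts=counts, kT=float(meta["kT"]),
                   metadata=meta)


# --- paths + barrier reports -------------------------------------------------

def write_path(path_file, p: Path, extra_meta: dict | None = None) -> None:
    df = pd.DataFrame(
        {
            "index": np.arange(p.points.shape[0]),
            "x": p.points[:, 0],
            "y": p.points[:, 1],
            "free_energy": p.energies,
        }
    )
    ends = [
        {"cell": list(m.cell), "point": list(m.point), "value": m.value}
        for m in p.endpoints
    ]
    meta = {
        "type": "mfep_path",
        "branch": p.branch,
        "converged": p.converged,
        "endpoints": ends,
        **(extra_meta or {}),
    }
    _write_tsv(path_file, df, meta)


def read_path(path_file) -> Path:
    df, meta = _read_tsv(path_file, ["index", "x", "y", "free_energy"])
    ends = tuple(
        Minimum(cell=tuple(e["cell"]), point=tuple(e["point"]), value=e["value"])
        for e in meta["endpoints"]
    )
    return Path(
        points=df[["x", "y"]].to_numpy(),
        energies=df["free_energy"].to_numpy(),
        branch=str(meta["branch"]),
        endpoints=ends,  # type: ignore[arg-type]
        converged=bool(meta["converged"]),
        metadata=meta,
    )


def write_barrier_report(path, report: BarrierReport, extra_meta: dict | None = None) -> None:
    payload = {
        "tool": f"loadpath {__version__}",
        "units": _UNITS_NOTE,
        "peak_kcal_mol": report.peak,
        "baseline_kcal_mol": report.baseline,
        "barrier_kcal_mol": report.barrier,
        "branch": report.branch,
        **(extra_meta or {}),
    }
    FilePath(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_barrier_report(path) -> BarrierReport:
    payload = json.loads(FilePath(path).read_text())
    try:
        return BarrierReport(
            peak=payload["peak_kcal_mol"],
            baseline=payload["baseline_kcal_mol"],
            barrier=payload["barrier_kcal_mol"],
            branch=payload["branch"],
        )
    except KeyError as exc:
        raise SchemaError(f"{path}: missing field {exc}") from None


# --- kinetics ----------------------------------------------------------------

def write_kinetics(path, datasets: list[KineticsDataset], extra_meta: dict | None = None) -> None:
    rows = []
    for ds in datasets:
        for rep in range(ds.n_replicates):
            for c, r in zip(ds.concentrations, ds.rates[rep]):
                rows.append((float(c), float(r), rep, ds.species))
    df = pd.DataFrame(rows, columns=["concentration_M", "rate", "replicate", "species"])
    meta = {
        "type": "kinetics",
        "datasets": [
            {"species": ds.species, **{k: v for k, v in ds.metadata.items() if _jsonable(v)}}
            for ds in datasets
        ],
        **(extra_meta or {}),
    }
    _write_tsv(path, df, meta)


def read_kinetics(path) -> list[KineticsDataset]:
    df, meta = _read_tsv(path, ["concentration_M", "rate", "replicate", "species"])
    out = []
    ds_meta = {d["species"]: d for d in meta.get("datasets", [])}
    for species, sub in df.groupby("species", sort=False):
        conc = np.sort(sub["concentration_M"].unique())
        reps = sorted(sub["replicate"].unique())
        rates = np.empty((len(reps), conc.size))
        for ri, rep in enumerate(reps):
            rsub = sub[sub["replicate"] == rep].sort_values("concentration_M")
            rates[ri] = rsub["rate"].to_numpy()
        out.append(
            KineticsDataset(
                concentrations=conc,
                rates=rates,
                species=str(species),
                metadata=ds_meta.get(species, {}),
            )
        )
    return out


def write_mmfit(path, fit: MMFit, extra_meta: dict | None = None) -> None:
    payload = {
        "tool": f"loadpath {__version__}",
        "Km_M": fit.Km,
        "Vmax": fit.Vmax,
        "se_Km": fit.se_Km,
        "se_Vmax": fit.se_Vmax,
        "method": fit.method,
        "species": fit.species,
        "diagnostics": {k: v for k, v in fit.diagnostics.items() if _jsonable(v)},
        **(extra_meta or {}),
    }
    FilePath(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_mmfit(path) -> MMFit:
    payload = json.loads(FilePath(path).read_text())
    try:
        return MMFit(
            Km=payload["Km_M"],
            Vmax=payload["Vmax"],
            se_Km=payload["se_Km"],
            se_Vmax=payload["se_Vmax"],
            method=payload["method"],
            species=payload.get("species", ""),
            diagnostics=payload.get("diagnostics", {}),
        )
    except KeyError as exc:
        raise SchemaError(f"{path}: missing field {exc}") from None


# --- coordinate ensembles and RMSF tables -----------------------------------

def write_ensemble(path, ens: CoordinateEnsemble, extra_meta: dict | None = None) -> None:
    f, s, _ = ens.coords.shape
    frames = np.repeat(np.arange(f), s)
    sites = np.tile(ens.site_labels, f)
    flat = ens.coords.reshape(f * s, 3)
    df = pd.DataFrame(
        {
            "run": ens.run_index,
            "frame": frames,
            "site": sites,
            "x": flat[:, 0],
            "y": flat[:, 1],
            "z": flat[:, 2],
        }
    )
    meta = {
        "type": "ensemble",
        "time_per_frame": ens.time_per_frame,
        "n_frames": f,
        "n_sites": s,
        **{k: v for k, v in ens.metadata.items() if _jsonable(v)},
        **(extra_meta or {}),
    }
    _write_tsv(path, df, meta)


def read_ensemble(path) -> CoordinateEnsemble:
    df, meta = _read_tsv(path, ["run", "frame", "site", "x", "y", "z"])
    f = int(meta["n_frames"])
    s = int(meta["n_sites"])
    coords = df[["x", "y", "z"]].to_numpy().reshape(f, s, 3)
    labels = df["site"].to_numpy()[:s]
    return CoordinateEnsemble(
        coords=coords,
        site_labels=labels,
        time_per_frame=float(meta["time_per_frame"]),
        run_index=int(df["run"].iloc[0]),
        metadata=meta,
    )


def write_rmsf_table(path, table: RMSFTable, extra_meta: dict | None = None) -> None:
    n_runs, n_windows, n_sites = table.per_run.shape
    rows = []
    for r in range(n_runs):
        for w in range(n_windows):
            for s in range(n_sites):
                rows.append((r, w, int(table.site_labels[s]), table.per_run[r, w, s]))
    avg = table.run_average
    for w in range(n_windows):
        for s in range(n_sites):
            rows.append((-1, w, int(table.site_labels[s]), avg[w, s]))
    df = pd.DataFrame(rows, columns=["run", "window", "site", "rmsf"])
    meta = {
        "type": "rmsf",
        "window_frames": table.window_frames,
        "run_average_run_id": -1,
        "dropped_frames_per_run": list(table.dropped_frames_per_run),
        **(extra_meta or {}),
    }
    _write_tsv(path, df, meta)


def _jsonable(v: Any) -> bool:
    try:
        json.dumps(v)
        return True
    except (TypeError, ValueError):
        return False
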