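"""File readers and writers: tidy trace tables, coordinate files, reports.

Traces travel as tidy long-format TSV/CSV (one row per time point, columns
``temperature_K``, ``replicate``, ``time_min``, ``fluorescence``,
``triton_reference``); coordinate snapshots as PDB (multi-frame via MODEL
records) or GRO through MDAnalysis; reports as JSON and configs as YAML.
All writes are atomic (write to a temporary sibling, then rename).
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import tempfile
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .defects import BilayerSnapshot
from .errors import SchemaError
from .kinetics import DequenchingTrace

__all__ = [
    "REQUIRED_TRACE_COLUMNS",
    "read_trace_table",
    "write_trace_table",
    "read_snapshots",
    "write_pdb",
    "atomic_write_text",
    "write_json",
    "read_yaml",
    "config_hash",
]

logger = logging.getLogger("fuse_kinetics")

REQUIRED_TRACE_COLUMNS = (
    "temperature_K",
    "replicate",
    "time_min",
    "fluorescence",
    "triton_reference",
)


def _read_table(path) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    return pd.read_csv(path, sep=sep)


def read_trace_table(path) -> list[DequenchingTrace]:
    """Load dequenching traces from a tidy TSV/CSV table.

    Rows are grouped by (temperature_K, replicate).  Malformed rows
    (non-numeric time or fluorescence) are dropped with a logged count;
    groups with a missing triton reference are excluded with a warning.

    Raises
    ------
    SchemaError
        If a required column is absent.
    """
    df = _read_table(path)
    missing = [c for c in REQUIRED_TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"trace table {path} is missing columns: {missing}")
    n_raw = len(df)
    for col in ("temperature_K", "time_min", "fluorescence", "triton_reference"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df = df.dropna(subset=["temperature_K", "time_min", "fluorescence"])
    n_dropped = n_raw - len(df)
    if n_dropped:
        logger.warning("dropped %d malformed row(s) from %s", n_dropped, path)

    traces = []
    for (temp, rep), group in df.groupby(["temperature_K", "replicate"], sort=True):
        group = group.sort_values("time_min")
        triton = group["triton_reference"].dropna().unique()
        if triton.size == 0:
            warnings.warn(
                f"trace (T={temp} K, replicate {rep}) has no triton reference; "
                "excluded",
                stacklevel=2,
            )
            continue
        traces.append(
            DequenchingTrace(
                times=group["time_min"].to_numpy(),
                fluorescence=group["fluorescence"].to_numpy(),
                triton_reference=float(triton[0]),
                temperature=float(temp),
                replicate=rep if not isinstance(rep, np.generic) else rep.item(),
                label=f"{temp}K/rep{rep}",
            )
        )
    return traces


def write_trace_table(traces, path) -> None:
    """Write traces as a tidy long-format table (TSV, or CSV by extension)."""
    frames = []
    for trace in traces:
        frames.append(
            pd.DataFrame(
                {
                    "temperature_K": trace.temperature,
                    "replicate": trace.replicate,
                    "time_min": trace.times,
                    "fluorescence": trace.fluorescence,
                    "triton_reference": trace.triton_reference,
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)
    sep = "," if str(path).endswith(".csv") else "\t"
    atomic_write_text(path, df.to_csv(index=False, sep=sep))


def read_snapshots(path) -> list[BilayerSnapshot]:
    """Read coordinate frames from a PDB (multi-MODEL) or GRO file."""
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
        snapshots = []
        for i, ts in enumerate(u.trajectory):
            snapshots.append(
                BilayerSnapshot(
                    names=u.atoms.names.astype(object),
                    resnames=u.atoms.resnames.astype(object),
                    resids=u.atoms.resids.copy(),
                    xyz=u.atoms.positions.astype(float),
                    box=ts.dimensions[:3].astype(float),
                    frame_id=i,
                )
            )
    return snapshots


def write_pdb(snapshot: BilayerSnapshot, path) -> None:
    """Write one snapshot as a PDB file (CRYST1 carries the box)."""
    import MDAnalysis as mda

    n = snapshot.n_atoms
    resids, resindex = np.unique(snapshot.resids, return_inverse=True)
    u = mda.Universe.empty(
        n, n_residues=resids.size, atom_resindex=resindex, trajectory=True
    )
    u.add_TopologyAttr("names", snapshot.names.astype(str))
    resnames = np.empty(resids.size, dtype=object)
    resnames[resindex] = snapshot.resnames
    u.add_TopologyAttr("resnames", resnames.astype(str))
    u.add_TopologyAttr("resids", resids)
    u.atoms.positions = snapshot.xyz
    u.dimensions = [snapshot.box[0], snapshot.box[1], snapshot.box[2], 90, 90, 90]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))


def atomic_write_text(path, text: str) -> None:
    """Write text to ``path`` via a temporary sibling and an atomic rename."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_json(payload: dict, path) -> None:
    atomic_write_text(path, json.dumps(payload, indent=2, default=_json_default) + "\n")


def read_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def config_hash(config: dict) -> str:
    """Stable sha256 over the canonical JSON form of a config mapping."""
    blob = json.dumps(config, sort_keys=True, default=_json_default)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]
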