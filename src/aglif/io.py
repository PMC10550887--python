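"""File formats: rasters, protocols, traces, parameters and fit results.

All tabular files are comma-separated CSV with mandatory headers, '.'
decimal and UTF-8 encoding; times are in ms and currents in pA.  Writers are
deterministic: stable key order and fixed float formatting (12 significant
digits), so identical inputs produce byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import DimensionalParameters, complete_parameters
from .optimize import FitResult
from .simulate import StimulusProtocol, TraceRecord
from .update_rules import BlockRule, MonodCoefficients, SpikeRaster

__all__ = [
    "SchemaError",
    "load_raster",
    "save_raster",
    "load_protocol",
    "save_trace",
    "load_parameters",
    "save_parameters",
    "save_fit",
    "load_fit",
    "write_manifest",
]

logger = logging.getLogger(__name__)

FIT_SCHEMA_VERSION = 1

RASTER_COLUMNS = ["cell_id", "I_pA", "spike_time_ms"]
PROTOCOL_COLUMNS = ["t_begin_ms", "t_end_ms", "I_pA"]


class SchemaError(ValueError):
    """A file does not match its expected schema."""


def _fmt(x: float) -> str:
    return f"{float(x):.12g}"


def load_raster(path, T: float | None = None) -> SpikeRaster:
    """Read a spike raster CSV (columns cell_id, I_pA, spike_time_ms)."""
    df = pd.read_csv(path)
    missing = [c for c in RASTER_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    cells = df["cell_id"].unique()
    if len(cells) != 1:
        raise SchemaError(f"{path}: expected a single cell, found {list(cells)}")
    trains: dict[float, np.ndarray] = {}
    for I, grp in df.groupby("I_pA"):
        ts = grp["spike_time_ms"].to_numpy(dtype=float)
        if np.any(np.diff(ts) < 0):
            warnings.warn(f"{path}: out-of-order spike times at {I} pA; sorting")
            ts = np.sort(ts)
        if np.any(np.diff(ts) == 0):
            warnings.warn(f"{path}: duplicate spike times at {I} pA")
        trains[float(I)] = ts
    Tmax = T if T is not None else (float(df["spike_time_ms"].max()) if len(df) else 0.0)
    return SpikeRaster(trains=trains, cell_id=str(cells[0]), T=Tmax)


def save_raster(raster: SpikeRaster, path) -> None:
    rows = ["cell_id,I_pA,spike_time_ms"]
    for I in raster.currents():
        for t in raster.spikes(I):
            rows.append(f"{raster.cell_id},{_fmt(I)},{_fmt(t)}")
    Path(path).write_text("\n".join(rows) + "\n")


def load_protocol(path) -> StimulusProtocol:
    """Read a piecewise-constant protocol from JSON or CSV."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        data = json.loads(path.read_text())
        segs = [(s["t_begin_ms"], s["t_end_ms"], s["I_pA"]) for s in data["segments"]]
    else:
        df = pd.read_csv(path)
        missing = [c for c in PROTOCOL_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"{path}: missing column(s) {missing}")
        segs = list(df[PROTOCOL_COLUMNS].itertuples(index=False, name=None))
    return StimulusProtocol(segments=tuple((float(a), float(b), float(I)) for a, b, I in segs))


def save_trace(trace: TraceRecord, path) -> None:
    rows = ["t_ms,V_mV,Iadap_pA,Idep_pA"]
    for t, v, ia, idp in zip(trace.t, trace.V, trace.I_adap, trace.I_dep):
        rows.append(",".join(_fmt(x) for x in (t, v, ia, idp)))
    Path(path).write_text("\n".join(rows) + "\n")


def load_parameters(path) -> DimensionalParameters:
    """Load a parameter file (YAML or JSON) and complete/validate it."""
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise SchemaError(f"{path}: expected a mapping of parameter names")
    return complete_parameters(raw)


def save_parameters(p: DimensionalParameters, path) -> None:
    path = Path(path)
    data = {k: float(v) for k, v in sorted(p.to_dict().items())}
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=True))


def save_fit(fit: FitResult, path) -> None:
    payload = {
        "schema_version": FIT_SCHEMA_VERSION,
        "parameters": {k: float(v) for k, v in sorted(fit.parameters.to_dict().items())},
        "monod": fit.monod.to_dict(),
        "block_rule": fit.block_rule.to_dict() if fit.block_rule else None,
        "iadap_sequences": {
            _fmt(I): [[_fmt(t), _fmt(v)] for t, v in seq]
            for I, seq in sorted(fit.iadap_sequences.items())
        },
        "cost": fit.cost,
        "generations_run": fit.generations_run,
        "seed": fit.seed,
        "best_cost_trace": list(fit.best_cost_trace),
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def load_fit(path) -> FitResult:
    data = json.loads(Path(path).read_text())
    version = data.get("schema_version")
    if version != FIT_SCHEMA_VERSION:
        raise SchemaError(
            f"{path}: fit schema version {version!r} not supported "
            f"(expected {FIT_SCHEMA_VERSION})"
        )
    params = complete_parameters(data["parameters"])
    m = data["monod"]
    block = BlockRule.from_dict(data["block_rule"]) if data.get("block_rule") else None
    sequences = {
        float(I): [(float(t), float(v)) for t, v in seq]
        for I, seq in data["iadap_sequences"].items()
    }
    return FitResult(
        parameters=params,
        iadap_sequences=sequences,
        monod=MonodCoefficients(**m),
        block_rule=block,
        cost=float(data["cost"]),
        generations_run=int(data["generations_run"]),
        seed=int(data["seed"]),
        best_cost_trace=tuple(data.get("best_cost_trace", ())),
    )


def write_manifest(out_dir, command: str, seed, inputs: dict | None = None,
                   outputs: dict | None = None) -> Path:
    """Write the per-run manifest (command, seed, version, file digests)."""
    from datetime import datetime, timezone

    from . import __version__

    def digest(p) -> str:
        return hashlib.sha256(Path(p).read_bytes()).hexdigest()[:16]

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "seed": seed,
        "package_version": __version__,
        "timestamp_utc": datetime.now(timezone.utc).isoformat(),
        "inputs": {k: digest(v) for k, v in (inputs or {}).items()},
        "outputs": {k: digest(v) for k, v in (outputs or {}).items()},
    }
    path = out_dir / "run_manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path
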