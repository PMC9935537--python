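"""Readers/writers for trace CSVs, dataset manifests and result JSON.

Numbers are serialised with 17 significant digits so that a
write -> read -> write round trip is byte-identical.
"""

from __future__ import annotations

import json
import os
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .network import STRANDS
from .ramp import Trace

__all__ = [
    "write_trace_csv",
    "read_trace_csv",
    "write_dataset",
    "read_dataset",
    "write_json",
    "read_json",
]

_FLOAT_FMT = "%.17g"


def write_trace_csv(trace: Trace, path: os.PathLike | str) -> None:
    """Write a trace as CSV (time_s, temperature_C, absorbance_AU [+ species])."""
    cols: Dict[str, np.ndarray] = {
        "time_s": trace.time,
        "temperature_C": trace.temperature_C,
        "absorbance_AU": trace.absorbance_AU,
    }
    if trace.species is not None and trace.species_labels is not None:
        for i, s in enumerate(trace.species_labels):
            cols[f"conc_M_{s}"] = trace.species[:, i]
    pd.DataFrame(cols).to_csv(path, index=False, float_format=_FLOAT_FMT,
                              lineterminator="\n")


def read_trace_csv(
    path: os.PathLike | str, conditions: Optional[Dict[str, object]] = None
) -> Trace:
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:
        raise ValueError(f"malformed trace CSV {path}: {exc}") from exc
    for col in ("time_s", "temperature_C", "absorbance_AU"):
        if col not in df.columns:
            raise ValueError(f"trace CSV {path} lacks column {col!r}")
    species_cols = [c for c in df.columns if c.startswith("conc_M_")]
    labels = tuple(c[len("conc_M_"):] for c in species_cols)
    for lab in labels:
        if lab not in STRANDS:
            raise ValueError(f"trace CSV {path} has unknown species column {lab!r}")
    return Trace(
        time=df["time_s"].to_numpy(),
        temperature_C=df["temperature_C"].to_numpy(),
        absorbance_AU=df["absorbance_AU"].to_numpy(),
        species=df[species_cols].to_numpy() if species_cols else None,
        species_labels=labels or None,
        conditions=dict(conditions or {}),
    )


def write_json(payload: Dict[str, object], path: os.PathLike | str) -> None:
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_json(path: os.PathLike | str) -> Dict[str, object]:
    try:
        return json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed JSON {path}: {exc}") from exc


def write_dataset(
    traces: Sequence[Trace], manifest: Dict[str, object], out_dir: os.PathLike | str
) -> Path:
    """Write a manifest + one CSV per trace into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = manifest["traces"]
    if len(entries) != len(traces):
        raise ValueError("manifest entries and traces differ in number")
    for entry, trace in zip(entries, traces):
        write_trace_csv(trace, out / entry["file"])
    write_json(manifest, out / "manifest.json")
    return out / "manifest.json"


def read_dataset(manifest_path: os.PathLike | str) -> Tuple[List[Trace], Dict[str, object]]:
    """Read a manifest and its trace CSVs; conditions come from the manifest."""
    manifest_path = Path(manifest_path)
    if manifest_path.is_dir():
        manifest_path = manifest_path / "manifest.json"
    manifest = read_json(manifest_path)
    traces = []
    for entry in manifest["traces"]:
        cond = {
            "trace_id": entry["trace_id"],
            "C_tot_strand": entry["C_tot_strand_uM"] * 1e-6,
            "C_tot_strand_uM": entry["C_tot_strand_uM"],
            "rate_C_per_min": entry["rate_C_per_min"],
            "direction": entry["direction"],
            "path_length_cm": entry["path_length_cm"],
            "init_protocol": entry["init_protocol"],
        }
        traces.append(read_trace_csv(manifest_path.parent / entry["file"], cond))
    return traces, manifest
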