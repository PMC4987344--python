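"""File formats: sweep-table CSV with JSON sidecar, and tabular exports.

A sweep table is a plain CSV whose first column is time in seconds and whose
remaining columns are sweeps named by stimulus amplitude in pA (e.g. "-50",
"300").  A JSON sidecar with the same stem carries the metadata: cell id,
clamp mode, units, sampling rate, the protocol definition, condition,
internal-solution flags and synthetic-data provenance.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Iterable

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES, IntrinsicFeatures
from .recordings import StimulusProtocol, SweepSet

__all__ = [
    "write_sweepset",
    "read_sweepset",
    "sidecar_path",
    "write_features_tsv",
    "read_features_tsv",
    "write_assignments_tsv",
]


def sidecar_path(csv_path: str | Path) -> Path:
    return Path(csv_path).with_suffix(".json")


def write_sweepset(sweepset: SweepSet, csv_path: str | Path) -> Path:
    """Write a sweep table and its JSON sidecar; returns the CSV path."""
    csv_path = Path(csv_path)
    proto = sweepset.protocol
    amps = sweepset.amplitudes
    table = pd.DataFrame({"time_s": sweepset.time()})
    for amp in amps:
        table[f"{amp:g}"] = sweepset.get(amp)
    table.to_csv(csv_path, index=False, float_format="%.6g")

    meta: dict[str, Any] = {
        "cell_id": sweepset.cell_id,
        "clamp_mode": sweepset.clamp_mode,
        "units": sweepset.units,
        "sampling_rate": proto.sampling_rate,
        "protocol": proto.to_dict(),
        "amplitudes": [float(a) for a in amps],
    }
    for key in ("condition", "qx314", "seed", "provenance", "spike_times"):
        if key in sweepset.meta:
            meta[key] = sweepset.meta[key]
    sidecar_path(csv_path).write_text(json.dumps(meta, indent=1, sort_keys=True))
    return csv_path


def read_sweepset(csv_path: str | Path) -> SweepSet:
    """Read a sweep table + sidecar back into a :class:`SweepSet`.

    Validates that the sidecar amplitudes match the CSV headers and that the
    row count equals sampling rate x duration.
    """
    csv_path = Path(csv_path)
    side = sidecar_path(csv_path)
    if not side.exists():
        raise FileNotFoundError(f"missing JSON sidecar for {csv_path}")
    meta = json.loads(side.read_text())
    table = pd.read_csv(csv_path)
    proto = StimulusProtocol.from_dict(meta["protocol"])

    header_amps = sorted(float(c) for c in table.columns if c != "time_s")
    sidecar_amps = sorted(float(a) for a in meta["amplitudes"])
    if len(header_amps) != len(sidecar_amps) or not np.allclose(
        header_amps, sidecar_amps
    ):
        raise ValueError(
            f"{csv_path}: sweep columns {header_amps} do not match sidecar "
            f"amplitudes {sidecar_amps}"
        )
    if len(table) != proto.n_samples:
        raise ValueError(
            f"{csv_path}: {len(table)} rows but protocol defines "
            f"{proto.n_samples} samples"
        )
    sweeps = {
        float(c): table[c].to_numpy(dtype=float)
        for c in table.columns
        if c != "time_s"
    }
    extra = {
        k: meta[k]
        for k in ("condition", "qx314", "seed", "provenance", "spike_times")
        if k in meta
    }
    return SweepSet(
        protocol=proto,
        sweeps=sweeps,
        units=meta.get("units", "mV"),
        clamp_mode=meta.get("clamp_mode", "current"),
        cell_id=meta.get("cell_id", csv_path.stem),
        meta=extra,
    )


def write_features_tsv(records: Iterable, path: str | Path) -> Path:
    """One row per cell: identity, eight features and validity flags."""
    rows = []
    for rec in records:
        feats = rec.features if rec.features is not None else IntrinsicFeatures()
        rows.append(
            {
                "cell_id": rec.cell_id,
                "label": rec.label,
                "layer": rec.layer,
                "benchmark": rec.benchmark,
            }
            | feats.to_dict()
        )
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path


def read_features_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in FEATURE_NAMES if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing feature columns {missing}")
    return df.set_index("cell_id")


def write_assignments_tsv(assignment, path: str | Path, stage: int = 0) -> Path:
    rows = [
        {
            "cell_id": cid,
            "stage": stage,
            "cluster": cl,
            "cluster_name": assignment.cluster_names.get(cl, ""),
            "misclassified": cid in assignment.misclassified,
        }
        for cid, cl in assignment.labels.items()
    ]
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path
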