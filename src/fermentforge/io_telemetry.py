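"""Curve file formats and IoT telemetry payloads.

CSV is the canonical on-disk format for fermentation curves (columns
``time_h, biomass_gL, sugar_gL, co2, pH, temp_C, alcohol_gL``); the
interchange format mirrors the ThingsBoard device-telemetry JSON
convention — one ``{"ts": epoch_ms, "values": {...}}`` record per
sampling instant.  Only payload encode/decode is implemented; transport
is out of scope.
"""

from __future__ import annotations

import json
import logging
import math

import numpy as np
import pandas as pd

from .simulator import ATTRIBUTES, FermentationCurve

__all__ = [
    "TelemetryRecord",
    "curve_to_telemetry",
    "telemetry_to_curve",
    "write_curve_csv",
    "read_curve_csv",
    "write_telemetry_jsonl",
    "read_telemetry_jsonl",
]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("time_h", "biomass_gL", "sugar_gL", "co2", "pH", "temp_C")
OPTIONAL_COLUMNS = ("alcohol_gL",)


class TelemetryRecord(dict):
    """A {"ts": epoch_ms, "values": {...}} telemetry payload."""

    def __init__(self, ts: int, values: dict):
        if not isinstance(ts, (int, np.integer)) or ts < 0:
            raise ValueError("ts must be a non-negative integer (epoch ms)")
        if not values:
            raise ValueError("values must be non-empty")
        for key, v in values.items():
            if not math.isfinite(float(v)):
                raise ValueError(f"non-finite telemetry value for {key!r}")
        super().__init__(ts=int(ts), values={k: float(v) for k, v in values.items()})

    @property
    def ts(self) -> int:
        return self["ts"]

    @property
    def values(self) -> dict:
        return self["values"]


def curve_to_telemetry(
    curve: FermentationCurve, start_epoch_ms: int = 0, period_min: float = 5.0
) -> list:
    """One telemetry record per curve sample, spaced ``period_min`` apart."""
    period_ms = int(round(period_min * 60_000))
    records = []
    for i in range(len(curve)):
        values = {col: float(curve.data[col].iloc[i]) for col in curve.data.columns}
        records.append(TelemetryRecord(start_epoch_ms + i * period_ms, values))
    return records


def telemetry_to_curve(records, period_min: float = 5.0) -> FermentationCurve:
    """Rebuild a curve from telemetry records (lossless round trip)."""
    records = list(records)
    if not records:
        raise ValueError("no telemetry records")
    cols = list(records[0]["values"].keys())
    data = pd.DataFrame([r["values"] for r in records], columns=cols)
    time = np.arange(len(records)) * (period_min / 60.0)
    return FermentationCurve(time=time, data=data, metadata={"source": "telemetry"})


def write_telemetry_jsonl(records, path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(json.dumps(rec) + "\n")


def read_telemetry_jsonl(path) -> list:
    records = []
    with open(path) as fh:
        for line in fh:
            if line.strip():
                payload = json.loads(line)
                records.append(TelemetryRecord(payload["ts"], payload["values"]))
    return records


def write_curve_csv(curve: FermentationCurve, path) -> None:
    curve.to_frame().to_csv(path, index=False, float_format="%.10g")


def read_curve_csv(path) -> FermentationCurve:
    """Read a curve CSV; tolerant of extra columns, strict on required ones.

    Malformed (non-numeric) rows are rejected with their line numbers;
    unknown columns are preserved in the curve metadata with a warning.
    """
    frame = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"missing required column(s) {missing} in {path}")
    known = [c for c in (*REQUIRED_COLUMNS, *OPTIONAL_COLUMNS) if c in frame.columns]
    extra = [c for c in frame.columns if c not in known]
    numeric = frame[known].apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1)
    if bad.any():
        lines = [int(i) + 2 for i in frame.index[bad]]  # +2: header + 1-based
        raise ValueError(f"malformed row(s) at line(s) {lines} in {path}")
    metadata = {"source": str(path)}
    if extra:
        logger.warning("preserving unknown column(s) %s in metadata", extra)
        metadata["extra_columns"] = {c: frame[c].tolist() for c in extra}
    attrs = [c for c in ATTRIBUTES if c in numeric.columns]
    return FermentationCurve(
        time=numeric["time_h"].to_numpy(),
        data=numeric[attrs].reset_index(drop=True),
        metadata=metadata,
    )
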