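"""Serialization: records as CSV with a JSON metadata sidecar.

A record ``name.csv`` holds two columns (``time_s``, ``value``) written at
full float precision; ``name.meta.json`` carries the provenance metadata
(age, VFM, wavelength, AC/DC, noise, filter, ADC, heart rate...).  Write
then read reproduces samples bit-for-bit and metadata exactly; a missing
sidecar is an explicit error, not a silent default.
"""

from __future__ import annotations

import json
import os
from pathlib import Path

import numpy as np
import pandas as pd

from .waveform import PPGRecord

__all__ = ["write_record", "read_record", "write_table", "read_table", "sidecar_path"]


def sidecar_path(csv_path: str | Path) -> Path:
    p = Path(csv_path)
    return p.with_suffix(".meta.json")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_record(record: PPGRecord, csv_path: str | Path) -> None:
    """Write samples to CSV (17 significant digits) and metadata to a sidecar."""
    p = Path(csv_path)
    p.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame({"time_s": record.time, "value": record.samples})
    df.to_csv(p, index=False, float_format="%.17g")
    meta = {"fs": record.fs, "n_samples": len(record.samples), "meta": _jsonable(record.meta)}
    with open(sidecar_path(p), "w") as fh:
        json.dump(meta, fh, indent=1)


def read_record(csv_path: str | Path) -> PPGRecord:
    """Read a record; raises FileNotFoundError for a missing sidecar and
    ValueError (with a line number where possible) for malformed content."""
    p = Path(csv_path)
    sc = sidecar_path(p)
    if not sc.exists():
        raise FileNotFoundError(f"metadata sidecar {sc} is missing for {p}")
    with open(sc) as fh:
        meta = json.load(fh)
    try:
        df = pd.read_csv(p, float_precision="round_trip")
    except pd.errors.ParserError as e:
        raise ValueError(f"malformed record CSV {p}: {e}") from e
    if list(df.columns) != ["time_s", "value"]:
        raise ValueError(f"{p}: expected columns time_s,value, found {list(df.columns)}")
    if len(df) != meta["n_samples"]:
        raise ValueError(
            f"{p}: sample count {len(df)} disagrees with sidecar ({meta['n_samples']})"
        )
    return PPGRecord(df["value"].to_numpy(), float(meta["fs"]), meta["meta"])


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.17g")


def read_table(path: str | Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, float_precision="round_trip")
    except pd.errors.ParserError as e:
        raise ValueError(f"malformed table {path}: {e}") from e
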