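"""CSV interfaces for traces, metadata, spectral and calibration tables.

Dialect is fixed for reproducibility: comma separator, dot decimal, UTF-8,
header required, ``\\n`` line endings.  Floats are written with 10
significant digits, which round-trips all quantities well beyond the 6
significant figures the contract requires.
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .core import PHASE_CODES, PHASE_NAMES, LoadTrace, Specimen

PathLike = Union[str, Path]

FLOAT_FORMAT = "%.10g"

TRACE_COLUMNS = ["time_s", "force_N", "displacement_mm"]
METADATA_COLUMNS = ["specimen_id", "group", "csa_mm2"]
SPECTRAL_COLUMNS = [
    "specimen_id", "group", "distance_mm", "dry_weight_mg",
    "fluorescence_au", "absorption_au",
]
CALIBRATION_COLUMNS = ["sample_id", "concentration_mM", "dry_weight_mg", "fluorescence_au"]


class SchemaError(ValueError):
    """Raised when a CSV does not match the expected column layout."""


def _check_columns(df: pd.DataFrame, required: list[str], path: PathLike,
                   allow_extra: bool = True) -> None:
    cols = list(df.columns)
    if cols[: len(required)] != required:
        raise SchemaError(
            f"{path}: expected leading columns {required}, found {cols}"
        )
    if not allow_extra and len(cols) > len(required):
        raise SchemaError(f"{path}: unexpected extra columns {cols[len(required):]}")


def _numeric(df: pd.DataFrame, columns: list[str], path: PathLike) -> None:
    for col in columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # 1-based plus header line
            raise SchemaError(
                f"{path}: non-numeric value {df[col][bad.idxmax()]!r} in column "
                f"{col!r} at line {row}"
            )
        if converted.isna().any():
            row = int(converted.isna().idxmax()) + 2
            raise SchemaError(f"{path}: missing value in column {col!r} at line {row}")
        df[col] = converted


def write_trace_csv(trace: LoadTrace, path: PathLike) -> None:
    """Write ``time_s,force_N,displacement_mm[,phase]`` rows for one trace."""
    data = {
        "time_s": trace.time,
        "force_N": trace.force,
        "displacement_mm": trace.displacement,
    }
    df = pd.DataFrame(data)
    if trace.phase is not None:
        df["phase"] = [PHASE_NAMES[int(c)] for c in trace.phase]
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT, lineterminator="\n")


def read_trace_csv(path: PathLike) -> LoadTrace:
    """Read a trace CSV; enforces the schema and strictly increasing time."""
    df = pd.read_csv(path, dtype=str)
    _check_columns(df, TRACE_COLUMNS, path)
    _numeric(df, TRACE_COLUMNS, path)
    phase = None
    if "phase" in df.columns:
        unknown = set(df["phase"].unique()) - set(PHASE_CODES)
        if unknown:
            raise SchemaError(f"{path}: unknown phase labels {sorted(unknown)}")
        phase = np.array([PHASE_CODES[p] for p in df["phase"]], dtype=np.int8)
    time = df["time_s"].to_numpy(float)
    if np.any(np.diff(time) <= 0):
        row = int(np.argmax(np.diff(time) <= 0)) + 3
        raise SchemaError(f"{path}: time not strictly increasing at line {row}")
    return LoadTrace(time, df["force_N"].to_numpy(float),
                     df["displacement_mm"].to_numpy(float), phase)


def write_metadata_csv(specimens: list[Specimen], path: PathLike) -> None:
    df = pd.DataFrame(
        {
            "specimen_id": [s.id for s in specimens],
            "group": [s.group for s in specimens],
            "csa_mm2": [s.csa for s in specimens],
        }
    )
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT, lineterminator="\n")


def read_metadata_csv(path: PathLike, gauge_length: float = 45.0) -> list[Specimen]:
    df = pd.read_csv(path, dtype=str)
    _check_columns(df, METADATA_COLUMNS, path)
    _numeric(df, ["csa_mm2"], path)
    return [
        Specimen(id=str(r.specimen_id), group=str(r.group), csa=float(r.csa_mm2),
                 gauge_length=gauge_length)
        for r in df.itertuples()
    ]


def write_table_csv(df: pd.DataFrame, path: PathLike) -> None:
    """Write any result table with the fixed dialect (byte-reproducible)."""
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT, lineterminator="\n")


def read_spectral_csv(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str)
    _check_columns(df, SPECTRAL_COLUMNS, path)
    _numeric(df, SPECTRAL_COLUMNS[2:], path)
    return df


def read_calibration_csv(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str)
    _check_columns(df, CALIBRATION_COLUMNS, path)
    _numeric(df, CALIBRATION_COLUMNS[1:], path)
    return df


def read_properties_csv(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "group" not in df.columns:
        raise SchemaError(f"{path}: properties table must carry a 'group' column")
    return df
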