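"""Plain-text readers and writers for the pipeline's file formats.

Formats
-------
* RR series: one interval in ms per line (optional ``# key: value`` header
  comments).
* ECG trace: two-column CSV ``time_s, amplitude_mv`` with a one-line
  header; sampling rate recoverable from the time column or overridable.
* Cohort manifest: CSV ``subject_id, gender, state, rr_path``.
* FS-14 table: CSV ``subject_id, gender, state, item01..item14``.
* Feature table: CSV, one row per (subject, state), standard HRV
  parameter names as columns.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import HRVError, ParameterError
from .stats import FS14Record
from .types import ECGRecord, RRSeries

__all__ = [
    "read_rr_text", "write_rr_text",
    "read_ecg_csv", "write_ecg_csv",
    "write_manifest", "read_manifest",
    "write_fs14_csv", "read_fs14_csv",
    "write_json",
]

#: Canonical feature-column order for feature tables.
FEATURE_COLUMNS = [
    "meanRR", "meanHR", "SDNN", "RMSSD", "SDSD", "CV", "PNN20", "PNN50",
    "VLF percent", "LF percent", "HF percent", "LF norm", "HF norm", "LF/HF",
    "SD1", "SD2", "SD1/SD2",
    "SampleEn_RR", "SampleEn_iHR", "SampleEn_Peak",
]


def write_rr_text(rr: RRSeries, path: str | Path) -> Path:
    """One interval (ms) per line; amplitudes, if any, as a second column."""
    path = Path(path)
    with path.open("w") as fh:
        if rr.amplitudes is not None:
            fh.write("# columns: rr_ms amplitude_mv\n")
            # amplitude of the beat that ends each interval
            for v, a in zip(rr.intervals, rr.amplitudes[1:]):
                fh.write(f"{v:.6f} {a:.6f}\n")
        else:
            for v in rr.intervals:
                fh.write(f"{v:.6f}\n")
    return path


def read_rr_text(path: str | Path) -> RRSeries:
    intervals: list[float] = []
    amplitudes: list[float] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        intervals.append(float(parts[0]))
        if len(parts) > 1:
            amplitudes.append(float(parts[1]))
    if not intervals:
        raise HRVError(f"no RR intervals found in {path}")
    amps = None
    if len(amplitudes) == len(intervals):
        # no amplitude is recorded for the first beat in this format
        amps = np.concatenate(([amplitudes[0]], amplitudes))
    return RRSeries(intervals=np.asarray(intervals), amplitudes=amps)


def write_ecg_csv(ecg: ECGRecord, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame({"time_s": ecg.times, "amplitude_mv": ecg.samples})
    df.to_csv(path, index=False, float_format="%.6f")
    return path


def read_ecg_csv(
    path: str | Path,
    time_column: str = "time_s",
    amplitude_column: str = "amplitude_mv",
    fs: float | None = None,
) -> ECGRecord:
    """Read a two-column ECG CSV; ``fs`` overrides the rate inferred from
    the time column."""
    df = pd.read_csv(path)
    if amplitude_column not in df.columns:
        raise ParameterError(f"column {amplitude_column!r} not in {path}")
    samples = df[amplitude_column].to_numpy(dtype=float)
    if fs is None:
        if time_column not in df.columns:
            raise ParameterError(
                f"no {time_column!r} column in {path}; supply fs explicitly"
            )
        t = df[time_column].to_numpy(dtype=float)
        dt = np.diff(t)
        # tolerate the microsecond quantization of the text format
        if dt.size == 0 or not np.allclose(dt, np.median(dt), atol=5e-6):
            raise ParameterError(f"time column in {path} is not uniformly sampled")
        fs = (t.size - 1) / (t[-1] - t[0])
        t0 = float(t[0])
    else:
        t0 = float(df[time_column].iloc[0]) if time_column in df.columns else 0.0
    return ECGRecord(samples=samples, fs=float(fs), t0=t0)


def write_manifest(rows: list[dict], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(rows, columns=["subject_id", "gender", "state", "rr_path"]).to_csv(
        path, index=False
    )
    return path


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"subject_id", "gender", "state", "rr_path"} - set(df.columns)
    if missing:
        raise ParameterError(f"manifest {path} lacks columns {sorted(missing)}")
    return df


def write_fs14_csv(records: list[dict], path: str | Path) -> Path:
    """Rows: subject_id, gender, state plus item01..item14."""
    path = Path(path)
    cols = ["subject_id", "gender", "state"] + [f"item{i:02d}" for i in range(1, 15)]
    pd.DataFrame(records, columns=cols).to_csv(path, index=False)
    return path


def read_fs14_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    item_cols = [f"item{i:02d}" for i in range(1, 15)]
    missing = set(item_cols) - set(df.columns)
    if missing:
        raise ParameterError(f"FS-14 table {path} lacks columns {sorted(missing)}")
    return df


def fs14_row(subject_id: str, gender: str, state: str, rec: FS14Record) -> dict:
    row = {"subject_id": subject_id, "gender": gender, "state": state}
    row.update({f"item{i + 1:02d}": s for i, s in enumerate(rec.item_scores)})
    return row


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, default=_jsonify) + "\n")
    return path


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Path):
        return str(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
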