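"""Reading and writing of current traces, idealizations, and event tables.

Conventions
-----------
* Time is seconds from the start of the trace; sample indexing is 0-based and
  intervals are half-open ``[start, end)``, so ``dwell_ms`` is exactly
  ``(end - start) / sample_rate * 1000``.
* CSV traces are comma-separated with '.' decimal point and '#'-prefixed
  metadata header lines (``# key=value``).
* Binary traces are raw little-endian float32 with a JSON metadata sidecar
  (``<path>.json``) that must at minimum carry ``sample_rate_hz``.
* Event/level tables are TSV with one documented header line.

All numeric formatting is locale-independent.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: columns of the per-level event table, in order
EVENT_TABLE_COLUMNS = [
    "event_id",
    "feature_idx",
    "level_label",
    "start_s",
    "dwell_ms",
    "mean_pA",
    "ires_pct",
    "rms_pA",
]

#: columns appended by the statistics stage
STATS_COLUMNS = [
    "sem_ires",
    "rms2k_pA",
    "rms_corr_pA",
    "rms_clipped",
    "excluded",
    "direction",
    "complete",
]


@dataclass
class Trace:
    """A sampled single-channel current recording.

    Parameters
    ----------
    samples : ndarray
        Current in pA; all values must be finite.
    sample_rate : float
        Acquisition rate in Hz (> 0).
    metadata : dict
        Condition metadata (applied voltage in mV, temperature in degC,
        chaotrope, analyte and concentration in uM, ...). Unknown keys are
        preserved on round-trip.
    """

    samples: np.ndarray
    sample_rate: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be > 0")
        bad = np.flatnonzero(~np.isfinite(self.samples))
        if bad.size:
            raise ValueError(f"non-finite sample at index {bad[0]}")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sample_rate


def write_trace(trace: Trace, path: str, format: str = "csv") -> None:
    """Write a trace as CSV (time_s, current_pA) or raw float32 + JSON sidecar."""
    if format == "csv":
        with open(path, "w", newline="\n") as fh:
            fh.write(f"# sample_rate_hz={trace.sample_rate!r}\n")
            for key in sorted(trace.metadata):
                fh.write(f"# {key}={trace.metadata[key]!r}\n")
            fh.write("time_s,current_pA\n")
            t = trace.times
            for ti, ci in zip(t, trace.samples):
                fh.write(f"{ti:.8g},{ci:.7g}\n")
    elif format == "binary":
        trace.samples.astype("<f4").tofile(path)
        sidecar = dict(trace.metadata)
        sidecar["sample_rate_hz"] = trace.sample_rate
        with open(_sidecar_path(path), "w") as fh:
            json.dump(sidecar, fh, indent=1, sort_keys=True)
            fh.write("\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_trace(path: str, format: str = "csv") -> Trace:
    """Read a trace written by :func:`write_trace`.

    Raises on empty files, header-only CSVs, missing sample rates and
    non-finite samples (with the offending index).
    """
    if format == "csv":
        return _read_csv_trace(path)
    if format == "binary":
        return _read_binary_trace(path)
    raise ValueError(f"unknown format {format!r}")


def _sidecar_path(path: str) -> str:
    return path + ".json"


def _parse_meta_value(raw: str):
    raw = raw.strip()
    if raw.startswith("'") and raw.endswith("'") and len(raw) >= 2:
        return raw[1:-1]
    try:
        return int(raw)
    except ValueError:
        pass
    try:
        return float(raw)
    except ValueError:
        return raw


def _read_csv_trace(path: str) -> Trace:
    if os.path.getsize(path) == 0:
        raise ValueError(f"empty trace file: {path}")
    metadata: dict = {}
    header_seen = False
    data = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line[1:].partition("=")
                metadata[key.strip()] = _parse_meta_value(val)
                continue
            if not header_seen:
                header_seen = True  # "time_s,current_pA"
                continue
            _, _, cur = line.partition(",")
            data.append(float(cur))
    if "sample_rate_hz" not in metadata:
        raise ValueError(f"{path}: missing required metadata key 'sample_rate_hz'")
    if not data:
        raise ValueError(f"{path}: header present but no data rows")
    rate = float(metadata.pop("sample_rate_hz"))
    return Trace(np.array(data), rate, metadata)


def _read_binary_trace(path: str) -> Trace:
    sidecar = _sidecar_path(path)
    if not os.path.exists(sidecar):
        raise FileNotFoundError(f"missing JSON sidecar {sidecar}")
    with open(sidecar) as fh:
        meta = json.load(fh)
    if "sample_rate_hz" not in meta:
        raise ValueError(f"{sidecar}: missing required key 'sample_rate_hz'")
    if os.path.getsize(path) == 0:
        raise ValueError(f"empty trace file: {path}")
    samples = np.fromfile(path, dtype="<f4").astype(np.float64)
    rate = float(meta.pop("sample_rate_hz"))
    return Trace(samples, rate, meta)


# ---------------------------------------------------------------------------
# tabular output


def write_table(df: pd.DataFrame, path: str, meta: dict | None = None) -> None:
    """Write a DataFrame as TSV with optional '#'-prefixed metadata lines."""
    with open(path, "w", newline="\n") as fh:
        if meta:
            for key in sorted(meta):
                fh.write(f"# {key}={meta[key]!r}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.8g", lineterminator="\n")


def read_table(path: str) -> tuple[pd.DataFrame, dict]:
    """Read a TSV written by :func:`write_table`; returns (frame, metadata)."""
    meta: dict = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if line.startswith("#"):
                key, _, val = line[1:].partition("=")
                meta[key.strip()] = _parse_meta_value(val)
                pos = fh.tell()
            else:
                fh.seek(pos)
                break
        df = pd.read_csv(fh, sep="\t")
    return df, meta


def write_event_table(events_df: pd.DataFrame, path: str, meta: dict | None = None) -> None:
    """Write the per-level event table (one row per idealized level).

    Zero events yields a header-only file; columns are
    :data:`EVENT_TABLE_COLUMNS` plus any statistics columns present.
    """
    cols = [c for c in EVENT_TABLE_COLUMNS + STATS_COLUMNS if c in events_df.columns]
    extra = [c for c in events_df.columns if c not in cols]
    write_table(events_df[cols + extra], path, meta)


def read_event_table(path: str) -> tuple[pd.DataFrame, dict]:
    return read_table(path)
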