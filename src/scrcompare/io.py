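"""Readers and writers for recordings, event tables, estimate tables, config.

All files are plain comma-separated text.  A recording file has two
columns (time in seconds, conductance in μS), header optional.  An event
file has two columns (onset in seconds, condition label), header
optional.  Estimate tables require a header.  Configuration is a flat
YAML mapping.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ScrRecording",
    "EventTable",
    "FormatError",
    "read_recording",
    "write_recording",
    "read_events",
    "write_events",
    "read_estimates",
    "write_estimates",
    "read_config",
    "write_config",
]

#: Column order of an SA-estimate table (one row per subject × condition ×
#: method, or per trial when ``trial`` is non-null).
ESTIMATE_COLUMNS = ["subject_id", "condition", "trial", "method", "value"]

#: Relative tolerance on sampling-interval jitter before a recording is
#: rejected as irregularly sampled.
SAMPLING_TOLERANCE = 0.01


class FormatError(ValueError):
    """A file violates the expected on-disk format or its invariants."""


@dataclass
class ScrRecording:
    """One subject's conductance time series.

    Attributes
    ----------
    subject_id : str
    fs : float
        Sampling rate, Hz (constant per recording).
    values : ndarray
        Conductance samples in μS.
    t0 : float
        Time of the first sample, seconds.
    """

    subject_id: str
    fs: float
    values: np.ndarray = field(repr=False)
    t0: float = 0.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.fs <= 0:
            raise FormatError(f"fs must be positive, got {self.fs}")
        if self.values.size < 1:
            raise FormatError("recording must contain at least one sample")
        if not np.all(np.isfinite(self.values)):
            raise FormatError("recording contains non-finite samples")

    @property
    def duration(self) -> float:
        return len(self.values) / self.fs

    @property
    def t(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.values)) / self.fs


@dataclass
class EventTable:
    """Stimulus onsets (seconds, relative to recording start) with labels."""

    onsets: np.ndarray = field(default_factory=lambda: np.empty(0))
    conditions: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=object))

    def __post_init__(self):
        self.onsets = np.asarray(self.onsets, dtype=float)
        self.conditions = np.asarray(self.conditions, dtype=object)
        if self.onsets.shape != self.conditions.shape:
            raise FormatError("onsets and conditions must have equal length")
        if self.onsets.size:
            if np.any(self.onsets < 0):
                raise FormatError("event onsets must be non-negative")
            if np.any(np.diff(self.onsets) <= 0):
                raise FormatError("event onsets must be strictly increasing")
            if any(not str(c) for c in self.conditions):
                raise FormatError("condition labels must be nonempty")

    def __len__(self) -> int:
        return len(self.onsets)

    @property
    def condition_labels(self) -> list:
        """Distinct condition labels in order of first appearance."""
        seen: dict = {}
        for c in self.conditions:
            seen.setdefault(str(c), None)
        return list(seen)

    def select(self, condition: str) -> "EventTable":
        mask = np.array([str(c) == condition for c in self.conditions], dtype=bool)
        return EventTable(self.onsets[mask], self.conditions[mask])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"onset": self.onsets, "condition": self.conditions})


def _read_two_columns(path) -> pd.DataFrame:
    """Read a two-column CSV, tolerating an optional single header line."""
    text = Path(path).read_text()
    if not text.strip():
        return pd.DataFrame(columns=[0, 1])
    first = text.splitlines()[0]
    skip = 0
    cells = first.split(",")
    try:
        float(cells[0])
    except (ValueError, IndexError):
        skip = 1
    df = pd.read_csv(_stdio.StringIO(text), header=None, skiprows=skip)
    if df.shape[1] != 2:
        raise FormatError(f"{path}: expected 2 columns, found {df.shape[1]}")
    return df


def read_recording(path, subject_id: str | None = None) -> ScrRecording:
    """Read a (time, conductance) CSV; fs is inferred from the median step.

    Raises
    ------
    FormatError
        If time is not strictly increasing or the sampling interval
        varies by more than 1% of the median step.
    """
    df = _read_two_columns(path)
    if len(df) == 0:
        raise FormatError(f"{path}: empty recording")
    t = df.iloc[:, 0].to_numpy(dtype=float)
    values = df.iloc[:, 1].to_numpy(dtype=float)
    if len(t) > 1:
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise FormatError(f"{path}: time column is not strictly increasing")
        step = float(np.median(dt))
        if np.max(np.abs(dt - step)) > SAMPLING_TOLERANCE * step:
            raise FormatError(f"{path}: irregular sampling (jitter > 1% of step)")
        fs = 1.0 / step
    else:
        fs = 1.0
    if subject_id is None:
        subject_id = Path(path).stem
    return ScrRecording(subject_id=subject_id, fs=fs, values=values, t0=float(t[0]))


def write_recording(rec: ScrRecording, path) -> None:
    df = pd.DataFrame({"time": rec.t, "conductance": rec.values})
    df.to_csv(path, index=False, header=False, float_format="%.10g")


def read_events(path) -> EventTable:
    """Read an (onset, condition) CSV into a sorted, validated table."""
    df = _read_two_columns(path)
    if len(df) == 0:
        return EventTable()
    onsets = df.iloc[:, 0].to_numpy(dtype=float)
    conditions = df.iloc[:, 1].astype(str).to_numpy(dtype=object)
    order = np.argsort(onsets, kind="stable")
    return EventTable(onsets[order], conditions[order])


def write_events(events: EventTable, path) -> None:
    events.to_frame().to_csv(path, index=False, header=False, float_format="%.10g")


def read_estimates(path) -> pd.DataFrame:
    """Read an SA-estimate table (header required)."""
    df = pd.read_csv(path)
    missing = set(ESTIMATE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: estimate table missing columns {sorted(missing)}")
    if not np.all(np.isfinite(df["value"].to_numpy(dtype=float))):
        raise FormatError(f"{path}: estimate values must be finite")
    return df[ESTIMATE_COLUMNS]


def write_estimates(estimates: pd.DataFrame, path) -> None:
    estimates[ESTIMATE_COLUMNS].to_csv(path, index=False, float_format="%.10g")


def read_config(path) -> dict:
    """Load a flat YAML mapping of configuration keys."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: config must be a flat key-value mapping")
    return cfg


def write_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, default_flow_style=False, sort_keys=True)
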