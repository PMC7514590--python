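"""Reading and writing gaze recordings and stimulus schedules.

A *gaze recording* is one participant-session of a jumping-point
experiment: per-sample timestamps (ms) and horizontal (optionally
vertical) gaze coordinates, sampled at a constant rate, together with
the schedule of stimulus-position onsets.  Files are plain delimited
text; the column layout is described by a :class:`FormatConfig` that can
be loaded from YAML or JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import DataError, FormatError, ParseError

__all__ = [
    "FormatConfig",
    "GazeRecording",
    "read_gaze",
    "read_stimulus_schedule",
    "write_gaze",
    "write_stimulus_schedule",
]


@dataclass
class FormatConfig:
    """Column layout and acquisition metadata for gaze text files.

    Parameters
    ----------
    fs : float
        Sampling rate in Hz.
    delimiter : str
        Field delimiter of the gaze and schedule files.
    t_col, x_col, y_col : str
        Column names for timestamps (ms), horizontal and (optional)
        vertical coordinates.
    participant_id, session_id : str
        Identity attached to recordings read with this config; may be
        overridden per call.
    """

    fs: float
    delimiter: str = ","
    t_col: str = "t"
    x_col: str = "x"
    y_col: Optional[str] = None
    participant_id: str = ""
    session_id: str = ""

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise FormatError(f"sampling rate must be positive, got {self.fs}")

    @classmethod
    def from_file(cls, path: str | Path) -> "FormatConfig":
        """Load a config from a YAML or JSON file."""
        path = Path(path)
        with open(path) as fh:
            raw = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise FormatError(f"config file {path} does not contain a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        if "fs" not in raw:
            raise FormatError("config is missing required key 'fs'")
        return cls(**raw)


@dataclass
class GazeRecording:
    """Raw sampled gaze positions for one participant-session.

    Invariants checked on construction: timestamps strictly increasing
    with spacing consistent with ``fs``; stimulus onsets sorted in time
    with unique indices.
    """

    participant_id: str
    session_id: str
    fs: float
    t: np.ndarray
    x: np.ndarray
    y: Optional[np.ndarray] = None
    stimulus_onsets: list[tuple[int, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        if self.y is not None:
            self.y = np.asarray(self.y, dtype=float)
            if self.y.shape != self.x.shape:
                raise DataError("y must have the same length as x")
        if self.t.ndim != 1 or self.t.shape != self.x.shape:
            raise DataError("t and x must be 1-D arrays of equal length")
        if self.t.size >= 2:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                i = int(np.argmax(dt <= 0))
                raise DataError(
                    f"timestamps not strictly increasing at sample {i + 1}"
                )
            expected = 1000.0 / self.fs
            if np.max(np.abs(dt - expected)) > 0.5 * expected:
                raise DataError(
                    "sample spacing inconsistent with declared sampling rate "
                    f"fs={self.fs} Hz"
                )
        onsets = list(self.stimulus_onsets)
        times = [float(t) for _, t in onsets]
        if times != sorted(times):
            raise DataError("stimulus onsets must be sorted by onset time")
        idx = [int(i) for i, _ in onsets]
        if len(idx) != len(set(idx)):
            raise DataError("stimulus indices must be unique")
        self.stimulus_onsets = [(int(i), float(t)) for i, t in onsets]

    @property
    def n_samples(self) -> int:
        return int(self.t.size)


def _numeric_column(df: pd.DataFrame, col: str, path: Path) -> np.ndarray:
    values = pd.to_numeric(df[col], errors="coerce")
    bad = values.isna().to_numpy()
    if bad.any():
        row = int(np.argmax(bad))
        raise ParseError(
            f"{path}: non-numeric value {df[col].iloc[row]!r} in column "
            f"'{col}' at data row {row}"
        )
    return values.to_numpy(dtype=float)


def read_stimulus_schedule(
    path: str | Path, delimiter: str = ","
) -> list[tuple[int, float]]:
    """Read a stimulus schedule CSV with columns stimulus_index, onset_ms."""
    path = Path(path)
    df = pd.read_csv(path, sep=delimiter, float_precision="round_trip")
    for col in ("stimulus_index", "onset_ms"):
        if col not in df.columns:
            raise FormatError(f"{path}: schedule is missing column '{col}'")
    idx = _numeric_column(df, "stimulus_index", path)
    onset = _numeric_column(df, "onset_ms", path)
    return [(int(i), float(t)) for i, t in zip(idx, onset)]


def read_gaze(
    path: str | Path,
    config: FormatConfig,
    schedule: str | Path | Sequence[tuple[int, float]] | None = None,
    participant_id: Optional[str] = None,
    session_id: Optional[str] = None,
) -> GazeRecording:
    """Read a gaze recording from a delimited text file.

    ``schedule`` may be a path to a schedule CSV or an already-parsed
    list of ``(stimulus_index, onset_ms)`` pairs.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"gaze file not found: {path}")
    df = pd.read_csv(path, sep=config.delimiter, float_precision="round_trip")
    required = [config.t_col, config.x_col]
    if config.y_col is not None:
        required.append(config.y_col)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    t = _numeric_column(df, config.t_col, path)
    x = _numeric_column(df, config.x_col, path)
    y = _numeric_column(df, config.y_col, path) if config.y_col else None

    if schedule is None:
        onsets: list[tuple[int, float]] = []
    elif isinstance(schedule, (str, Path)):
        onsets = read_stimulus_schedule(schedule, config.delimiter)
    else:
        onsets = [(int(i), float(t_)) for i, t_ in schedule]

    return GazeRecording(
        participant_id=participant_id or config.participant_id,
        session_id=session_id or config.session_id,
        fs=config.fs,
        t=t,
        x=x,
        y=y,
        stimulus_onsets=onsets,
    )


def write_gaze(rec: GazeRecording, path: str | Path, delimiter: str = ",") -> None:
    """Write a recording's samples as delimited text (columns t, x[, y])."""
    data = {"t": rec.t, "x": rec.x}
    if rec.y is not None:
        data["y"] = rec.y
    # %.17g round-trips float64 exactly through text
    pd.DataFrame(data).to_csv(path, sep=delimiter, index=False, float_format="%.17g")


def write_stimulus_schedule(
    onsets: Sequence[tuple[int, float]], path: str | Path, delimiter: str = ","
) -> None:
    pd.DataFrame(onsets, columns=["stimulus_index", "onset_ms"]).to_csv(
        path, sep=delimiter, index=False, float_format="%.17g"
    )
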