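"""Cutting recordings into per-stimulus velocity series.

Each stimulus onset starts one *EM series*: the eye-movement samples
between two successive stimulus appearances.  Position is converted to
velocity by two-point (forward) differentiation so that downstream
entropy features do not depend on the absolute stimulus layout, and the
series is truncated to a power-of-two length ``nemr`` counted from the
onset sample, where the saccadic period of interest lies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import DataError
from .io import GazeRecording

__all__ = ["EMSeries", "differentiate", "extract_em_series", "DEFAULT_NEMR"]

logger = logging.getLogger(__name__)

#: Default EM-series length in samples: 3 s at 1000 Hz aligned down to
#: the nearest power of two.
DEFAULT_NEMR = 2048


@dataclass
class EMSeries:
    """One per-stimulus eye-movement velocity series.

    ``v`` holds velocity in coordinate units per second; its length is
    fixed by the extraction (``nemr``) and every value must be finite.
    """

    participant_id: str
    session_id: str
    stimulus_index: int
    v: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.v = np.asarray(self.v, dtype=float)
        if self.v.ndim != 1:
            raise DataError("velocity series must be 1-D")
        if not np.all(np.isfinite(self.v)):
            raise DataError(
                f"non-finite velocity in series {self.key}/{self.stimulus_index}"
            )

    @property
    def key(self) -> str:
        """Participant-session identifier used for cross-validation folds."""
        return f"{self.participant_id}/{self.session_id}"


def differentiate(x: np.ndarray, fs: float) -> np.ndarray:
    """Two-point forward differentiation of a position series.

    Returns ``v`` with ``v[i] = (x[i+1] - x[i]) * fs``, i.e. one sample
    shorter than ``x``, in coordinate units per second.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise DataError("need at least 2 samples to differentiate")
    return np.diff(x) * fs


def extract_em_series(
    rec: GazeRecording, nemr: int = DEFAULT_NEMR
) -> list[EMSeries]:
    """Cut a recording into per-stimulus velocity series of length ``nemr``.

    For each stimulus onset the ``nemr + 1`` position samples starting at
    the onset sample (the nearest sample at or after the onset time) are
    differentiated, keeping the first ``nemr`` velocity samples.
    Intervals too short to supply ``nemr + 1`` samples are skipped with a
    warning, mirroring the removal of defective series from a recording
    session rather than aborting it.
    """
    if nemr < 1:
        raise DataError(f"nemr must be positive, got {nemr}")
    out: list[EMSeries] = []
    for stim_idx, onset_ms in rec.stimulus_onsets:
        i0 = int(np.searchsorted(rec.t, onset_ms, side="left"))
        if i0 + nemr + 1 > rec.n_samples:
            logger.warning(
                "skipping stimulus %d of %s/%s: interval has only %d samples "
                "after onset, need %d",
                stim_idx,
                rec.participant_id,
                rec.session_id,
                rec.n_samples - i0,
                nemr + 1,
            )
            continue
        v = differentiate(rec.x[i0 : i0 + nemr + 1], rec.fs)[:nemr]
        out.append(
            EMSeries(
                participant_id=rec.participant_id,
                session_id=rec.session_id,
                stimulus_index=stim_idx,
                v=v,
                fs=rec.fs,
            )
        )
    return out
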