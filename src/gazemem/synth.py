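"""Synthetic jumping-point eye-movement recordings with ground truth.

The generator emulates the experimental paradigm the entropy-map method
targets: a fixation target jumps between screen positions at fixed
3-second intervals while gaze is sampled at 1000 Hz.  Each trial
contains a saccadic-latency period (gaze holds near the previous
target), one saccade to the new target with a smooth raised-cosine
velocity pulse whose integral equals the target step, and post-saccadic
fixation.  Fixation micro-movement is modelled as white position noise
plus a slow random-walk drift, with optional microsaccade pulses.

Every trial's latency and saccade window is recorded as ground truth so
the detection pipeline can be validated end to end without any human
dataset.  All randomness flows from a single seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .errors import DataError
from .io import GazeRecording, write_gaze, write_stimulus_schedule
from .preprocess import DEFAULT_NEMR

__all__ = [
    "SynthConfig",
    "TrialTruth",
    "GroundTruth",
    "simulate_recording",
    "simulate_cohort",
    "write_cohort",
]


@dataclass(frozen=True)
class SynthConfig:
    """Cohort and signal parameters of the simulator.

    Defaults mirror the jumping-point study design: 24 participants,
    2 sessions, 29 stimulus positions, 3 s trials at 1000 Hz.  Latency
    is Uniform[100, 250] ms (so the saccade lands in the early part of
    the series), saccade duration Uniform[30, 80] ms, and the target
    step amplitude Uniform[0.15, 0.4] in normalised screen units.
    Fixation position noise (5e-4 units RMS) corresponds to a quiet
    research-grade tracker; drift is a per-sample random walk.
    Microsaccades are off by default.
    """

    n_participants: int = 24
    n_sessions: int = 2
    n_points: int = 29
    fs: float = 1000.0
    trial_ms: float = 3000.0
    latency_range_ms: tuple[float, float] = (100.0, 250.0)
    saccade_range_ms: tuple[float, float] = (30.0, 80.0)
    amplitude_range: tuple[float, float] = (0.15, 0.4)
    fixation_noise_sd: float = 5e-4
    drift_sd: float = 2e-5
    microsaccade_rate: float = 0.0
    microsaccade_amplitude: float = 0.01
    latency_subject_sd_ms: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_participants, self.n_sessions, self.n_points) < 1:
            raise DataError("cohort counts must be positive")
        if self.fs <= 0 or self.trial_ms <= 0:
            raise DataError("fs and trial_ms must be positive")
        for lo, hi, what in (
            (*self.latency_range_ms, "latency"),
            (*self.saccade_range_ms, "saccade duration"),
            (*self.amplitude_range, "amplitude"),
        ):
            if lo <= 0 or hi < lo:
                raise DataError(f"invalid {what} range ({lo}, {hi})")
        if (
            self.latency_range_ms[1]
            + 3 * self.latency_subject_sd_ms
            + self.saccade_range_ms[1]
            >= self.trial_ms
        ):
            raise DataError("latency + saccade duration must fit in a trial")
        if self.samples_per_trial < DEFAULT_NEMR + 1:
            raise DataError(
                f"a trial must contain at least {DEFAULT_NEMR + 1} samples, "
                f"got {self.samples_per_trial}"
            )
        if self.fixation_noise_sd < 0 or self.drift_sd < 0:
            raise DataError("noise SDs must be non-negative")

    @property
    def samples_per_trial(self) -> int:
        return int(round(self.fs * self.trial_ms / 1000.0))


@dataclass
class TrialTruth:
    """Ground truth for one trial; sample indices are recording-global."""

    stimulus_index: int
    trial_start_sample: int
    latency_ms: float
    saccade_onset: int
    saccade_offset: int
    target_from: float
    target_to: float


@dataclass
class GroundTruth:
    participant_id: str
    session_id: str
    trials: list[TrialTruth] = field(default_factory=list)

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "participant_id": self.participant_id,
                    "session_id": self.session_id,
                    "trials": [asdict(t) for t in self.trials],
                },
                indent=1,
            )
        )

    @classmethod
    def load_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            participant_id=d["participant_id"],
            session_id=d["session_id"],
            trials=[TrialTruth(**t) for t in d["trials"]],
        )


def _raised_cosine_pulse(n: int, displacement: float, fs: float) -> np.ndarray:
    """Per-sample velocity of a smooth unimodal saccade profile.

    Samples a raised cosine at midpoints and rescales so the discrete
    integral (sum / fs) equals the displacement exactly.
    """
    shape = 1.0 - np.cos(2.0 * np.pi * (np.arange(n) + 0.5) / n)
    return shape * (displacement * fs / shape.sum())


def _next_target(
    current: float, rng: np.random.Generator, amp_range: tuple[float, float]
) -> float:
    amp = rng.uniform(*amp_range)
    lo, hi = 0.05, 0.95
    candidates = [current + amp, current - amp]
    valid = [c for c in candidates if lo <= c <= hi]
    if not valid:
        return float(np.clip(candidates[0], lo, hi))
    if len(valid) == 2:
        return valid[rng.integers(2)]
    return valid[0]


def simulate_recording(
    config: SynthConfig,
    participant_id: str = "p01",
    session_id: str = "s1",
    rng: Optional[np.random.Generator] = None,
    latency_offset_ms: float = 0.0,
) -> tuple[GazeRecording, GroundTruth]:
    """Simulate one participant-session of the jumping-point paradigm.

    ``latency_offset_ms`` shifts this recording's latency distribution,
    modelling idiosyncratic reaction speed; the cohort generator draws
    it per participant.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    npt = config.samples_per_trial
    total = config.n_points * npt
    fs = config.fs

    velocity = np.zeros(total)
    truth = GroundTruth(participant_id, session_id)
    lat_lo, lat_hi = config.latency_range_ms
    sac_lo, sac_hi = config.saccade_range_ms
    current = 0.5
    for trial in range(config.n_points):
        start = trial * npt
        target = _next_target(current, rng, config.amplitude_range)
        latency = rng.uniform(lat_lo, lat_hi) + latency_offset_ms
        latency = float(
            np.clip(latency, 1.0, config.trial_ms - sac_hi - 2000.0 / fs)
        )
        dur_ms = rng.uniform(sac_lo, sac_hi)
        onset = start + int(round(latency * fs / 1000.0))
        n_sac = max(2, int(round(dur_ms * fs / 1000.0)))
        velocity[onset : onset + n_sac] = _raised_cosine_pulse(
            n_sac, target - current, fs
        )
        if config.microsaccade_rate > 0:
            fix_time_s = (config.trial_ms - latency - dur_ms) / 1000.0
            for _ in range(rng.poisson(config.microsaccade_rate * fix_time_s)):
                n_ms = max(2, int(round(0.010 * fs)))
                pos = int(rng.integers(start, start + npt - n_ms))
                if pos + n_ms <= onset or pos >= onset + n_sac:
                    amp = config.microsaccade_amplitude * rng.choice([-1.0, 1.0])
                    velocity[pos : pos + n_ms] += _raised_cosine_pulse(
                        n_ms, amp, fs
                    )
        truth.trials.append(
            TrialTruth(
                stimulus_index=trial,
                trial_start_sample=start,
                latency_ms=latency,
                saccade_onset=onset,
                saccade_offset=onset + n_sac,
                target_from=current,
                target_to=target,
            )
        )
        current = target

    # integrate the designed velocity, then add fixation micro-movement
    x = 0.5 + np.concatenate(([0.0], np.cumsum(velocity[:-1]))) / fs
    if config.fixation_noise_sd > 0:
        x = x + rng.normal(0.0, config.fixation_noise_sd, total)
    if config.drift_sd > 0:
        steps = rng.normal(0.0, config.drift_sd, total)
        drift = np.cumsum(steps.reshape(config.n_points, npt), axis=1).ravel()
        x = x + drift

    t = np.arange(total) * (1000.0 / fs)
    onsets = [(j, j * npt * 1000.0 / fs) for j in range(config.n_points)]
    rec = GazeRecording(
        participant_id=participant_id,
        session_id=session_id,
        fs=fs,
        t=t,
        x=x,
        stimulus_onsets=onsets,
    )
    return rec, truth


def simulate_cohort(
    config: SynthConfig,
) -> list[tuple[GazeRecording, GroundTruth]]:
    """Simulate every participant-session of the configured cohort.

    Each participant receives a latency-mean offset (Normal with SD
    ``latency_subject_sd_ms``, clipped to three SDs) applied to all of
    their sessions, so sessions of one participant resemble each other
    more than those of different participants.
    """
    ss = np.random.SeedSequence(config.seed)
    master = np.random.default_rng(ss)
    sd = config.latency_subject_sd_ms
    offsets = (
        np.clip(master.normal(0.0, sd, config.n_participants), -3 * sd, 3 * sd)
        if sd > 0
        else np.zeros(config.n_participants)
    )
    children = ss.spawn(config.n_participants * config.n_sessions)
    out = []
    width = max(2, len(str(config.n_participants)))
    idx = 0
    for p in range(config.n_participants):
        pid = f"p{p + 1:0{width}d}"
        for s in range(config.n_sessions):
            rec, gt = simulate_recording(
                config,
                participant_id=pid,
                session_id=f"s{s + 1}",
                rng=np.random.default_rng(children[idx]),
                latency_offset_ms=float(offsets[p]),
            )
            out.append((rec, gt))
            idx += 1
    return out


def write_cohort(
    cohort: Sequence[tuple[GazeRecording, GroundTruth]],
    outdir: str | Path,
    delimiter: str = ",",
) -> list[dict]:
    """Write each session as gaze CSV + schedule CSV + ground-truth JSON.

    Returns a manifest (one entry per session with the file names and
    identities) that callers typically serialise next to the data.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = []
    for rec, gt in cohort:
        stem = f"{rec.participant_id}_{rec.session_id}"
        gaze = outdir / f"gaze_{stem}.csv"
        sched = outdir / f"schedule_{stem}.csv"
        truth = outdir / f"truth_{stem}.json"
        write_gaze(rec, gaze, delimiter)
        write_stimulus_schedule(rec.stimulus_onsets, sched, delimiter)
        gt.save_json(truth)
        manifest.append(
            {
                "participant_id": rec.participant_id,
                "session_id": rec.session_id,
                "fs": rec.fs,
                "gaze": gaze.name,
                "schedule": sched.name,
                "truth": truth.name,
            }
        )
    return manifest
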