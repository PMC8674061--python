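"""Seeded synthetic electrooculogram (EOG) trial generator.

Emulates a cued eye-movement protocol: a subject performs one of eleven
tasks per trial — six directional gaze shifts (right, left, and the four
obliques), two compound movements (rapid vertical movement, lateral
movement), and three non-event actions (eyes open, eyes close, stare) —
while a two-channel bipolar EOG (horizontal + vertical) is recorded at
100 Hz in 1-second (100-sample) trial windows.

The corneo-retinal standing potential makes a gaze shift appear as a
step deflection on the corresponding channel; lid movement (close)
appears as a biphasic spike on the vertical channel.  Each task template
is deterministic; trial-to-trial variability comes from additive
Gaussian noise and an optional mains (50 Hz) contamination term.

A note on template design: the downstream feature (circular lag-1
autocorrelation, see :mod:`eoghci.features`) is quadratic in the signal
and therefore blind to a global sign flip — a pure mirror-image pair of
templates (e.g. a +step for "right" and the same −step for "left")
would be mathematically inseparable.  Real cued protocols vary in gaze
hold/return timing, so each directional task here carries a distinct
hold duration (sustained step vs. return-to-center pulse of a distinct
width), which encodes class identity in temporal structure the feature
can resolve.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, List, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Task",
    "TASKS",
    "EVENT_TASKS",
    "SynthParams",
    "TrialRecord",
    "SubjectDataset",
    "SynthesisError",
    "generate_trial",
    "generate_subject",
    "is_event",
    "task_index",
    "write_trials_csv",
    "read_trials_csv",
    "trials_to_frame",
]


class SynthesisError(ValueError):
    """Invalid generator input (unknown task, non-finite parameter...)."""


class Task(str, Enum):
    """The eleven eye-movement tasks.

    The first eight are intentional command movements ("events"); open,
    close and stare are non-events.  Enum order fixes the task index
    used for class coding.
    """

    RIGHT = "right"
    LEFT = "left"
    UP_RIGHT = "up_right"
    DOWN_RIGHT = "down_right"
    UP_LEFT = "up_left"
    DOWN_LEFT = "down_left"
    RAPID_MOVEMENT = "rapid_movement"
    LATERAL_MOVEMENT = "lateral_movement"
    OPEN = "open"
    CLOSE = "close"
    STARE = "stare"


TASKS: tuple = tuple(Task)

#: The eight intentional command movements.
EVENT_TASKS: frozenset = frozenset(TASKS[:8])

#: Trials recorded per task per subject.
TRIALS_PER_TASK = 10

#: Default noise level (same arbitrary units as the unit deflection
#: amplitude).  Chosen so the Elman classifier operates in the 85-95%
#: held-out-accuracy regime on default synthetic subjects; see
#: docs/methods.md.
DEFAULT_NOISE_SD = 0.05


def task_index(task: Task) -> int:
    """0-based index of *task* in the fixed enum order."""
    return TASKS.index(Task(task))


def is_event(task: Task) -> bool:
    """True for the eight command movements, False for open/close/stare."""
    return Task(task) in EVENT_TASKS


@dataclass(frozen=True)
class SynthParams:
    """Generator configuration.

    Parameters
    ----------
    sampling_rate : float
        Hz; the acquisition protocol rate (default 100).
    trial_length : int
        Samples per trial window (default 100, i.e. 1 s at 100 Hz).
    deflection_amplitude : float
        Peak-to-baseline saccade deflection in arbitrary (µV-scale)
        units; templates are scaled by this.
    noise_sd : float
        Standard deviation of the additive white Gaussian noise.
    mains_amplitude : float
        Amplitude of the additive mains-frequency cosine contamination.
    mains_freq : float
        Contamination frequency in Hz (default 50).
    seed : int
        Base seed; one RNG stream per subject, split per trial.
    """

    sampling_rate: float = 100.0
    trial_length: int = 100
    deflection_amplitude: float = 1.0
    noise_sd: float = DEFAULT_NOISE_SD
    mains_amplitude: float = 0.1
    mains_freq: float = 50.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("sampling_rate", "deflection_amplitude", "noise_sd",
                     "mains_amplitude", "mains_freq"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise SynthesisError(f"non-finite parameter {name}={v!r}")
        if self.sampling_rate <= 0:
            raise SynthesisError("sampling_rate must be > 0")
        if self.trial_length < 4:
            raise SynthesisError("trial_length must be >= 4")
        if self.noise_sd < 0:
            raise SynthesisError("noise_sd must be >= 0")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SynthParams":
        return cls(**json.loads(text))


@dataclass
class TrialRecord:
    """One labeled two-channel EOG trial window."""

    subject_id: str
    task: Task
    trial_index: int
    horizontal: np.ndarray
    vertical: np.ndarray

    def validate(self) -> None:
        n = len(self.horizontal)
        if len(self.vertical) != n:
            raise SynthesisError("channel length mismatch")
        if not (np.all(np.isfinite(self.horizontal))
                and np.all(np.isfinite(self.vertical))):
            raise SynthesisError("non-finite samples in trial")


@dataclass
class SubjectDataset:
    """All 110 trials (11 tasks x 10 trials) of one synthetic subject."""

    subject_id: str
    trials: List[TrialRecord]
    params: SynthParams


# --------------------------------------------------------------------------
# Task templates
# --------------------------------------------------------------------------

_DIAG = 2.0 ** -0.5  # oblique movements project ~1/sqrt(2) on each channel
_RAMP = 3            # saccade rise time in samples (~30 ms at 100 Hz)


def _step(n: int, on: float, off: float | None, ramp: int = _RAMP) -> np.ndarray:
    """Unit step (or return-to-baseline pulse) with a linear rise.

    `on`/`off` are fractions of the window; the plateau reaches exactly 1
    and the baseline is exactly 0.
    """
    i = np.arange(n, dtype=float)
    prof = np.clip((i - on * n) / ramp, 0.0, 1.0)
    if off is not None:
        prof = prof - np.clip((i - off * n) / ramp, 0.0, 1.0)
    return prof


def _bump(n: int, center: float, width: float) -> np.ndarray:
    i = np.arange(n, dtype=float)
    return np.exp(-0.5 * ((i - center * n) / (width * n)) ** 2)


def _template(task: Task, n: int) -> tuple:
    """(horizontal, vertical) unit-amplitude deflection profiles.

    Directional tasks: sign pattern follows the corneo-retinal dipole
    (rightward gaze -> positive horizontal; upward -> positive vertical);
    each task has a distinct gaze-hold duration (see module docstring).
    """
    z = np.zeros(n)
    if task is Task.RIGHT:
        return _step(n, 0.30, None), z
    if task is Task.LEFT:
        return -_step(n, 0.30, 0.70), z
    if task is Task.UP_RIGHT:
        return _DIAG * _step(n, 0.25, None), _DIAG * _step(n, 0.25, 0.85)
    if task is Task.DOWN_RIGHT:
        return _DIAG * _step(n, 0.25, 0.75), -_DIAG * _step(n, 0.25, None)
    if task is Task.UP_LEFT:
        return -_DIAG * _step(n, 0.30, 0.55), _DIAG * _step(n, 0.30, 0.90)
    if task is Task.DOWN_LEFT:
        return -_DIAG * _step(n, 0.30, 0.90), -_DIAG * _step(n, 0.30, 0.55)
    if task is Task.RAPID_MOVEMENT:
        # two alternating vertical steps within the window
        return z, _step(n, 0.20, 0.45) - _step(n, 0.45, 0.70)
    if task is Task.LATERAL_MOVEMENT:
        # two alternating horizontal steps
        return _step(n, 0.20, 0.45) - _step(n, 0.45, 0.70), z
    if task is Task.OPEN:
        # small rebound transient as the lids open
        return z, 0.4 * _bump(n, 0.40, 0.05)
    if task is Task.CLOSE:
        # biphasic blink-like lid spike
        return z, _bump(n, 0.45, 0.04) - 0.6 * _bump(n, 0.58, 0.05)
    if task is Task.STARE:
        return z, z
    raise SynthesisError(f"unknown task label: {task!r}")


# --------------------------------------------------------------------------
# Generation
# --------------------------------------------------------------------------

def generate_trial(task: Task, params: SynthParams,
                   rng: np.random.Generator,
                   subject_id: str = "S0", trial_index: int = 1) -> TrialRecord:
    """Generate one labeled trial: template + Gaussian noise + mains term.

    Deterministic for a fixed RNG state.  The mains contamination is a
    fixed-phase cosine so that, with ``noise_sd = 0``, repeated trials of
    the same task are bit-identical.
    """
    try:
        task = Task(task)
    except ValueError as exc:
        raise SynthesisError(f"unknown task label: {task!r}") from exc
    params.validate()

    n = params.trial_length
    h, v = _template(task, n)
    a = params.deflection_amplitude
    h = a * h
    v = a * v
    if params.mains_amplitude:
        t = np.arange(n) / params.sampling_rate
        mains = params.mains_amplitude * np.cos(2 * np.pi * params.mains_freq * t)
        h = h + mains
        v = v + mains
    if params.noise_sd > 0:
        h = h + rng.normal(0.0, params.noise_sd, n)
        v = v + rng.normal(0.0, params.noise_sd, n)
    rec = TrialRecord(subject_id=subject_id, task=task,
                      trial_index=trial_index,
                      horizontal=np.asarray(h, dtype=float),
                      vertical=np.asarray(v, dtype=float))
    rec.validate()
    return rec


def _subject_key(subject_id: str) -> int:
    return zlib.crc32(str(subject_id).encode()) & 0x7FFFFFFF


def _trial_rng(params: SynthParams, subject_id: str, counter: int) -> np.random.Generator:
    # one stream per subject, split per trial by counter: trial i is
    # independent of how many trials precede it
    ss = np.random.SeedSequence(
        entropy=[int(params.seed), _subject_key(subject_id)],
        spawn_key=(counter,),
    )
    return np.random.default_rng(ss)


def generate_subject(subject_id: str, params: SynthParams) -> SubjectDataset:
    """Generate the full 110-trial dataset of one subject.

    11 tasks x 10 trials, trial_index 1..10 per task; reproducible from
    ``(subject_id, params.seed)``.
    """
    params.validate()
    trials: List[TrialRecord] = []
    counter = 0
    for task in TASKS:
        for trial_index in range(1, TRIALS_PER_TASK + 1):
            rng = _trial_rng(params, subject_id, counter)
            counter += 1
            trials.append(generate_trial(task, params, rng,
                                         subject_id=subject_id,
                                         trial_index=trial_index))
    return SubjectDataset(subject_id=subject_id, trials=trials, params=params)


# --------------------------------------------------------------------------
# I/O — long-format trials CSV
# --------------------------------------------------------------------------

TRIALS_CSV_COLUMNS = ["subject_id", "task", "trial_index",
                      "channel", "sample_index", "value"]


def trials_to_frame(trials: Iterable[TrialRecord]) -> pd.DataFrame:
    """Long-format frame: one row per (trial, channel, sample)."""
    rows = []
    for rec in trials:
        for channel, samples in (("horizontal", rec.horizontal),
                                 ("vertical", rec.vertical)):
            rows.append(pd.DataFrame({
                "subject_id": rec.subject_id,
                "task": rec.task.value,
                "trial_index": rec.trial_index,
                "channel": channel,
                "sample_index": np.arange(len(samples)),
                "value": samples,
            }))
    return pd.concat(rows, ignore_index=True)


def write_trials_csv(trials: Iterable[TrialRecord], path) -> None:
    trials_to_frame(trials).to_csv(path, index=False, float_format="%.17g")


def read_trials_csv(path) -> List[TrialRecord]:
    """Read a long-format trials CSV back into TrialRecords.

    Raises :class:`SynthesisError` with the offending line number on a
    malformed row.
    """
    df = pd.read_csv(path)
    missing = set(TRIALS_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise SynthesisError(f"trials CSV missing columns: {sorted(missing)}")
    if df.empty:
        raise SynthesisError("trials CSV contains no rows")
    bad = df.index[~np.isfinite(df["value"].to_numpy(dtype=float, na_value=np.nan))]
    if len(bad):
        # +2: header line and 1-based numbering
        raise SynthesisError(f"malformed value on CSV line {bad[0] + 2}")
    trials = []
    for (sub, task, idx), grp in df.groupby(
            ["subject_id", "task", "trial_index"], sort=False):
        try:
            tsk = Task(task)
        except ValueError as exc:
            raise SynthesisError(f"unknown task label in CSV: {task!r}") from exc
        chans = {}
        for channel, cgrp in grp.groupby("channel", sort=False):
            cgrp = cgrp.sort_values("sample_index")
            chans[channel] = cgrp["value"].to_numpy(dtype=float)
        if set(chans) != {"horizontal", "vertical"}:
            raise SynthesisError(
                f"trial {sub}/{task}/{idx} lacks horizontal+vertical channels")
        rec = TrialRecord(subject_id=str(sub), task=tsk, trial_index=int(idx),
                          horizontal=chans["horizontal"],
                          vertical=chans["vertical"])
        rec.validate()
        trials.append(rec)
    return trials
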