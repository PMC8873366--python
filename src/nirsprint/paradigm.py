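"""Acquisition paradigm: block-design trial structure and scheduling.

The experimental paradigm is a motor block design recorded around the motor
cortex (C3/C4): each trial is a 2-s instruction phase, a 10-s task phase
(right-handed tapping RHT, left-handed tapping LHT, or foot tapping FT) and a
17-19-s rest phase.  Three sessions of 25 trials give 75 trials per subject,
~2250 s of signal at ~13.33 Hz over 20 channels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

#: Sampling rate implied by 30003 samples over a 2250-s session block (Hz).
DEFAULT_SAMPLING_RATE = 30003.0 / 2250.0

OXY = "OXY"
DEOXY = "DEOXY"
VIEWS = (OXY, DEOXY)


def round_half_up(x: float) -> int:
    """Round to the nearest integer, ties away from zero toward +inf."""
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class ParadigmConfig:
    """All acquisition constants of the block-design paradigm.

    Parameters
    ----------
    n_subjects : int
        Cohort size (default 30).
    n_sessions : int
        Recording sessions per subject (default 3).
    trials_per_session : int
        Trials in each session (default 25).
    intro_duration, task_duration : float
        Instruction and task phase lengths in seconds (defaults 2 and 10).
    rest_duration_range : tuple of float
        Closed interval the per-trial rest duration is drawn from, in
        seconds (default (17, 19)).
    sampling_rate : float
        Acquisition rate in Hz (default 30003/2250 ~ 13.3347).
    n_channels : int
        Number of source-detector channels (default 20).
    task_labels : tuple of str
        Ordered task set (default RHT, LHT, FT).
    rest_label : str
        Label used for rest-state epochs.
    """

    n_subjects: int = 30
    n_sessions: int = 3
    trials_per_session: int = 25
    intro_duration: float = 2.0
    task_duration: float = 10.0
    rest_duration_range: tuple[float, float] = (17.0, 19.0)
    sampling_rate: float = DEFAULT_SAMPLING_RATE
    n_channels: int = 20
    task_labels: tuple[str, ...] = ("RHT", "LHT", "FT")
    rest_label: str = "REST"

    def __post_init__(self) -> None:
        for name in ("n_subjects", "n_sessions", "trials_per_session", "n_channels"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        lo, hi = self.rest_duration_range
        if lo > hi:
            raise ValueError(f"rest_duration_range min {lo} exceeds max {hi}")
        if self.intro_duration < 0 or self.task_duration < 0 or lo < 0:
            raise ValueError("phase durations must be non-negative")
        if self.intro_duration + self.task_duration + lo <= 0:
            raise ValueError("a trial must have positive duration")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if len(set(self.task_labels)) != len(self.task_labels):
            raise ValueError("task_labels must be distinct")
        if self.rest_label in self.task_labels:
            raise ValueError("rest_label must differ from task_labels")

    @property
    def n_trials(self) -> int:
        return self.n_sessions * self.trials_per_session

    @property
    def classes(self) -> tuple[str, ...]:
        """Task labels plus the rest label — one fingerprint per class."""
        return self.task_labels + (self.rest_label,)

    @property
    def intro_samples(self) -> int:
        return round_half_up(self.intro_duration * self.sampling_rate)

    @property
    def task_samples(self) -> int:
        # floor, so the extracted task segment covers exactly the task phase
        return int(math.floor(self.task_duration * self.sampling_rate))

    def channel_labels(self) -> list[str]:
        return [f"CH{i + 1:02d}" for i in range(self.n_channels)]


@dataclass(frozen=True)
class Trial:
    """One trial: onset is the sample index of the instruction-phase start."""

    session_index: int
    onset: int
    task: str
    rest_duration: float  # seconds, already rounded to a whole sample count


@dataclass(frozen=True)
class TrialSchedule:
    """Ordered trial list plus the phase lengths (in samples) used to build it."""

    trials: tuple[Trial, ...]
    intro_samples: int
    task_samples: int
    sampling_rate: float

    def __post_init__(self) -> None:
        onsets = [t.onset for t in self.trials]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("trial onsets must be strictly increasing")

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def n_samples(self) -> int:
        """Total sample count spanned by the schedule (end of last rest phase)."""
        last = self.trials[-1]
        return last.onset + self.trial_length(last)

    def rest_samples(self, trial: Trial) -> int:
        return round_half_up(trial.rest_duration * self.sampling_rate)

    def trial_length(self, trial: Trial) -> int:
        return self.intro_samples + self.task_samples + self.rest_samples(trial)

    def task_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for t in self.trials:
            counts[t.task] = counts.get(t.task, 0) + 1
        return counts


def make_trial_schedule(paradigm: ParadigmConfig, seed: int) -> TrialSchedule:
    """Draw a balanced, randomly ordered trial schedule.

    Every task label appears exactly ``n_trials / len(task_labels)`` times
    over the whole recording; the order is a seeded random permutation.  Rest
    durations are drawn uniformly on ``rest_duration_range`` and rounded to
    whole samples (half up).  Onsets accumulate the per-phase sample counts.

    Raises
    ------
    ValueError
        If the total trial count is not divisible by the number of tasks.
    """
    n_trials = paradigm.n_trials
    n_tasks = len(paradigm.task_labels)
    if n_trials % n_tasks != 0:
        raise ValueError(
            f"cannot balance {n_trials} trials "
            f"({paradigm.n_sessions} sessions x {paradigm.trials_per_session}) "
            f"over {n_tasks} task labels: {n_trials} % {n_tasks} != 0"
        )
    rng = np.random.default_rng(seed)
    labels = np.repeat(np.array(paradigm.task_labels, dtype=object), n_trials // n_tasks)
    labels = labels[rng.permutation(n_trials)]
    rest_secs = rng.uniform(*paradigm.rest_duration_range, size=n_trials)

    fs = paradigm.sampling_rate
    intro_len = paradigm.intro_samples
    task_len = paradigm.task_samples
    trials = []
    onset = 0
    for i in range(n_trials):
        rest_len = round_half_up(rest_secs[i] * fs)
        trials.append(
            Trial(
                session_index=i // paradigm.trials_per_session,
                onset=onset,
                task=str(labels[i]),
                rest_duration=rest_len / fs,
            )
        )
        onset += intro_len + task_len + rest_len
    return TrialSchedule(
        trials=tuple(trials),
        intro_samples=intro_len,
        task_samples=task_len,
        sampling_rate=fs,
    )
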