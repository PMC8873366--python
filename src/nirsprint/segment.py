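"""Trial segmentation: extract task-phase and mid-rest epochs per trial.

Per trial, two epochs are cut: the full task phase (the 2-s instruction
phase is discarded) and a fixed-length window centered in the rest phase —
the middle of the rest phase avoids transients from task-rest switching.
At the default paradigm this gives 133-sample task segments and 200-sample
rest segments, 2 segments per trial.

Sample indexing is 0-based, half-open [start, start + length).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .simulate import Recording

#: Default rest-window length in seconds: 200 samples at the default rate,
#: fitting inside the minimum 17-s rest phase with >= 1 s guard each side.
DEFAULT_REST_WINDOW = 15.0


@dataclass(frozen=True)
class Segment:
    """One epoch (task or rest) from one recording, time x channels."""

    subject_id: str
    view: str
    state: str  # a task label, or the rest label
    trial_index: int
    data: np.ndarray
    sampling_rate: float
    start: int  # sample index into the source recording

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.data)):
            raise ValueError("segment contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]


def segment_trials(
    recording: Recording,
    rest_window: float = DEFAULT_REST_WINDOW,
    rest_label: str = "REST",
) -> list[Segment]:
    """Cut a recording into per-trial task and rest segments.

    Parameters
    ----------
    recording : Recording
        Preprocessed (or raw) recording carrying its trial schedule.
    rest_window : float
        Length of the rest epoch in seconds; must fit inside every trial's
        rest phase.  The window is centered in the rest phase; when the
        leftover guard is odd, the extra sample goes before the window.
    rest_label : str
        State label assigned to rest epochs.

    Returns
    -------
    list of Segment
        2 segments per trial (task then rest), in trial order.
    """
    sched = recording.schedule
    fs = recording.sampling_rate
    rest_len = int(math.floor(rest_window * fs))
    if rest_len < 1:
        raise ValueError("rest_window too small: yields an empty segment")
    segments: list[Segment] = []
    for i, trial in enumerate(sched.trials):
        task_start = trial.onset + sched.intro_samples
        task_stop = task_start + sched.task_samples
        rest_phase_start = task_stop
        rest_phase_len = sched.rest_samples(trial)
        guard = rest_phase_len - rest_len
        if guard < 0:
            raise ValueError(
                f"rest_window {rest_window} s ({rest_len} samples) exceeds the "
                f"{trial.rest_duration:.3f}-s rest phase of trial {i}"
            )
        rest_start = rest_phase_start + (guard + 1) // 2
        if rest_start + rest_len > recording.n_samples:
            raise ValueError(f"trial {i} extends past the end of the recording")
        segments.append(
            Segment(
                subject_id=recording.subject_id,
                view=recording.view,
                state=trial.task,
                trial_index=i,
                data=recording.data[task_start:task_stop].copy(),
                sampling_rate=fs,
                start=task_start,
            )
        )
        segments.append(
            Segment(
                subject_id=recording.subject_id,
                view=recording.view,
                state=rest_label,
                trial_index=i,
                data=recording.data[rest_start : rest_start + rest_len].copy(),
                sampling_rate=fs,
                start=rest_start,
            )
        )
    return segments
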