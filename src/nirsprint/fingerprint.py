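"""Brain-functional-network (BFN) estimation and per-class fingerprints.

A BFN is a dense, signed 20x20 matrix of Pearson correlations between
channel time series over one segment.  A subject's fingerprint for a class
(RHT, LHT, FT, or REST) is the element-wise average of all that class's
BFNs; at the default paradigm each task class averages 25 networks and REST
averages 75, giving 4 fingerprints per subject per view.

Averaging is done on raw correlation values (no Fisher z-transform, no
thresholding); ``group_and_average(..., fisher=True)`` averages in z-space
for comparison.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np

from .segment import Segment


@dataclass(frozen=True)
class BFN:
    """A symmetric channel x channel correlation network."""

    weights: np.ndarray
    class_label: str
    subject_id: str
    view: str
    n_segments_averaged: int = 1

    def __post_init__(self) -> None:
        w = np.asarray(self.weights)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("BFN weights must be a square matrix")
        if not np.allclose(w, w.T, atol=1e-10):
            raise ValueError("BFN weights must be symmetric")
        if not np.allclose(np.diag(w), 1.0, atol=1e-10):
            raise ValueError("BFN diagonal must be 1")
        if np.nanmax(np.abs(w)) > 1.0 + 1e-10:
            raise ValueError("BFN entries must lie in [-1, 1]")
        if not np.all(np.isfinite(w)):
            raise ValueError("BFN contains non-finite entries")

    @property
    def n_channels(self) -> int:
        return self.weights.shape[0]


@dataclass(frozen=True)
class FingerprintSet:
    """One subject x view: a class-label -> fingerprint-BFN map."""

    subject_id: str
    view: str
    fingerprints: dict[str, BFN]

    def __post_init__(self) -> None:
        dims = {b.n_channels for b in self.fingerprints.values()}
        if len(dims) > 1:
            raise ValueError("fingerprints must all share one dimension")
        for label, b in self.fingerprints.items():
            if b.subject_id != self.subject_id or b.view != self.view:
                raise ValueError(
                    f"fingerprint {label!r} belongs to "
                    f"({b.subject_id}, {b.view}), not ({self.subject_id}, {self.view})"
                )

    @property
    def classes(self) -> tuple[str, ...]:
        return tuple(self.fingerprints)


def pearson_network(segment: Segment) -> BFN:
    """Estimate the Pearson-correlation network of one segment.

    Raises
    ------
    ValueError
        If the segment has fewer than 3 samples, or any channel has zero
        variance (every channel is kept in this pipeline, so a flat channel
        is a hard error rather than a silent NaN).
    """
    data = np.asarray(segment.data, dtype=float)
    if data.shape[0] < 3:
        raise ValueError(
            f"need >= 3 samples to estimate correlations, got {data.shape[0]}"
        )
    sd = data.std(axis=0)
    flat = np.flatnonzero(sd <= 1e-13 * (np.abs(data).max(initial=0.0) + 1.0))
    if flat.size:
        raise ValueError(
            f"channel(s) {flat.tolist()} have zero variance in trial "
            f"{segment.trial_index} ({segment.state}); correlation undefined"
        )
    w = np.corrcoef(data, rowvar=False)
    w = np.clip((w + w.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(w, 1.0)
    return BFN(
        weights=w,
        class_label=segment.state,
        subject_id=segment.subject_id,
        view=segment.view,
    )


def group_and_average(
    bfns: list[BFN],
    expected_classes: tuple[str, ...] | None = None,
    fisher: bool = False,
) -> FingerprintSet:
    """Average BFNs element-wise within each class label.

    Parameters
    ----------
    bfns : list of BFN
        Per-segment networks of a single subject and view.
    expected_classes : tuple of str, optional
        If given, exactly these classes must be present (an empty class is
        an error).
    fisher : bool
        Average in Fisher z-space instead of on raw correlations.
    """
    if not bfns:
        raise ValueError("no BFNs to average")
    subjects = {b.subject_id for b in bfns}
    views = {b.view for b in bfns}
    dims = {b.n_channels for b in bfns}
    if len(subjects) > 1 or len(views) > 1:
        raise ValueError(
            f"BFNs mix subjects/views: subjects={sorted(subjects)}, views={sorted(views)}"
        )
    if len(dims) > 1:
        raise ValueError(f"BFNs mix dimensions: {sorted(dims)}")

    groups: dict[str, list[np.ndarray]] = defaultdict(list)
    for b in bfns:
        groups[b.class_label].append(b.weights)
    if expected_classes is not None:
        missing = [c for c in expected_classes if c not in groups]
        if missing:
            raise ValueError(f"no BFNs for class(es) {missing}")
        extra = [c for c in groups if c not in expected_classes]
        if extra:
            raise ValueError(f"unexpected class(es) {extra}")

    subject_id, view = subjects.pop(), views.pop()
    fingerprints: dict[str, BFN] = {}
    for label, mats in groups.items():
        stack = np.stack(mats)
        if fisher:
            z = np.arctanh(np.clip(stack, -1 + 1e-12, 1 - 1e-12))
            mean = np.tanh(z.mean(axis=0))
            np.fill_diagonal(mean, 1.0)
        else:
            mean = stack.mean(axis=0)
        mean = np.clip((mean + mean.T) / 2.0, -1.0, 1.0)
        np.fill_diagonal(mean, 1.0)
        fingerprints[label] = BFN(
            weights=mean,
            class_label=label,
            subject_id=subject_id,
            view=view,
            n_segments_averaged=len(mats),
        )
    return FingerprintSet(subject_id=subject_id, view=view, fingerprints=fingerprints)
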