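"""Nearest-neighbor individual identification from BFN fingerprints.

Given a *source set* (one fingerprint per subject from one state/view) and a
*target set* (one per subject from another state/view), each target is
matched to the source with maximal similarity, where similarity is the
Pearson correlation between the two networks' edge weights.  A prediction
scores 1 if it recovers the true subject; accuracy is the mean score over
subjects.  With 4 classes (3 tasks + rest) there are 16 ordered
source-target combinations per view pair.

Similarity is computed over the strictly upper-triangular off-diagonal
weights by default: the unit diagonal is constant across all BFNs and the
lower triangle duplicates the upper, so including them inflates similarity
without adding information (``vectorization="full"`` flattens the whole
matrix for comparison).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fingerprint import BFN, FingerprintSet

CLASS_ORDER = ("RHT", "LHT", "FT", "REST")


@dataclass(frozen=True)
class ModeSpec:
    """One identification mode: which class and view feed each side."""

    source_class: str
    target_class: str
    source_view: str = "OXY"
    target_view: str = "OXY"


@dataclass
class IdentificationResult:
    """Predictions, per-subject scores and accuracy for one mode."""

    mode: ModeSpec
    predictions: dict[str, str]
    scores: dict[str, int]
    n_correct: int
    accuracy: float
    similarity_table: pd.DataFrame  # rows: target subject, cols: source subject

    def __post_init__(self) -> None:
        n = len(self.predictions)
        if self.n_correct != sum(self.scores.values()):
            raise ValueError("n_correct inconsistent with scores")
        if abs(self.accuracy - self.n_correct / n) > 1e-12:
            raise ValueError("accuracy inconsistent with n_correct / n_subjects")


def _vectorize(bfn: BFN, vectorization: str) -> np.ndarray:
    w = bfn.weights
    if vectorization == "upper":
        iu = np.triu_indices(w.shape[0], k=1)
        return w[iu]
    if vectorization == "full":
        return w.ravel()
    raise ValueError(f"unknown vectorization {vectorization!r}")


def similarity(a: BFN, b: BFN, vectorization: str = "upper") -> float:
    """Pearson correlation between two BFNs' edge-weight vectors."""
    if a.n_channels != b.n_channels:
        raise ValueError(
            f"BFN dimensions differ: {a.n_channels} vs {b.n_channels}"
        )
    va, vb = _vectorize(a, vectorization), _vectorize(b, vectorization)
    tol = 1e-12
    if va.std() <= tol * (np.abs(va).max() + 1) or vb.std() <= tol * (np.abs(vb).max() + 1):
        raise ValueError("BFN edge weights have zero variance; similarity undefined")
    return float(np.corrcoef(va, vb)[0, 1])


def predict_identity(
    target: BFN, source_set: list[BFN], vectorization: str = "upper"
) -> str:
    """Nearest-neighbor prediction: the source subject with maximal similarity.

    Exact ties are broken toward the earliest subject in ``source_set``
    order, with a warning (ties have measure zero on real data but the rule
    must be deterministic).
    """
    if not source_set:
        raise ValueError("source_set is empty")
    ids = [b.subject_id for b in source_set]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate subject ids in source_set: {ids}")
    sims = np.array([similarity(target, s, vectorization) for s in source_set])
    best = int(np.argmax(sims))
    if np.sum(sims == sims[best]) > 1:
        warnings.warn(
            f"similarity tie at {sims[best]:.6f}; choosing earliest subject "
            f"{ids[best]}",
            stacklevel=2,
        )
    return ids[best]


def _index_sets(
    fingerprints: list[FingerprintSet],
) -> tuple[list[str], dict[tuple[str, str], FingerprintSet]]:
    subjects: list[str] = []
    by_key: dict[tuple[str, str], FingerprintSet] = {}
    for fs in fingerprints:
        if fs.subject_id not in subjects:
            subjects.append(fs.subject_id)
        key = (fs.subject_id, fs.view)
        if key in by_key:
            raise ValueError(f"duplicate fingerprint set for {key}")
        by_key[key] = fs
    return subjects, by_key


def _get_bfn(
    by_key: dict[tuple[str, str], FingerprintSet],
    subject: str,
    view: str,
    class_label: str,
) -> BFN:
    key = (subject, view)
    if key not in by_key:
        raise ValueError(f"no fingerprint set for subject {subject!r}, view {view!r}")
    fps = by_key[key].fingerprints
    if class_label not in fps:
        raise ValueError(
            f"subject {subject!r} (view {view!r}) has no {class_label!r} fingerprint"
        )
    return fps[class_label]


def run_mode(
    mode: ModeSpec,
    fingerprints: list[FingerprintSet],
    vectorization: str = "upper",
) -> IdentificationResult:
    """Run one source/target identification mode over a cohort.

    The full subjects x subjects similarity table (rows: target subject,
    columns: source subject) is retained in the result.
    """
    subjects, by_key = _index_sets(fingerprints)
    sources = [
        _get_bfn(by_key, s, mode.source_view, mode.source_class) for s in subjects
    ]
    targets = [
        _get_bfn(by_key, s, mode.target_view, mode.target_class) for s in subjects
    ]
    table = pd.DataFrame(
        [[similarity(t, s, vectorization) for s in sources] for t in targets],
        index=pd.Index(subjects, name="target"),
        columns=pd.Index(subjects, name="source"),
    )
    predictions: dict[str, str] = {}
    scores: dict[str, int] = {}
    for subj in subjects:
        row = table.loc[subj].to_numpy()
        best = int(np.argmax(row))
        if np.sum(row == row[best]) > 1:
            warnings.warn(
                f"similarity tie for target {subj}; choosing earliest subject",
                stacklevel=2,
            )
        predictions[subj] = subjects[best]
        scores[subj] = int(predictions[subj] == subj)
    n_correct = sum(scores.values())
    return IdentificationResult(
        mode=mode,
        predictions=predictions,
        scores=scores,
        n_correct=n_correct,
        accuracy=n_correct / len(subjects),
        similarity_table=table,
    )


def _accuracy_matrix(
    fingerprints: list[FingerprintSet],
    source_view: str,
    target_view: str,
    classes: tuple[str, ...],
    vectorization: str,
    return_results: bool,
):
    acc = pd.DataFrame(
        np.zeros((len(classes), len(classes))),
        index=pd.Index(classes, name="target"),
        columns=pd.Index(classes, name="source"),
    )
    results: dict[tuple[str, str], IdentificationResult] = {}
    for src in classes:
        for tgt in classes:
            mode = ModeSpec(
                source_class=src,
                target_class=tgt,
                source_view=source_view,
                target_view=target_view,
            )
            res = run_mode(mode, fingerprints, vectorization)
            acc.loc[tgt, src] = res.accuracy
            results[(src, tgt)] = res
    acc.attrs["source_view"] = source_view
    acc.attrs["target_view"] = target_view
    if return_results:
        return acc, results
    return acc


def cross_task_matrix(
    fingerprints: list[FingerprintSet],
    view: str = "OXY",
    classes: tuple[str, ...] = CLASS_ORDER,
    vectorization: str = "upper",
    return_results: bool = False,
):
    """Accuracy for every ordered (source class, target class) pair, one view.

    Rows are target classes, columns source classes; 16 cells for the four
    classes.  Diagonal cells compare a class against itself and are 1.0 by
    self-match.
    """
    return _accuracy_matrix(
        fingerprints, view, view, classes, vectorization, return_results
    )


def cross_view_matrix(
    fingerprints: list[FingerprintSet],
    source_view: str = "OXY",
    target_view: str = "DEOXY",
    classes: tuple[str, ...] = CLASS_ORDER,
    vectorization: str = "upper",
    return_results: bool = False,
):
    """Accuracy for every ordered class pair with source and target from
    different hemoglobin views.  With ``source_view == target_view`` this
    reduces exactly to :func:`cross_task_matrix`."""
    return _accuracy_matrix(
        fingerprints, source_view, target_view, classes, vectorization, return_results
    )


def summarize(matrix: pd.DataFrame, include_diagonal: bool = False) -> tuple[float, float]:
    """Mean and sample standard deviation (ddof=1) of the accuracy cells.

    By default the diagonal (same source and target class) is excluded: for
    cross-task matrices it is a trivial self-match.  Both summaries are
    worth reporting because diagonal handling changes the headline number.
    """
    values = matrix.to_numpy(dtype=float)
    if values.size == 0:
        raise ValueError("empty accuracy matrix")
    if include_diagonal:
        cells = values.ravel()
    else:
        mask = ~np.eye(values.shape[0], values.shape[1], dtype=bool)
        cells = values[mask]
    sd = float(np.std(cells, ddof=1)) if cells.size > 1 else 0.0
    return float(np.mean(cells)), sd
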