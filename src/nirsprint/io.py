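"""Interchange formats: TSV signal matrices with JSON sidecars.

The pipeline's native on-disk format is deliberately plain text:

* a recording is ``<subject>_<view>.tsv`` (one header row of channel labels,
  one row per sample) plus ``<subject>_<view>.json`` holding the trial
  schedule, sampling rate, view, subject id and provenance metadata;
* segments are one TSV each plus a single ``segments_manifest.json``;
* a fingerprint (BFN) is a channels x channels TSV plus JSON metadata;
* accuracy matrices are CSV, full identification results JSON.

SNIRF import (the community standard for fNIRS) is provided through MNE when
it is installed; it maps hemoglobin channels and annotations into the native
types.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .fingerprint import BFN, FingerprintSet
from .paradigm import OXY, ParadigmConfig, Trial, TrialSchedule
from .segment import Segment
from .simulate import Recording

_FLOAT_FMT = "%.17g"  # full double precision for lossless round-trips


# ---------------------------------------------------------------- recordings

def _schedule_to_dict(schedule: TrialSchedule) -> dict:
    return {
        "intro_samples": schedule.intro_samples,
        "task_samples": schedule.task_samples,
        "sampling_rate": schedule.sampling_rate,
        "trials": [
            {
                "session_index": t.session_index,
                "onset": t.onset,
                "task": t.task,
                "rest_duration": t.rest_duration,
            }
            for t in schedule.trials
        ],
    }


def _schedule_from_dict(d: dict) -> TrialSchedule:
    return TrialSchedule(
        trials=tuple(
            Trial(
                session_index=int(t["session_index"]),
                onset=int(t["onset"]),
                task=str(t["task"]),
                rest_duration=float(t["rest_duration"]),
            )
            for t in d["trials"]
        ),
        intro_samples=int(d["intro_samples"]),
        task_samples=int(d["task_samples"]),
        sampling_rate=float(d["sampling_rate"]),
    )


def recording_basename(recording: Recording) -> str:
    return f"{recording.subject_id}_{recording.view}"


def write_recording(recording: Recording, directory: str | Path) -> Path:
    """Write a recording as TSV + JSON sidecar; returns the TSV path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    base = directory / recording_basename(recording)
    tsv = base.with_suffix(".tsv")
    header = "\t".join(recording.channel_labels)
    np.savetxt(tsv, recording.data, fmt=_FLOAT_FMT, delimiter="\t",
               header=header, comments="")
    sidecar = {
        "subject_id": recording.subject_id,
        "view": recording.view,
        "sampling_rate": recording.sampling_rate,
        "n_samples": recording.n_samples,
        "channel_labels": list(recording.channel_labels),
        "schedule": _schedule_to_dict(recording.schedule),
        "meta": recording.meta,
    }
    base.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return tsv


def read_recording(path: str | Path) -> Recording:
    """Read a TSV + JSON recording pair written by :func:`write_recording`.

    ``path`` may point at the TSV, the JSON, or the common basename.
    """
    path = Path(path)
    base = path.with_suffix("") if path.suffix in (".tsv", ".json") else path
    tsv, sidecar_path = base.with_suffix(".tsv"), base.with_suffix(".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing JSON sidecar {sidecar_path}")
    if not tsv.exists():
        raise FileNotFoundError(f"missing signal TSV {tsv}")
    sidecar = json.loads(sidecar_path.read_text())
    frame = pd.read_csv(tsv, sep="\t", float_precision="round_trip")
    labels = list(sidecar["channel_labels"])
    if list(frame.columns) != labels:
        raise ValueError(
            f"{tsv.name}: TSV has {len(frame.columns)} column(s) "
            f"{list(frame.columns)[:3]}..., sidecar declares {len(labels)} "
            f"channel label(s)"
        )
    data = frame.to_numpy(dtype=float)
    if not np.all(np.isfinite(data)):
        raise ValueError(f"{tsv.name}: signal contains non-finite values")
    if data.shape[0] != int(sidecar["n_samples"]):
        raise ValueError(
            f"{tsv.name}: {data.shape[0]} rows but sidecar declares "
            f"{sidecar['n_samples']} samples"
        )
    return Recording(
        subject_id=sidecar["subject_id"],
        view=sidecar["view"],
        data=data,
        sampling_rate=float(sidecar["sampling_rate"]),
        schedule=_schedule_from_dict(sidecar["schedule"]),
        channel_labels=tuple(labels),
        meta=dict(sidecar.get("meta", {})),
    )


def list_recordings(directory: str | Path) -> list[Path]:
    """TSV paths of all recording pairs in a directory, sorted."""
    directory = Path(directory)
    return sorted(
        p for p in directory.glob("*.tsv") if p.with_suffix(".json").exists()
    )


# ------------------------------------------------------------------ segments

def write_segments(
    segments: list[Segment], directory: str | Path, channel_labels: tuple[str, ...]
) -> Path:
    """Write segments as TSVs plus a manifest; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest_path = directory / "segments_manifest.json"
    entries = []
    if manifest_path.exists():
        entries = json.loads(manifest_path.read_text())["segments"]
    header = "\t".join(channel_labels)
    for seg in segments:
        name = f"{seg.subject_id}_{seg.view}_t{seg.trial_index:03d}_{seg.state}.tsv"
        np.savetxt(directory / name, seg.data, fmt=_FLOAT_FMT, delimiter="\t",
                   header=header, comments="")
        entries.append(
            {
                "file": name,
                "subject_id": seg.subject_id,
                "view": seg.view,
                "state": seg.state,
                "trial_index": seg.trial_index,
                "start": seg.start,
                "n_samples": seg.n_samples,
                "sampling_rate": seg.sampling_rate,
            }
        )
    manifest_path.write_text(
        json.dumps({"channel_labels": list(channel_labels), "segments": entries},
                   indent=1)
    )
    return manifest_path


def read_segments(directory: str | Path) -> list[Segment]:
    directory = Path(directory)
    manifest = json.loads((directory / "segments_manifest.json").read_text())
    segments = []
    for e in manifest["segments"]:
        data = pd.read_csv(directory / e["file"], sep="\t", float_precision="round_trip").to_numpy(dtype=float)
        if data.shape[0] != e["n_samples"]:
            raise ValueError(f"{e['file']}: row count disagrees with manifest")
        segments.append(
            Segment(
                subject_id=e["subject_id"],
                view=e["view"],
                state=e["state"],
                trial_index=int(e["trial_index"]),
                data=data,
                sampling_rate=float(e["sampling_rate"]),
                start=int(e["start"]),
            )
        )
    return segments


# -------------------------------------------------------------- fingerprints

def write_fingerprint_set(fset: FingerprintSet, directory: str | Path) -> None:
    """One TSV per class BFN plus a shared JSON metadata file per set."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {"subject_id": fset.subject_id, "view": fset.view, "classes": {}}
    for label, bfn in fset.fingerprints.items():
        name = f"{fset.subject_id}_{fset.view}_{label}.tsv"
        n = bfn.n_channels
        header = "\t".join(f"CH{i + 1:02d}" for i in range(n))
        np.savetxt(directory / name, bfn.weights, fmt=_FLOAT_FMT, delimiter="\t",
                   header=header, comments="")
        meta["classes"][label] = {
            "file": name,
            "n_segments_averaged": bfn.n_segments_averaged,
        }
    (directory / f"{fset.subject_id}_{fset.view}.json").write_text(
        json.dumps(meta, indent=1)
    )


def read_fingerprint_sets(directory: str | Path) -> list[FingerprintSet]:
    directory = Path(directory)
    sets = []
    for meta_path in sorted(directory.glob("*.json")):
        meta = json.loads(meta_path.read_text())
        if "classes" not in meta:
            continue
        fingerprints = {}
        for label, info in meta["classes"].items():
            w = pd.read_csv(directory / info["file"], sep="\t", float_precision="round_trip").to_numpy(dtype=float)
            fingerprints[label] = BFN(
                weights=w,
                class_label=label,
                subject_id=meta["subject_id"],
                view=meta["view"],
                n_segments_averaged=int(info["n_segments_averaged"]),
            )
        sets.append(
            FingerprintSet(
                subject_id=meta["subject_id"],
                view=meta["view"],
                fingerprints=fingerprints,
            )
        )
    return sets


# ------------------------------------------------------------------- results

def write_accuracy_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    """CSV with explicit axis labels: rows are targets, columns sources."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = matrix.copy()
    out.index.name = "target\\source"
    out.to_csv(path)


def read_accuracy_matrix(path: str | Path) -> pd.DataFrame:
    m = pd.read_csv(path, index_col=0)
    m.index.name = "target"
    m.columns.name = "source"
    return m


def write_results_json(results: dict, path: str | Path) -> None:
    """Serialize per-mode identification results (tables as nested dicts)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {}
    for key, res in results.items():
        payload["->".join(key) if isinstance(key, tuple) else key] = {
            "mode": vars(res.mode),
            "predictions": res.predictions,
            "scores": res.scores,
            "n_correct": res.n_correct,
            "accuracy": res.accuracy,
            "similarity_table": res.similarity_table.round(10).to_dict(),
        }
    path.write_text(json.dumps(payload, indent=1))


# -------------------------------------------------------------- SNIRF import

def read_snirf(
    path: str | Path,
    view: str = OXY,
    paradigm: ParadigmConfig | None = None,
) -> Recording:
    """Import a SNIRF file's hemoglobin time series as a Recording.

    Requires MNE.  Channels of type hbo map to the OXY view and hbr to
    DEOXY.  Trial onsets are taken from the file's annotations (one trial
    per annotation whose description is a task label); phase durations come
    from ``paradigm`` (default :class:`ParadigmConfig`), and each trial's
    rest duration is whatever remains until the next onset (or the end of
    the recording).  This is an adapter for externally recorded data, not a
    loader for any specific study layout.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("SNIRF import requires the 'mne' package") from exc
    if paradigm is None:
        paradigm = ParadigmConfig()
    raw = mne.io.read_raw_snirf(str(path), preload=True, verbose="error")
    ch_type = "hbo" if view == OXY else "hbr"
    picks = mne.pick_types(raw.info, fnirs=ch_type)
    if len(picks) == 0:
        raise ValueError(f"no {ch_type} channels found in {path}")
    data = raw.get_data(picks).T
    fs = float(raw.info["sfreq"])
    labels = tuple(raw.ch_names[i] for i in picks)

    intro_len = int(np.floor(paradigm.intro_duration * fs + 0.5))
    task_len = int(np.floor(paradigm.task_duration * fs))
    onsets = [
        (float(a["onset"]), str(a["description"]))
        for a in raw.annotations
        if str(a["description"]) in paradigm.task_labels
    ]
    trials = []
    for i, (onset_s, task) in enumerate(onsets):
        onset = int(np.floor(onset_s * fs + 0.5))
        end_s = onsets[i + 1][0] if i + 1 < len(onsets) else data.shape[0] / fs
        rest = end_s - onset_s - paradigm.intro_duration - paradigm.task_duration
        if rest <= 0:
            raise ValueError(f"annotation {i} leaves no rest phase before the next")
        trials.append(
            Trial(session_index=0, onset=onset, task=task, rest_duration=rest)
        )
    if not trials:
        raise ValueError(f"no task annotations found in {path}")
    schedule = TrialSchedule(
        trials=tuple(trials),
        intro_samples=intro_len,
        task_samples=task_len,
        sampling_rate=fs,
    )
    subject = Path(path).stem
    return Recording(
        subject_id=subject,
        view=view,
        data=data,
        sampling_rate=fs,
        schedule=schedule,
        channel_labels=labels,
        meta={"source": str(path), "format": "snirf"},
    )
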