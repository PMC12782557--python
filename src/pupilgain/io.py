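"""Delimited-text readers and writers for the pipeline's on-disk formats.

All formats are plain TSV (plus one JSON sidecar for the epoch time axis):

* samples:   ``t_s``, ``pupil``, ``valid`` (0/1)
* artifacts: ``kind``, ``start_s``, ``end_s``
* events:    ``subject``, ``trial``, ``event_k``, ``is_oddball``, condition
  labels, ``feedback_onset_s``, ``rt_s``, ``accuracy``, ``frequency``
* trial info: ``subject``, ``trial``, ``event_k``, ``p_pred``, ``I_bits``,
  ``H_bits``, ``DKL_bits``
* epochs:    first column trial id, remaining columns timepoints, with a
  ``.time.json`` sidecar holding the time axis
* windows:   ``subject``, ``trial``, ``baseline``, ``early``, ``late``
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .learner import EventSequence
from .preprocess import ArtifactAnnotations, EpochSet, PupilRecording

__all__ = [
    "read_samples_tsv",
    "write_samples_tsv",
    "read_artifacts_tsv",
    "write_artifacts_tsv",
    "read_events_tsv",
    "write_events_tsv",
    "events_to_sequence",
    "write_trial_info_tsv",
    "read_trial_info_tsv",
    "write_epochs",
    "read_epochs",
]


def write_samples_tsv(rec: PupilRecording, path) -> None:
    pd.DataFrame(
        {"t_s": rec.t, "pupil": rec.y, "valid": rec.valid.astype(int)}
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_samples_tsv(path) -> PupilRecording:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    t = df["t_s"].to_numpy(dtype=float)
    fs = 1.0 / np.median(np.diff(t))
    return PupilRecording(
        t=t,
        y=df["pupil"].to_numpy(dtype=float),
        fs=float(np.round(fs, 6)),
        valid=df["valid"].to_numpy(dtype=bool),
    )


def write_artifacts_tsv(ann: ArtifactAnnotations, path) -> None:
    pd.DataFrame(ann.intervals, columns=["kind", "start_s", "end_s"]).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def read_artifacts_tsv(path) -> ArtifactAnnotations:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return ArtifactAnnotations(
        [(str(k), float(a), float(b)) for k, a, b in df.itertuples(index=False)]
    )


def write_events_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_events_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", float_precision="round_trip")


def events_to_sequence(table: pd.DataFrame, K: int) -> EventSequence:
    """Build an :class:`EventSequence` from an events table."""
    flags = None
    if "is_oddball" in table.columns:
        flags = table["is_oddball"].to_numpy(dtype=bool)
    return EventSequence(
        events=table["event_k"].to_numpy(dtype=int), K=K, is_oddball=flags
    )


def write_trial_info_tsv(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_trial_info_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", float_precision="round_trip")


def write_epochs(epochs: EpochSet, path) -> None:
    """Epoch matrix as TSV (trial id first) plus a JSON time-axis sidecar."""
    path = Path(path)
    trial = (
        epochs.labels["trial"].to_numpy()
        if "trial" in epochs.labels.columns
        else np.arange(1, epochs.n_trials + 1)
    )
    df = pd.DataFrame(epochs.data)
    df.insert(0, "trial", trial)
    df.to_csv(path, sep="\t", index=False, header=False, float_format="%.17g")
    sidecar = path.with_suffix(path.suffix + ".time.json")
    sidecar.write_text(json.dumps({"time_s": epochs.time.tolist()}))
    epochs.labels.to_csv(
        path.with_suffix(path.suffix + ".labels.tsv"), sep="\t", index=False,
        float_format="%.17g"
    )


def read_epochs(path) -> EpochSet:
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", header=None, float_precision="round_trip")
    time = np.asarray(
        json.loads(path.with_suffix(path.suffix + ".time.json").read_text())["time_s"]
    )
    labels_path = path.with_suffix(path.suffix + ".labels.tsv")
    if labels_path.exists():
        labels = pd.read_csv(labels_path, sep="\t", float_precision="round_trip")
    else:
        labels = pd.DataFrame({"trial": raw.iloc[:, 0].to_numpy()})
    return EpochSet(data=raw.iloc[:, 1:].to_numpy(dtype=float), time=time,
                    labels=labels)
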