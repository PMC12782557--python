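"""Pupil preprocessing: from raw trace to feedback-locked window averages.

The chain mirrors standard pupillometry practice: (i)-(ii) linear
interpolation around missing samples and blink/saccade artifacts (padded by
0.15 s on each side), (iii) third-order Butterworth band-pass 0.01-6 Hz,
(iv) deconvolution-based nuisance regression of blink/saccade responses,
(v) conversion to percent signal change, then epoching around feedback
onsets, per-trial baseline correction over the 0.5 s pre-feedback window,
and early (0.75-1.25 s) / late (2.5-3 s) window means.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal, sparse

logger = logging.getLogger(__name__)

__all__ = [
    "PupilRecording",
    "ArtifactAnnotations",
    "EpochSet",
    "NuisanceFit",
    "detect_derivative_artifacts",
    "missing_intervals",
    "interpolate_intervals",
    "bandpass_filter",
    "remove_nuisance_responses",
    "percent_signal_change",
    "extract_epochs",
    "baseline_and_window",
    "exclude_rt_outliers",
]


class InvalidRecordingError(ValueError):
    pass


@dataclass
class PupilRecording:
    """A uniformly sampled pupil trace.

    ``stage`` tracks which processing steps have been applied (free-form,
    e.g. ``"raw"``, ``"interpolated"``, ``"filtered"``, ``"residual"``,
    ``"psc"``).
    """

    t: np.ndarray
    y: np.ndarray
    fs: float
    valid: np.ndarray | None = None
    stage: str = "raw"

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.valid is None:
            self.valid = np.ones(self.t.size, dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not (self.t.size == self.y.size == self.valid.size):
            raise InvalidRecordingError("t, y, valid must have equal length")
        if self.t.size >= 2:
            dt = np.diff(self.t)
            step = 1.0 / self.fs
            if np.any(np.abs(dt - step) > 1e-9 * max(1.0, abs(step))):
                raise InvalidRecordingError("sampling must be uniform at 1/fs")

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) if self.t.size else 0.0


@dataclass
class ArtifactAnnotations:
    """Artifact intervals as ``(kind, start_s, end_s)`` tuples."""

    intervals: list[tuple[str, float, float]] = field(default_factory=list)

    def __post_init__(self):
        for kind, a, b in self.intervals:
            if not a < b:
                raise ValueError(f"interval {kind} [{a}, {b}] has start >= end")

    def __len__(self):
        return len(self.intervals)

    def __add__(self, other: "ArtifactAnnotations") -> "ArtifactAnnotations":
        return ArtifactAnnotations(list(self.intervals) + list(other.intervals))

    def kinds(self) -> list[str]:
        return sorted({k for k, _, _ in self.intervals})

    def of_kind(self, kind: str) -> list[tuple[float, float]]:
        return [(a, b) for k, a, b in self.intervals if k == kind]


def detect_derivative_artifacts(
    rec: PupilRecording, threshold: float = 10.0
) -> ArtifactAnnotations:
    """Flag samples whose absolute first difference exceeds ``threshold``.

    ``threshold`` is in raw device units per sample (device-dependent; the
    conventional default is a minimum peak height of 10 units).  Adjacent
    flagged samples are merged into single intervals.
    """
    dy = np.abs(np.diff(rec.y))
    hits = dy > threshold
    intervals = [
        # difference i..i+1 implicates samples i and i+1
        ("derivative_spike", float(rec.t[i0]), float(rec.t[i1]))
        for i0, i1 in _bool_runs(hits)
    ]
    return ArtifactAnnotations(intervals)


def _bool_runs(mask: np.ndarray):
    """(first, last) index pairs of consecutive True runs."""
    d = np.diff(np.concatenate(([0], mask.view(np.int8), [0])))
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    return list(zip(starts, stops))


def missing_intervals(rec: PupilRecording) -> ArtifactAnnotations:
    """Intervals of invalid (missing) samples from the validity mask."""
    inv = ~rec.valid
    half = 0.5 / rec.fs
    intervals = [
        ("missing", float(rec.t[i0]), float(rec.t[i1 - 1]) + half)
        for i0, i1 in _bool_runs(inv)
    ]
    return ArtifactAnnotations(intervals)


def _merge(spans: list[tuple[float, float]]) -> list[tuple[float, float]]:
    if not spans:
        return []
    spans = sorted(spans)
    out = [list(spans[0])]
    for a, b in spans[1:]:
        if a <= out[-1][1]:
            out[-1][1] = max(out[-1][1], b)
        else:
            out.append([a, b])
    return [(a, b) for a, b in out]


def interpolate_intervals(
    rec: PupilRecording, annotations: ArtifactAnnotations, pad_s: float = 0.15
) -> PupilRecording:
    """Linearly interpolate across padded artifact intervals.

    Each interval is expanded by ``pad_s`` on both sides (clamped to the
    recording; overlapping padded spans merged) and the samples inside are
    replaced by linear interpolation between the nearest samples outside.
    Gaps extending past either edge are filled with the nearest kept value.
    """
    if not len(annotations):
        return replace(rec, y=rec.y.copy(), valid=np.ones_like(rec.valid),
                       stage="interpolated")
    t0, t1 = rec.t[0], rec.t[-1]
    spans = _merge(
        [(max(a - pad_s, t0), min(b + pad_s, t1)) for _, a, b in annotations.intervals]
    )
    bad = np.zeros(rec.t.size, dtype=bool)
    for a, b in spans:
        i0 = int(np.searchsorted(rec.t, a - 1e-12, side="left"))
        i1 = int(np.searchsorted(rec.t, b + 1e-12, side="right"))
        bad[i0:i1] = True
    if bad.all():
        raise InvalidRecordingError("recording entirely covered by artifacts")
    y = rec.y.copy()
    good = ~bad
    y[bad] = np.interp(rec.t[bad], rec.t[good], rec.y[good])
    return replace(rec, y=y, valid=np.ones_like(rec.valid), stage="interpolated")


def bandpass_filter(
    rec: PupilRecording, low: float = 0.01, high: float = 6.0, order: int = 3
) -> PupilRecording:
    """Zero-phase Butterworth band-pass (forward-backward, so no lag)."""
    nyq = rec.fs / 2.0
    if not 0 < low < high < nyq:
        raise ValueError(
            f"cutoffs must satisfy 0 < {low} < {high} < Nyquist ({nyq})"
        )
    sos = signal.butter(order, [low, high], btype="bandpass", fs=rec.fs, output="sos")
    y = signal.sosfiltfilt(sos, rec.y)
    return replace(rec, y=y, stage="filtered")


@dataclass
class NuisanceFit:
    """Estimated finite impulse responses of nuisance events.

    ``kernels`` maps each artifact kind to its FIR estimate on the coarse
    design grid; ``kernel_time`` is the corresponding lag axis in seconds.
    """

    kernels: dict[str, np.ndarray]
    kernel_time: np.ndarray
    design_fs: float
    fitted: np.ndarray

    def kernel_at(self, kind: str, fs: float) -> np.ndarray:
        """Kernel linearly interpolated back to sampling rate ``fs``."""
        t = np.arange(0.0, self.kernel_time[-1] + 1.0 / self.design_fs, 1.0 / fs)
        return np.interp(t, self.kernel_time, self.kernels[kind])


def remove_nuisance_responses(
    rec: PupilRecording,
    annotations: ArtifactAnnotations,
    window_s: float = 6.0,
    design_fs: float = 20.0,
) -> tuple[PupilRecording, NuisanceFit]:
    """Estimate and subtract event-locked nuisance responses.

    For every artifact kind present, an FIR over ``[0, window_s]`` seconds is
    estimated by ordinary least squares from a boxcar design aligned to the
    *end* of each artifact interval (when the eye re-opens), at a coarse
    ``design_fs`` resolution.  The fitted nuisance signal is subtracted.
    With no events the recording passes through unchanged.
    """
    kinds = annotations.kinds()
    n = rec.y.size
    if not kinds:
        return (
            replace(rec, y=rec.y.copy(), stage="residual"),
            NuisanceFit({}, np.array([0.0]), design_fs, np.zeros(n)),
        )
    n_bins = int(round(window_s * design_fs))
    span = int(round(window_s * rec.fs))
    offsets = np.arange(span)
    bin_of = np.minimum(
        (offsets * design_fs / rec.fs).astype(int), n_bins - 1
    )
    row_parts, col_parts = [], []
    col0 = 0
    for kind in kinds:
        for _, onset in annotations.of_kind(kind):
            start = int(np.round((onset - rec.t[0]) * rec.fs))
            idx = start + offsets
            ok = (idx >= 0) & (idx < n)
            row_parts.append(idx[ok])
            col_parts.append(col0 + bin_of[ok])
        col0 += n_bins
    rows = np.concatenate(row_parts)
    cols = np.concatenate(col_parts)
    vals = np.ones(rows.size)
    ncols = n_bins * len(kinds)
    if ncols >= n:
        raise ValueError("more FIR coefficients than samples: underdetermined")
    X = sparse.csr_matrix((vals, (rows, cols)), shape=(n, ncols))
    XtX = (X.T @ X).toarray()
    Xty = X.T @ rec.y
    # ridge epsilon only guards empty columns (events entirely off the edge)
    beta = np.linalg.solve(XtX + 1e-10 * np.eye(ncols), Xty)
    fitted = np.asarray(X @ beta).ravel()
    kernel_time = (np.arange(n_bins) + 0.5) / design_fs
    kernels = {
        kind: beta[i * n_bins : (i + 1) * n_bins] for i, kind in enumerate(kinds)
    }
    out = replace(rec, y=rec.y - fitted, stage="residual")
    return out, NuisanceFit(kernels, kernel_time, design_fs, fitted)


def percent_signal_change(rec: PupilRecording, reference_mean: float) -> PupilRecording:
    """Express the trace as percent signal change of ``reference_mean``.

    The reference is the temporal mean of the signal before nuisance
    residualization (residuals themselves are ~zero-mean).
    """
    if reference_mean <= 0:
        raise ValueError(f"reference mean must be positive, got {reference_mean}")
    return replace(rec, y=100.0 * rec.y / reference_mean, stage="psc")


@dataclass
class EpochSet:
    """Feedback-locked trials x timepoints matrix with per-trial labels."""

    data: np.ndarray
    time: np.ndarray
    labels: pd.DataFrame
    baselines: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        self.time = np.asarray(self.time, dtype=float)
        if self.data.shape[0] != len(self.labels):
            raise ValueError("label rows must align with epoch rows")
        if self.data.shape[1] != self.time.size:
            raise ValueError("time axis must align with epoch columns")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def decimate(self, target_fs: float) -> "EpochSet":
        """Subsample the time axis to roughly ``target_fs`` (no antialiasing:
        the trace is already low-passed well below the new Nyquist)."""
        fs = 1.0 / np.median(np.diff(self.time))
        step = max(int(round(fs / target_fs)), 1)
        return EpochSet(
            data=self.data[:, ::step],
            time=self.time[::step],
            labels=self.labels,
            baselines=self.baselines,
        )


def extract_epochs(
    rec: PupilRecording,
    feedback_onsets_s: np.ndarray,
    window: tuple[float, float] = (-0.5, 3.0),
    labels: pd.DataFrame | None = None,
) -> EpochSet:
    """Cut one epoch per feedback onset, aligned by nearest sample.

    Onsets whose window would leave the recording are dropped with a logged
    warning; their label rows are dropped too.
    """
    onsets = np.asarray(feedback_onsets_s, dtype=float)
    if labels is None:
        labels = pd.DataFrame({"trial": np.arange(1, onsets.size + 1)})
    if len(labels) != onsets.size:
        raise ValueError("labels must have one row per onset")
    n_pre = int(round(-window[0] * rec.fs))
    n_post = int(round(window[1] * rec.fs))
    time = np.arange(-n_pre, n_post + 1) / rec.fs
    rows, kept = [], []
    for i, onset in enumerate(onsets):
        c = int(np.round((onset - rec.t[0]) * rec.fs))
        i0, i1 = c - n_pre, c + n_post + 1
        if i0 < 0 or i1 > rec.y.size:
            logger.warning("trial %d dropped: window outside recording", i + 1)
            continue
        rows.append(rec.y[i0:i1])
        kept.append(i)
    if not rows:
        raise ValueError("no epoch fits inside the recording")
    return EpochSet(
        data=np.vstack(rows),
        time=time,
        labels=labels.iloc[kept].reset_index(drop=True),
    )


def baseline_and_window(
    epochs: EpochSet,
    baseline: tuple[float, float] = (-0.5, 0.0),
    windows: dict[str, tuple[float, float]] | None = None,
) -> tuple[EpochSet, pd.DataFrame]:
    """Baseline-correct each epoch and average over interest windows.

    The per-trial baseline is the mean over ``baseline`` (half-open
    ``[t0, t1)``), subtracted from the whole epoch.  Window means are taken
    on the corrected trace over half-open windows, by default the early
    (0.75-1.25 s) and late (2.5-3.0 s) post-feedback windows.

    Returns the corrected :class:`EpochSet` and a per-trial table with
    ``baseline`` plus one column per window, alongside the label columns.
    """
    if windows is None:
        windows = {"early": (0.75, 1.25), "late": (2.5, 3.0)}
    t = epochs.time
    for name, (a, b) in {**windows, "baseline": baseline}.items():
        if a < t[0] - 1e-9 or b > t[-1] + 1.0 / max(t.size, 1) + 1e-9:
            raise ValueError(f"window {name!r} [{a}, {b}] outside epoch span")
    bmask = (t >= baseline[0]) & (t < baseline[1])
    base = epochs.data[:, bmask].mean(axis=1)
    corrected = epochs.data - base[:, None]
    table = epochs.labels.copy()
    table["baseline"] = base
    for name, (a, b) in windows.items():
        wmask = (t >= a) & (t < b)
        table[name] = corrected[:, wmask].mean(axis=1)
    out = EpochSet(data=corrected, time=t, labels=epochs.labels, baselines=base)
    return out, table


def exclude_rt_outliers(
    rts: np.ndarray,
    subjects: np.ndarray | None = None,
    z_crit: float = 3.0,
) -> np.ndarray:
    """Inclusion mask for reaction times: keep |z| <= ``z_crit`` per subject.

    RTs are z-scored within participant; trials more extreme than
    ``z_crit`` standard deviations are excluded.  Zero-variance participants
    keep all trials (with a warning).
    """
    rts = np.asarray(rts, dtype=float)
    if subjects is None:
        subjects = np.zeros(rts.size, dtype=int)
    subjects = np.asarray(subjects)
    mask = np.ones(rts.size, dtype=bool)
    for s in np.unique(subjects):
        sel = subjects == s
        x = rts[sel]
        if x.size < 2:
            raise ValueError("need at least 2 RTs per participant")
        sd = x.std(ddof=1)
        if sd == 0:
            warnings.warn(f"participant {s}: zero RT variance, nothing excluded")
            continue
        z = (x - x.mean()) / sd
        mask[sel] = np.abs(z) <= z_crit
    frac = 1.0 - mask.mean()
    logger.info("RT outlier exclusion: %.2f%% of trials removed", 100 * frac)
    return mask
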