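"""Synthetic task sequences, behavior, and pupil traces.

Three generative designs are covered:

* a probabilistic cue-target 2AFC (200 trials, two cue shapes, 80/20
  cue-to-orientation contingency, counterbalanced mappings, K = 4
  cue-by-orientation events),
* an odd-ball exposure stream (660 trials, ~9% odd-balls, 6 letters x 6
  green shades; intended letter-color association frequencies 20/40/80%
  which, because the "noise" color is drawn from all six shades, realize
  33/50/84%),
* a letter-color 2AFC (250 trials, match and no-match in a 1:1 ratio,
  events in the same 36-pair space as the exposure stream).

Pupil traces are built from a canonical impulse response (Erlang-shaped,
unit peak at ``t_max``) whose per-trial amplitude loads on the ideal
observer variables, plus slow drift, noise, and annotated blink/saccade
dropouts.  Every generator is bit-reproducible from its (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .learner import EventSequence
from .preprocess import ArtifactAnnotations, PupilRecording

__all__ = [
    "ConfigError",
    "CueTargetConfig",
    "OddballConfig",
    "LetterColorConfig",
    "PupilGenConfig",
    "GroundTruth",
    "LETTERS",
    "COLORS",
    "gen_cue_target_sequence",
    "gen_oddball_sequence",
    "gen_lettercolor_sequence",
    "simulate_behavior",
    "schedule_onsets",
    "pupil_irf",
    "synthesize_pupil",
]

LETTERS = ("A", "D", "I", "O", "R", "T")
COLORS = tuple(f"green{i + 1}" for i in range(6))

CUE_TARGET_EVENTS = ("square-left", "square-right", "diamond-left", "diamond-right")


class ConfigError(ValueError):
    pass


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# --------------------------------------------------------------------------
# cue-target 2AFC


@dataclass(frozen=True)
class CueTargetConfig:
    n_trials: int = 200
    contingency: float = 0.8
    mapping: str = "condition1"  # condition1: square->left frequent
    composition: str = "exact"  # or "iid"

    def __post_init__(self):
        if not 0.0 < self.contingency < 1.0:
            raise ConfigError("contingency must lie in (0, 1)")
        if self.mapping not in ("condition1", "condition2"):
            raise ConfigError(f"unknown mapping {self.mapping!r}")
        if self.composition not in ("exact", "iid"):
            raise ConfigError(f"unknown composition {self.composition!r}")
        if self.n_trials % 2:
            raise ConfigError("n_trials must be even (cues split 50/50)")
        if self.composition == "exact":
            per_cue = self.n_trials // 2
            if abs(per_cue * self.contingency - round(per_cue * self.contingency)) > 1e-9:
                raise ConfigError(
                    f"contingency {self.contingency} does not yield integer "
                    f"counts for {per_cue} trials per cue; use composition='iid' "
                    "or adjust n_trials"
                )


def gen_cue_target_sequence(
    config: CueTargetConfig = CueTargetConfig(), seed=None
) -> tuple[EventSequence, pd.DataFrame]:
    """Generate one participant's cue-target trial sequence.

    Events are the K=4 cue-by-orientation pairs.  With the default exact
    composition, cues are split 50/50 and within each cue the frequent
    (mapped) orientation appears on exactly ``contingency`` of trials.
    """
    rng = _rng(seed)
    n = config.n_trials
    per_cue = n // 2
    # frequent orientation for each cue: condition1 square->left, diamond->right
    freq_ori = (0, 1) if config.mapping == "condition1" else (1, 0)
    cues = np.repeat([0, 1], per_cue)
    if config.composition == "exact":
        n_freq = int(round(per_cue * config.contingency))
        oris = np.empty(n, dtype=int)
        for c in (0, 1):
            block = np.array(
                [freq_ori[c]] * n_freq + [1 - freq_ori[c]] * (per_cue - n_freq)
            )
            oris[cues == c] = block
    else:
        u = rng.random(n)
        oris = np.where(
            u < config.contingency,
            np.array(freq_ori)[cues],
            1 - np.array(freq_ori)[cues],
        )
    order = rng.permutation(n)
    cues, oris = cues[order], oris[order]
    events = cues * 2 + oris
    congruent = oris == np.array(freq_ori)[cues]
    table = pd.DataFrame(
        {
            "trial": np.arange(1, n + 1),
            "cue": np.where(cues == 0, "square", "diamond"),
            "target": np.where(oris == 0, "left", "right"),
            "event_k": events,
            "congruent": congruent,
            "frequency": np.where(congruent, config.contingency, 1 - config.contingency),
        }
    )
    seq = EventSequence(events=events, K=4, labels=CUE_TARGET_EVENTS)
    return seq, table


# --------------------------------------------------------------------------
# odd-ball exposure


@dataclass(frozen=True)
class OddballConfig:
    n_trials: int = 660
    n_oddballs: int = 60  # ~9% of 660
    intended_freqs: tuple[float, ...] = (0.2, 0.4, 0.8)

    def __post_init__(self):
        if self.n_oddballs >= self.n_trials:
            raise ConfigError("n_oddballs must be < n_trials")
        n_reg = self.n_trials - self.n_oddballs
        if n_reg % len(LETTERS):
            raise ConfigError("regular trials must divide evenly over letters")
        if len(self.intended_freqs) * 2 != len(LETTERS):
            raise ConfigError("need two letters per frequency condition")


def actual_association_frequency(intended: float) -> float:
    """Realized associated-color frequency ``f + (1 - f) / 6``.

    The non-signal color is drawn uniformly from all six shades (including
    the associated one), so intended 20/40/80% realize 1/3, 1/2, 5/6.
    """
    return intended + (1.0 - intended) / 6.0


def gen_oddball_sequence(
    config: OddballConfig = OddballConfig(), seed=None
) -> tuple[EventSequence, pd.DataFrame]:
    """Generate one participant's odd-ball exposure stream.

    Each letter is shown equally often over the regular trials; on each
    regular trial of a letter with intended frequency ``f`` the associated
    color appears with probability ``f``, otherwise the color is drawn
    uniformly from all six shades.  Odd-ball trials carry event index -1 and
    the ``is_oddball`` flag; the letter-to-color and letter-to-condition
    assignment is randomized per participant and stored in ``table.attrs``.
    """
    rng = _rng(seed)
    n_reg = config.n_trials - config.n_oddballs
    per_letter = n_reg // len(LETTERS)

    color_of = rng.permutation(len(COLORS))  # associated color per letter
    cond_letters = rng.permutation(len(LETTERS))
    intended_of = np.empty(len(LETTERS))
    for ci, f in enumerate(config.intended_freqs):
        intended_of[cond_letters[2 * ci : 2 * ci + 2]] = f

    letters = np.repeat(np.arange(len(LETTERS)), per_letter)
    use_assoc = rng.random(n_reg) < intended_of[letters]
    colors = np.where(
        use_assoc, color_of[letters], rng.integers(0, len(COLORS), n_reg)
    )
    is_odd = np.zeros(config.n_trials, dtype=bool)
    is_odd[rng.choice(config.n_trials, config.n_oddballs, replace=False)] = True
    reg_order = rng.permutation(n_reg)
    letters, colors = letters[reg_order], colors[reg_order]

    events = np.full(config.n_trials, -1, dtype=int)
    letter_col = np.full(config.n_trials, -1, dtype=int)
    color_col = np.full(config.n_trials, -1, dtype=int)
    events[~is_odd] = letters * len(COLORS) + colors
    letter_col[~is_odd] = letters
    color_col[~is_odd] = colors

    intended = np.full(config.n_trials, np.nan)
    intended[~is_odd] = intended_of[letters]
    table = pd.DataFrame(
        {
            "trial": np.arange(1, config.n_trials + 1),
            "is_oddball": is_odd,
            "letter": letter_col,
            "color": color_col,
            "event_k": events,
            "intended_freq": intended,
            "is_associated": np.where(
                is_odd, False, color_col == np.where(is_odd, -1, color_of[letter_col])
            ),
        }
    )
    assignment = {
        "color_of": color_of.tolist(),
        "intended_of": intended_of.tolist(),
    }
    table.attrs["assignment"] = assignment
    seq = EventSequence(events=events, K=36, is_oddball=is_odd)
    return seq, table


# --------------------------------------------------------------------------
# letter-color 2AFC


@dataclass(frozen=True)
class LetterColorConfig:
    n_trials: int = 250
    composition: str = "ratio_1_1"  # or "equal_36"

    def __post_init__(self):
        if self.composition not in ("ratio_1_1", "equal_36"):
            raise ConfigError(f"unknown composition {self.composition!r}")
        if self.composition == "ratio_1_1" and self.n_trials % 2:
            raise ConfigError("n_trials must be even for a 1:1 match ratio")


def gen_lettercolor_sequence(
    config: LetterColorConfig,
    assignment: dict,
    seed=None,
) -> tuple[EventSequence, pd.DataFrame]:
    """Generate one participant's letter-color 2AFC sequence.

    ``assignment`` is the odd-ball phase's letter-to-color map (the
    ``table.attrs['assignment']`` of :func:`gen_oddball_sequence`).  By
    default, half the trials are matches drawn uniformly from the 6
    associated pairs and half are no-matches drawn uniformly from the 30
    unassociated pairs; the strict equal-frequency-over-36-pairs variant is
    available via ``composition='equal_36'``.
    """
    rng = _rng(seed)
    color_of = np.asarray(assignment["color_of"], dtype=int)
    intended_of = np.asarray(assignment["intended_of"], dtype=float)
    if color_of.size != 6 or np.unique(color_of).size != 6:
        raise ConfigError("assignment must map the 6 letters onto the 6 colors")
    match_pairs = [(l, color_of[l]) for l in range(6)]
    nomatch_pairs = [
        (l, c) for l in range(6) for c in range(6) if c != color_of[l]
    ]
    n = config.n_trials
    if config.composition == "ratio_1_1":
        half = n // 2
        mi = rng.integers(0, len(match_pairs), half)
        ni = rng.integers(0, len(nomatch_pairs), half)
        pairs = [match_pairs[i] for i in mi] + [nomatch_pairs[i] for i in ni]
    else:
        base = n // 36
        extra = rng.choice(36, n - base * 36, replace=False)
        all_pairs = match_pairs + nomatch_pairs
        idx = np.concatenate([np.repeat(np.arange(36), base), extra])
        pairs = [all_pairs[i] for i in idx]
    order = rng.permutation(n)
    pairs = [pairs[i] for i in order]
    letters = np.array([p[0] for p in pairs])
    colors = np.array([p[1] for p in pairs])
    events = letters * 6 + colors
    is_match = colors == color_of[letters]
    table = pd.DataFrame(
        {
            "trial": np.arange(1, n + 1),
            "letter": letters,
            "color": colors,
            "event_k": events,
            "is_match": is_match,
            "intended_freq": intended_of[letters],
            "frequency": np.vectorize(actual_association_frequency)(
                intended_of[letters]
            ),
        }
    )
    table.attrs["assignment"] = assignment
    seq = EventSequence(events=events, K=36)
    return seq, table


# --------------------------------------------------------------------------
# behavior


def simulate_behavior(
    table: pd.DataFrame,
    policy: str = "probability_matching",
    p_correct: float | None = None,
    seed=None,
    rt_mu: float = np.log(0.7),
    rt_sigma: float = 0.3,
    rt_error_shift: float = 0.3,
) -> pd.DataFrame:
    """Simulate per-trial accuracy and reaction times.

    ``probability_matching`` makes the response frequency track the learned
    contingency, so accuracy within a frequency condition approximates the
    condition's frequency itself (~0.8 on 80% trials, ~0.2 on 20% trials);
    it requires a ``frequency`` column.  ``fixed_accuracy`` draws accuracy
    as Bernoulli(``p_correct``).  RTs are log-normal with a positive shift
    of the log-mean on error trials.
    """
    rng = _rng(seed)
    out = table.copy()
    n = len(out)
    if policy == "probability_matching":
        if "frequency" not in out.columns:
            raise ConfigError("probability_matching requires a 'frequency' column")
        p = out["frequency"].to_numpy(dtype=float)
    elif policy == "fixed_accuracy":
        if p_correct is None or not 0.0 <= p_correct <= 1.0:
            raise ConfigError("fixed_accuracy requires p_correct in [0, 1]")
        p = np.full(n, p_correct)
    else:
        raise ConfigError(f"unknown policy {policy!r}")
    accuracy = (rng.random(n) < p).astype(int)
    log_rt = rng.normal(rt_mu, rt_sigma, n) + rt_error_shift * (1 - accuracy)
    out["accuracy"] = accuracy
    out["rt_s"] = np.exp(log_rt)
    return out


# --------------------------------------------------------------------------
# pupil synthesis


def pupil_irf(
    t: np.ndarray, w: float = 10.1, t_max: float = 0.93
) -> np.ndarray:
    """Canonical pupil impulse response, unit peak at ``t_max`` seconds.

    Erlang-style kernel ``(t / t_max)^w * exp(w * (1 - t / t_max))`` for
    t >= 0, zero before the event.
    """
    t = np.asarray(t, dtype=float)
    h = np.zeros_like(t)
    pos = t > 0
    tp = t[pos] / t_max
    h[pos] = tp**w * np.exp(w * (1.0 - tp))
    return h


def schedule_onsets(
    n_trials: int,
    seed=None,
    lead_in_s: float = 8.0,
    iti_s: tuple[float, float] = (4.0, 5.0),
) -> np.ndarray:
    """Feedback onset times with jittered inter-trial spacing (>= 3.5 s)."""
    if iti_s[0] < 3.5:
        raise ConfigError("feedback onsets need >= 3.5 s spacing")
    rng = _rng(seed)
    gaps = rng.uniform(iti_s[0], iti_s[1], n_trials - 1)
    return lead_in_s + np.concatenate([[0.0], np.cumsum(gaps)])


@dataclass(frozen=True)
class PupilGenConfig:
    """Generative settings for a synthetic pupil recording.

    Amplitude of the feedback-locked response on trial j is
    ``beta0 + beta_I*I_j + beta_H*H_j + beta_DKL*D_j + beta_acc*error_j``
    plus Gaussian amplitude noise, in raw recording units (the mean level
    of 5000 units makes 50 units = 1% signal change).
    """

    fs: float = 500.0
    beta0: float = 150.0
    beta_I: float = 20.0
    beta_H: float = 0.0
    beta_DKL: float = 50.0
    beta_acc: float = 30.0
    beta0_subject_sd: float = 30.0  # between-subject spread of the mean response
    amp_noise_sd: float = 25.0
    sample_noise_sd: float = 5.0
    mean_level: float = 5000.0
    drift_amp: float = 50.0
    drift_freq: float = 0.002
    irf_w: float = 10.1
    irf_tmax: float = 0.93
    blink_rate: float = 0.05  # per second
    saccade_rate: float = 0.02
    blink_duration_s: tuple[float, float] = (0.1, 0.3)
    saccade_duration_s: tuple[float, float] = (0.02, 0.06)
    tail_s: float = 6.0

    def __post_init__(self):
        if self.fs not in (500.0, 1000.0, 500, 1000):
            raise ConfigError("fs must be 500 or 1000 Hz")
        # duration bounds may arrive as lists after a config round-trip
        object.__setattr__(self, "blink_duration_s", tuple(self.blink_duration_s))
        object.__setattr__(self, "saccade_duration_s", tuple(self.saccade_duration_s))


@dataclass
class GroundTruth:
    """Everything needed to score recovery of the planted effects."""

    config: PupilGenConfig
    seed: int | None
    onsets_s: np.ndarray
    amplitudes: np.ndarray
    trial_variables: pd.DataFrame

    def regenerate_key(self):
        return (self.config, self.seed)


def synthesize_pupil(
    variables: pd.DataFrame,
    config: PupilGenConfig = PupilGenConfig(),
    seed=None,
    onsets_s: np.ndarray | None = None,
) -> tuple[PupilRecording, ArtifactAnnotations, GroundTruth]:
    """Build a pupil trace with planted feedback-locked responses.

    ``variables`` must provide per-trial ``I_bits``, ``H_bits``,
    ``DKL_bits`` and ``accuracy`` columns.  Blinks are injected as annotated
    dropouts (samples invalid and zeroed); saccades as brief annotated dips.
    """
    rng = _rng(seed)
    n_trials = len(variables)
    if onsets_s is None:
        onsets_s = schedule_onsets(n_trials, rng)
    onsets_s = np.asarray(onsets_s, dtype=float)
    if np.any(np.diff(onsets_s) < 3.5 - 1e-9):
        raise ConfigError("feedback onsets must be >= 3.5 s apart")
    if onsets_s[0] < 1.0:
        raise ConfigError("first onset too close to the recording start")
    fs = float(config.fs)
    duration = onsets_s[-1] + config.tail_s
    n = int(round(duration * fs)) + 1
    t = np.arange(n) / fs

    I = variables["I_bits"].to_numpy(dtype=float)
    H = variables["H_bits"].to_numpy(dtype=float)
    D = variables["DKL_bits"].to_numpy(dtype=float)
    err = 1 - variables["accuracy"].to_numpy(dtype=int)
    subject_offset = rng.normal(0.0, config.beta0_subject_sd)
    amplitudes = (
        config.beta0
        + subject_offset
        + config.beta_I * I
        + config.beta_H * H
        + config.beta_DKL * D
        + config.beta_acc * err
        + rng.normal(0.0, config.amp_noise_sd, n_trials)
    )

    kernel_t = np.arange(0.0, 4.0, 1.0 / fs)
    kernel = pupil_irf(kernel_t, config.irf_w, config.irf_tmax)
    y = np.full(n, config.mean_level)
    y += config.drift_amp * np.sin(2 * np.pi * config.drift_freq * t + rng.uniform(0, 2 * np.pi))
    for onset, amp in zip(onsets_s, amplitudes):
        i0 = int(np.round(onset * fs))
        i1 = min(i0 + kernel.size, n)
        y[i0:i1] += amp * kernel[: i1 - i0]
    # measurement noise is band-limited: pupil traces are smooth at the
    # sample level, so white noise is low-passed at 4 Hz and rescaled
    if config.sample_noise_sd > 0:
        from scipy import signal as _signal

        white = rng.normal(0.0, 1.0, n)
        sos = _signal.butter(2, 4.0, btype="lowpass", fs=fs, output="sos")
        smooth = _signal.sosfiltfilt(sos, white)
        sd = smooth.std()
        if sd > 0:
            y += config.sample_noise_sd * smooth / sd

    valid = np.ones(n, dtype=bool)
    intervals = []
    for kind, rate, dur in (
        ("blink", config.blink_rate, config.blink_duration_s),
        ("saccade", config.saccade_rate, config.saccade_duration_s),
    ):
        n_events = rng.poisson(rate * duration)
        starts = np.sort(rng.uniform(1.0, duration - 1.0, n_events))
        for s in starts:
            d = rng.uniform(*dur)
            intervals.append((kind, float(s), float(s + d)))
            i0, i1 = int(s * fs), int((s + d) * fs) + 1
            if kind == "blink":
                y[i0:i1] = 0.0
                valid[i0:i1] = False
            else:
                y[i0:i1] -= 0.02 * config.mean_level

    rec = PupilRecording(t=t, y=y, fs=fs, valid=valid, stage="raw")
    ann = ArtifactAnnotations(intervals)
    gt = GroundTruth(
        config=config,
        seed=seed if not isinstance(seed, np.random.Generator) else None,
        onsets_s=onsets_s,
        amplitudes=amplitudes,
        trial_variables=variables.copy(),
    )
    return rec, ann, gt
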