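"""Sequential Dirichlet-categorical ideal observer.

The observer watches a sequence of discrete events ``x_1 .. x_j`` drawn from
``K`` types and maintains a Dirichlet belief over the event probabilities.
After ``j`` observations with per-type counts ``n_k`` and prior concentration
``alpha_k``, the belief is ``Dir(n_k + alpha_k)``; its mean probability vector
is ``(n_k + alpha_k) / (j + sum(alpha))``.

Three per-trial information-theoretic quantities are derived, all in bits:

* surprise ``I = -log2 p~`` of the observed event under the *pre-update*
  predictive probability,
* entropy ``H`` of the *post-update* posterior-mean distribution (the
  observer has received the trial's information by feedback time),
* information gain ``D_KL``, the Kullback-Leibler divergence from the
  pre-update to the post-update posterior mean ("Bayesian surprise").
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "EventSequence",
    "PriorSpec",
    "BeliefState",
    "TrialInfo",
    "InvalidPriorError",
    "InvalidEventError",
    "init_belief",
    "update_belief",
    "predictive_prob",
    "predictive_distribution",
    "shannon_surprise",
    "posterior_entropy",
    "kl_update",
    "run_learner",
    "trial_info_frame",
    "oddball_prior",
]

#: probabilities are clipped here before logs; never binds with positive alpha
_P_FLOOR = 1e-12


class InvalidPriorError(ValueError):
    """Raised for non-positive, wrong-length, or degenerate priors."""


class InvalidEventError(ValueError):
    """Raised when an event index falls outside [0, K)."""


@dataclass(frozen=True)
class EventSequence:
    """An ordered sequence of discrete event indices in ``[0, K)``.

    Odd-ball trials may be flagged through ``is_oddball``; flagged trials are
    allowed to carry the sentinel event index ``-1`` (they are outside the
    modelled event space).
    """

    events: np.ndarray
    K: int
    labels: tuple[str, ...] | None = None
    is_oddball: np.ndarray | None = None

    def __post_init__(self):
        ev = np.asarray(self.events, dtype=int)
        object.__setattr__(self, "events", ev)
        if self.K < 2:
            raise ValueError(f"K must be >= 2, got {self.K}")
        if self.is_oddball is not None:
            flags = np.asarray(self.is_oddball, dtype=bool)
            if flags.shape != ev.shape:
                raise ValueError("is_oddball must align with events")
            object.__setattr__(self, "is_oddball", flags)
            checked = ev[~flags]
        else:
            checked = ev
        if checked.size and (checked.min() < 0 or checked.max() >= self.K):
            raise InvalidEventError(
                f"event indices must lie in [0, {self.K}); "
                f"found range [{checked.min()}, {checked.max()}]"
            )
        if self.labels is not None and len(self.labels) != self.K:
            raise ValueError("labels must have length K")

    @property
    def trial_count(self) -> int:
        return int(self.events.size)


@dataclass(frozen=True)
class PriorSpec:
    """Dirichlet prior specification.

    ``alpha`` are the concentration parameters actually handed to the
    observer.  When the prior is estimated from an exposure phase the raw
    probability vector ``P_o`` is kept alongside; ``scale_mode`` records
    whether ``alpha`` is ``K * P_o`` (pseudo-counts summing to ``K``, which
    recovers the textbook ``(n_k + alpha_k) / (j - 1 + K)`` predictive form)
    or the raw probabilities themselves.
    """

    alpha: np.ndarray
    source: str = "uniform"  # or "oddball_estimated"
    P_o: np.ndarray | None = None
    scale_mode: str = "pseudo_counts_sum_K"

    def __post_init__(self):
        a = np.asarray(self.alpha, dtype=float)
        object.__setattr__(self, "alpha", a)
        if a.ndim != 1 or a.size < 2:
            raise InvalidPriorError("alpha must be a vector of length >= 2")
        if not np.all(a > 0):
            raise InvalidPriorError("all alpha entries must be positive")
        if self.source not in ("uniform", "oddball_estimated"):
            raise InvalidPriorError(f"unknown prior source {self.source!r}")
        if self.scale_mode not in ("pseudo_counts_sum_K", "raw_probabilities"):
            raise InvalidPriorError(f"unknown scale_mode {self.scale_mode!r}")
        if self.P_o is not None:
            p = np.asarray(self.P_o, dtype=float)
            object.__setattr__(self, "P_o", p)
            if p.size != a.size:
                raise InvalidPriorError("P_o must have the same length as alpha")
            if not np.all(p > 0):
                raise InvalidPriorError("P_o entries must be positive")
            if abs(p.sum() - 1.0) > 1e-9:
                raise InvalidPriorError("P_o must sum to 1")
        if self.scale_mode == "pseudo_counts_sum_K" and abs(a.sum() - a.size) > 1e-6:
            raise InvalidPriorError(
                "scale_mode 'pseudo_counts_sum_K' requires sum(alpha) == K"
            )

    @property
    def K(self) -> int:
        return int(self.alpha.size)

    @classmethod
    def uniform(cls, K: int) -> "PriorSpec":
        return cls(alpha=np.ones(K), source="uniform")

    @classmethod
    def from_probabilities(
        cls,
        P_o: np.ndarray,
        scale_mode: str = "pseudo_counts_sum_K",
        source: str = "oddball_estimated",
    ) -> "PriorSpec":
        p = np.asarray(P_o, dtype=float)
        if scale_mode == "pseudo_counts_sum_K":
            alpha = p.size * p
        else:
            alpha = p.copy()
        return cls(alpha=alpha, source=source, P_o=p, scale_mode=scale_mode)


@dataclass(frozen=True)
class BeliefState:
    """Dirichlet belief after ``j`` observations: ``Dir(counts + alpha)``."""

    alpha: np.ndarray
    counts: np.ndarray
    j: int

    def __post_init__(self):
        a = np.asarray(self.alpha, dtype=float)
        c = np.asarray(self.counts, dtype=int)
        object.__setattr__(self, "alpha", a)
        object.__setattr__(self, "counts", c)
        if not np.all(a > 0):
            raise InvalidPriorError("all alpha entries must be positive")
        if a.shape != c.shape:
            raise ValueError("alpha and counts must have the same shape")
        if np.any(c < 0) or c.sum() != self.j:
            raise ValueError("counts must be non-negative and sum to j")

    @property
    def K(self) -> int:
        return int(self.alpha.size)

    @property
    def posterior_mean(self) -> np.ndarray:
        conc = self.counts + self.alpha
        return conc / conc.sum()


def init_belief(K: int, prior: PriorSpec) -> BeliefState:
    """Create the pre-observation belief state from a prior specification."""
    if K < 2:
        raise InvalidPriorError(f"K must be >= 2, got {K}")
    if prior.K != K:
        raise InvalidPriorError(f"prior has K={prior.K}, expected {K}")
    return BeliefState(alpha=prior.alpha.copy(), counts=np.zeros(K, dtype=int), j=0)


def update_belief(state: BeliefState, event: int) -> BeliefState:
    """Absorb one observation; returns a new state with the count incremented."""
    if not 0 <= event < state.K:
        raise InvalidEventError(f"event {event} outside [0, {state.K})")
    counts = state.counts.copy()
    counts[event] += 1
    return replace(state, counts=counts, j=state.j + 1)


def predictive_prob(state: BeliefState, event: int) -> float:
    """Predictive probability of ``event`` on the next trial.

    Equals ``(counts[event] + alpha[event]) / (j + sum(alpha))``; with a
    prior whose concentrations sum to ``K`` this is the familiar
    ``(n_k + alpha_k) / (j - 1 + K)`` form for predicting trial ``j``.
    """
    if not 0 <= event < state.K:
        raise InvalidEventError(f"event {event} outside [0, {state.K})")
    conc = state.counts + state.alpha
    return float(conc[event] / conc.sum())


def predictive_distribution(state: BeliefState) -> np.ndarray:
    """Predictive probability vector over all K event types (sums to 1)."""
    conc = state.counts + state.alpha
    return conc / conc.sum()


def shannon_surprise(p: float) -> float:
    """Shannon information ``-log2 p`` of an event with probability ``p``."""
    if not 0.0 < p <= 1.0:
        raise ValueError(f"probability must lie in (0, 1], got {p}")
    return float(-np.log2(max(p, _P_FLOOR)))


def posterior_entropy(p: np.ndarray) -> float:
    """Shannon entropy of a probability vector, in bits; 0*log2(0) := 0."""
    p = np.asarray(p, dtype=float)
    if abs(p.sum() - 1.0) > 1e-6 or np.any(p < 0):
        raise ValueError("input must be a normalized probability vector")
    nz = p[p > 0]
    return float(-(nz * np.log2(np.maximum(nz, _P_FLOOR))).sum())


def kl_update(posterior: np.ndarray, prior: np.ndarray) -> float:
    """KL divergence (bits) from ``prior`` to ``posterior`` mean vectors."""
    q = np.asarray(posterior, dtype=float)
    p = np.asarray(prior, dtype=float)
    if abs(q.sum() - 1.0) > 1e-6 or abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("both vectors must be normalized")
    if np.any((p <= 0) & (q > 0)):
        raise ValueError("prior has zero mass where posterior is positive")
    mask = q > 0
    qm = q[mask]
    pm = np.maximum(p[mask], _P_FLOOR)
    return float((qm * np.log2(qm / pm)).sum())


@dataclass(frozen=True)
class TrialInfo:
    """Per-trial output of the ideal observer (all information units in bits)."""

    trial: int  # 1-based
    event: int
    p_pred: float
    I: float
    H: float
    D_KL: float


def run_learner(seq: EventSequence, prior: PriorSpec) -> list[TrialInfo]:
    """Run the observer over a sequence, one :class:`TrialInfo` per trial.

    For each trial ``j``: the predictive probability and surprise come from
    the belief *before* absorbing the trial; the state is then updated;
    entropy is evaluated on the post-update posterior mean; information gain
    is the KL divergence from the pre-update to the post-update mean.

    Trials flagged as odd-balls are skipped entirely: they neither produce a
    :class:`TrialInfo` row nor advance the belief.
    """
    state = init_belief(seq.K, prior)
    out: list[TrialInfo] = []
    flags = seq.is_oddball
    for idx, event in enumerate(seq.events):
        if flags is not None and flags[idx]:
            continue
        event = int(event)
        pre_mean = state.posterior_mean
        p_pred = predictive_prob(state, event)
        I = shannon_surprise(p_pred)
        state = update_belief(state, event)
        post_mean = state.posterior_mean
        H = posterior_entropy(post_mean)
        D = kl_update(post_mean, pre_mean)
        out.append(
            TrialInfo(trial=idx + 1, event=event, p_pred=p_pred, I=I, H=H, D_KL=D)
        )
    return out


def trial_info_frame(infos: list[TrialInfo]):
    """Convert ``run_learner`` output to a pandas DataFrame."""
    import pandas as pd

    return pd.DataFrame(
        {
            "trial": [t.trial for t in infos],
            "event_k": [t.event for t in infos],
            "p_pred": [t.p_pred for t in infos],
            "I_bits": [t.I for t in infos],
            "H_bits": [t.H for t in infos],
            "DKL_bits": [t.D_KL for t in infos],
        }
    )


def oddball_prior(
    oddball_seq: EventSequence, scale_mode: str = "pseudo_counts_sum_K"
) -> PriorSpec:
    """Estimate a prior from an odd-ball exposure sequence.

    Only regular (non-odd-ball) trials count: with ``n_k`` occurrences of
    event ``k`` over ``N_reg`` regular trials and ``K`` event types,
    ``P_o,k = (n_k + 1) / (N_reg + K)`` (a Laplace-smoothed relative
    frequency, renormalized).  Odd-ball trials are outside the modelled
    event space and contribute nothing.
    """
    if oddball_seq.is_oddball is None:
        regular = oddball_seq.events
    else:
        regular = oddball_seq.events[~oddball_seq.is_oddball]
    if regular.size == 0:
        raise InvalidPriorError("no regular trials to estimate a prior from")
    K = oddball_seq.K
    counts = np.bincount(regular, minlength=K).astype(float)
    P_o = (counts + 1.0) / (regular.size + K)
    P_o = P_o / P_o.sum()
    return PriorSpec.from_probabilities(P_o, scale_mode=scale_mode)
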