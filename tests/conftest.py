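import warnings

import numpy as np
import pandas as pd
import pytest

from pupilgain import learner as L
from pupilgain import preprocess as P
from pupilgain import synthetic as G

warnings.filterwarnings("ignore", category=FutureWarning)
warnings.filterwarnings("ignore", category=UserWarning, module="statsmodels")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def cue_target_subject():
    """One simulated participant: sequence, trial table with learner variables."""
    rng = np.random.default_rng(7)
    seq, table = G.gen_cue_target_sequence(G.CueTargetConfig(), rng)
    ti = L.trial_info_frame(L.run_learner(seq, L.PriorSpec.uniform(4)))
    table = table.merge(ti.drop(columns=["event_k"]), on="trial")
    table = G.simulate_behavior(table, seed=rng)
    return seq, table


def preprocess_chain(rec, ann, pad_s=0.15, threshold=10.0):
    """The full preprocessing chain used throughout the tests."""
    rec_i = P.interpolate_intervals(rec, P.missing_intervals(rec) + ann, pad_s)
    spikes = P.detect_derivative_artifacts(rec_i, threshold)
    if len(spikes):
        rec_i = P.interpolate_intervals(rec_i, spikes, pad_s)
    reference = float(rec_i.y.mean())
    rec_f = P.bandpass_filter(rec_i)
    rec_r, fit = P.remove_nuisance_responses(rec_f, ann + spikes)
    return P.percent_signal_change(rec_r, reference), fit


def analyze_planted_subject(subject, seed_seq, gen_cfg_fn):
    """Simulate one subject with a planted pupil loading and run the chain.

    ``gen_cfg_fn(table)`` maps the trial table to a PupilGenConfig.
    Returns (decimated corrected epochs, window table, ground truth).
    """
    rngs = [np.random.default_rng(x) for x in seed_seq.spawn(4)]
    seq, table = G.gen_cue_target_sequence(G.CueTargetConfig(), rngs[0])
    ti = L.trial_info_frame(L.run_learner(seq, L.PriorSpec.uniform(4)))
    table = table.merge(ti.drop(columns=["event_k"]), on="trial")
    table = G.simulate_behavior(table, seed=rngs[1])
    table.insert(0, "subject", subject)
    cfg = gen_cfg_fn(table)
    rec, ann, gt = G.synthesize_pupil(
        table[["I_bits", "H_bits", "DKL_bits", "accuracy"]], cfg, seed=rngs[2]
    )
    rec_p, _ = preprocess_chain(rec, ann)
    epochs = P.extract_epochs(rec_p, gt.onsets_s, labels=table)
    corrected, wtable = P.baseline_and_window(epochs)
    return corrected.decimate(20.0), wtable, gt, rngs[3]
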