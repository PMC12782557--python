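"""End-to-end orchestration: simulate -> learn -> preprocess -> statistics.

``run_pipeline`` executes the full analysis on synthetic data for one task
design and returns a :class:`ResultBundle`; ``write_report`` serializes the
bundle as TSV/JSON plus a plain-text summary.  All randomness flows from
the named seeds in the configuration; reruns with the same config are
bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time as _time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import learner as L
from . import preprocess as P
from . import stats as S
from . import synthetic as G

logger = logging.getLogger(__name__)

__all__ = ["AnalysisConfig", "ResultBundle", "run_pipeline", "write_report"]


@dataclass(frozen=True)
class AnalysisConfig:
    """Resolved settings for one pipeline run."""

    task: str = "cue_target"  # or "lettercolor"
    n_subjects: int = 24
    n_trials: int = 200
    seed: int = 0
    # prior
    prior_scale_mode: str = "pseudo_counts_sum_K"
    # preprocessing
    pad_s: float = 0.15
    filter_low: float = 0.01
    filter_high: float = 6.0
    filter_order: int = 3
    derivative_threshold: float = 10.0
    deconv_window_s: float = 6.0
    deconv_design_fs: float = 20.0
    rt_z_crit: float = 3.0
    # windows (seconds relative to feedback onset)
    epoch_window: tuple[float, float] = (-0.5, 3.0)
    baseline_window: tuple[float, float] = (-0.5, 0.0)
    early_window: tuple[float, float] = (0.75, 1.25)
    late_window: tuple[float, float] = (2.5, 3.0)
    epoch_fs: float = 20.0  # decimated rate for the correlation/cluster stage
    # statistics
    n_perm: int = 10000
    cluster_alpha: float = 0.05
    fdr_q: float = 0.05
    cv_folds: int = 5
    # generation
    pupil: G.PupilGenConfig = field(default_factory=G.PupilGenConfig)
    behavior_policy: str = "probability_matching"
    behavior_p_correct: float = 0.8

    def __post_init__(self):
        if self.task not in ("cue_target", "lettercolor"):
            raise ValueError(f"unknown task {self.task!r}")
        for name in ("baseline_window", "early_window", "late_window"):
            a, b = getattr(self, name)
            if not a < b:
                raise ValueError(f"{name} has start >= end")
        if not (
            self.early_window[1] <= self.late_window[0]
            or self.late_window[1] <= self.early_window[0]
        ):
            raise ValueError("early and late windows must not overlap")
        for name in ("early_window", "late_window"):
            a, b = getattr(self, name)
            if a < self.epoch_window[0] or b > self.epoch_window[1]:
                raise ValueError(f"{name} outside the epoch window")
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)
        if "pupil" in d and isinstance(d["pupil"], dict):
            d["pupil"] = G.PupilGenConfig(**d["pupil"])
        for key in ("epoch_window", "baseline_window", "early_window", "late_window"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "AnalysisConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


@dataclass
class ResultBundle:
    """All pipeline outputs sharing one subject/trial index space."""

    config: AnalysisConfig
    trial_table: pd.DataFrame
    corr_timecourses: dict
    group_averages: dict
    cluster_results: dict
    anova: pd.DataFrame
    hlm_results: dict
    hlm_comparisons: dict
    metadata: dict


def _subject_dataset(config: AnalysisConfig, subject: int, seed_seq):
    """Simulate and preprocess one subject.

    Returns the per-trial window table and the baseline-corrected,
    decimated epochs used by the correlation stage.
    """
    rngs = [np.random.default_rng(s) for s in seed_seq.spawn(4)]
    gen_rng, beh_rng, pupil_rng, _ = rngs

    if config.task == "cue_target":
        mapping = "condition1" if subject % 2 == 0 else "condition2"
        seq, table = G.gen_cue_target_sequence(
            G.CueTargetConfig(n_trials=config.n_trials, mapping=mapping), gen_rng
        )
        prior = L.PriorSpec.uniform(4)
    else:
        odd_seq, odd_table = G.gen_oddball_sequence(G.OddballConfig(), gen_rng)
        prior = L.oddball_prior(odd_seq, scale_mode=config.prior_scale_mode)
        seq, table = G.gen_lettercolor_sequence(
            G.LetterColorConfig(n_trials=config.n_trials),
            odd_table.attrs["assignment"],
            gen_rng,
        )

    infos = L.run_learner(seq, prior)
    ti = L.trial_info_frame(infos)
    table = table.merge(ti.drop(columns=["event_k"]), on="trial")
    policy = config.behavior_policy
    if config.task == "lettercolor" and policy == "probability_matching":
        policy = "fixed_accuracy"
    table = G.simulate_behavior(
        table, policy=policy, p_correct=config.behavior_p_correct, seed=beh_rng
    )
    table.insert(0, "subject", subject)

    rec, ann, gt = G.synthesize_pupil(
        table[["I_bits", "H_bits", "DKL_bits", "accuracy"]], config.pupil,
        seed=pupil_rng,
    )
    table["feedback_onset_s"] = gt.onsets_s

    # (i)-(ii) interpolation around missing samples and derivative spikes
    rec_i = P.interpolate_intervals(rec, P.missing_intervals(rec) + ann, config.pad_s)
    spikes = P.detect_derivative_artifacts(rec_i, config.derivative_threshold)
    if len(spikes):
        rec_i = P.interpolate_intervals(rec_i, spikes, config.pad_s)
    reference_mean = float(rec_i.y.mean())
    # (iii) band-pass
    rec_f = P.bandpass_filter(
        rec_i, config.filter_low, config.filter_high, config.filter_order
    )
    # (iv) nuisance deconvolution + regression
    rec_r, _fit = P.remove_nuisance_responses(
        rec_f, ann + spikes, config.deconv_window_s, config.deconv_design_fs
    )
    # (v) percent signal change
    rec_p = P.percent_signal_change(rec_r, reference_mean)

    epochs = P.extract_epochs(
        rec_p, gt.onsets_s, window=config.epoch_window, labels=table
    )
    corrected, wtable = P.baseline_and_window(
        epochs,
        baseline=config.baseline_window,
        windows={"early": config.early_window, "late": config.late_window},
    )
    return wtable, corrected.decimate(config.epoch_fs)


def run_pipeline(config: AnalysisConfig) -> ResultBundle:
    """Run the full analysis; deterministic given ``config.seed``."""
    t0 = _time.time()
    root = np.random.SeedSequence(config.seed)
    subject_seqs = root.spawn(config.n_subjects)

    stage = "simulate+preprocess"
    try:
        wtables, epoch_sets = [], []
        for s in range(config.n_subjects):
            wt, ep = _subject_dataset(config, s, subject_seqs[s])
            wtables.append(wt)
            epoch_sets.append(ep)
        trial_table = pd.concat(wtables, ignore_index=True)
        keep = P.exclude_rt_outliers(
            trial_table["rt_s"].to_numpy(),
            trial_table["subject"].to_numpy(),
            config.rt_z_crit,
        )
        trial_table = trial_table[keep].reset_index(drop=True)
        epochs = P.EpochSet(
            data=np.vstack([e.data for e in epoch_sets])[keep],
            time=epoch_sets[0].time,
            labels=trial_table,
        )
    except Exception as e:
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {e}") from e

    stage = "correlations"
    try:
        post = epochs.time >= 0.0
        epochs_post = P.EpochSet(
            data=epochs.data[:, post], time=epochs.time[post], labels=epochs.labels
        )
        corr, gavg, clusters = {}, {}, {}
        cl_seed_root = np.random.SeedSequence(config.seed + 1_000_003)
        cl_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in cl_seed_root.spawn(3)]
        for var, col, cseed in zip(
            ("I", "H", "D_KL"), ("I_bits", "H_bits", "DKL_bits"), cl_seeds
        ):
            tc = S.correlation_timecourse(
                epochs_post, epochs.labels[col].to_numpy(), variable=var
            )
            corr[var] = tc
            gavg[var] = S.group_average_fisher(tc)
            rows = ~np.isnan(tc.z).any(axis=1)
            clusters[var] = S.cluster_permutation_test(
                tc.z[rows],
                n_perm=config.n_perm,
                cluster_alpha=config.cluster_alpha,
                seed=cseed,
                time=tc.time,
            )
    except Exception as e:
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {e}") from e

    stage = "window statistics"
    try:
        anova = S.window_factorial_anova(
            trial_table.assign(frequency=trial_table["frequency"].round(3)),
            dv="early",
            within=["frequency", "accuracy"],
        )
        hlm_results, hlm_comparisons = {}, {}
        for window in ("early", "late"):
            df = trial_table.rename(
                columns={
                    window: "pupil",
                    "I_bits": "I",
                    "H_bits": "H",
                    "DKL_bits": "DKL",
                    "rt_s": "rt",
                }
            )[["pupil", "I", "H", "DKL", "baseline", "rt", "subject"]]
            r1, r2, cmp_ = S.fit_and_compare_hlm(df, cv_folds=config.cv_folds)
            hlm_results[(window, 1)] = r1
            hlm_results[(window, 2)] = r2
            hlm_comparisons[window] = cmp_
    except Exception as e:
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {e}") from e

    metadata = {
        "seed": config.seed,
        "config_digest": config.digest(),
        "n_subjects": config.n_subjects,
        "task": config.task,
        "elapsed_s": round(_time.time() - t0, 2),
        "timestamp": _time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    return ResultBundle(
        config=config,
        trial_table=trial_table,
        corr_timecourses=corr,
        group_averages=gavg,
        cluster_results=clusters,
        anova=anova,
        hlm_results=hlm_results,
        hlm_comparisons=hlm_comparisons,
        metadata=metadata,
    )


def write_report(bundle: ResultBundle, out_dir) -> list[Path]:
    """Write all bundle components plus a plain-text summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    def _w(path: Path):
        written.append(path)
        return path

    bundle.trial_table.to_csv(_w(out / "trial_table.tsv"), sep="\t", index=False, float_format="%.17g")

    rows = []
    for var, df in bundle.group_averages.items():
        d = df.copy()
        d.insert(0, "variable", var)
        d.insert(1, "subset", bundle.corr_timecourses[var].subset)
        rows.append(d)
    pd.concat(rows, ignore_index=True).to_csv(
        _w(out / "corr_timecourse.tsv"), sep="\t", index=False, float_format="%.17g"
    )

    crows = []
    for var, cr in bundle.cluster_results.items():
        for start, end, mass, p in cr.clusters:
            crows.append(
                {
                    "variable": var,
                    "subset": bundle.corr_timecourses[var].subset,
                    "start_s": start,
                    "end_s": end,
                    "mass": mass,
                    "p": p,
                }
            )
    pd.DataFrame(
        crows, columns=["variable", "subset", "start_s", "end_s", "mass", "p"]
    ).to_csv(_w(out / "clusters.tsv"), sep="\t", index=False, float_format="%.17g")

    anova_payload = {
        "effects": bundle.anova.to_dict(orient="records"),
        "excluded_participants": bundle.anova.attrs.get("excluded", []),
        "n_subjects": bundle.anova.attrs.get("n_subjects"),
    }
    _w(out / "anova.json").write_text(json.dumps(anova_payload, indent=2))

    hlm_payload = {}
    for (window, mid), res in bundle.hlm_results.items():
        hlm_payload[f"{window}_model{mid}"] = {
            "formula": res.formula,
            "coefficients": res.coefficients.reset_index().to_dict(orient="records"),
            "elpd": res.elpd,
            "elpd_se": res.elpd_se,
        }
    for window, cmp_ in bundle.hlm_comparisons.items():
        hlm_payload[f"{window}_comparison"] = {
            "delta_elpd": cmp_.delta_elpd,
            "se": cmp_.se_delta,
            "ratio": cmp_.ratio,
            "preferred": cmp_.preferred,
            "meaningful": cmp_.meaningful,
        }
    _w(out / "hlm.json").write_text(json.dumps(hlm_payload, indent=2))

    _w(out / "config.json").write_text(
        json.dumps(bundle.config.to_dict(), indent=2, default=str)
    )

    lines = [
        f"pupilgain run summary (task={bundle.config.task}, "
        f"seed={bundle.metadata['seed']}, config {bundle.metadata['config_digest']})",
        f"subjects: {bundle.metadata['n_subjects']}, "
        f"trials analyzed: {len(bundle.trial_table)}",
        "",
    ]
    any_cluster = False
    for var, cr in bundle.cluster_results.items():
        for start, end, mass, p in cr.clusters:
            any_cluster = True
            sig = "significant" if p < 0.05 else "n.s."
            lines.append(
                f"cluster [{var}]: {start:.2f}-{end:.2f} s, mass {mass:.1f}, "
                f"p={p:.4f} ({sig})"
            )
    if not any_cluster:
        lines.append("no significant clusters")
    lines.append("")
    for _, row in bundle.anova.iterrows():
        lines.append(
            f"ANOVA {row['effect']}: F({row['df1']},{row['df2']})={row['F']:.2f}, "
            f"p={row['p']:.4f}, p_GG={row['p_gg']:.4f}, ges={row['ges']:.3f}"
        )
    lines.append("")
    for window, cmp_ in bundle.hlm_comparisons.items():
        lines.append(f"HLM ({window} window): {cmp_.summary()}")
    _w(out / "summary.txt").write_text("\n".join(lines) + "\n")
    return written
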