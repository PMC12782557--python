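"""Statistics linking ideal-observer variables to the pupil response.

Covers the trial-wise correlation time courses with Fisher-z group
inference, one-sample cluster-based sign-flip permutation tests,
Benjamini-Hochberg FDR, balanced within-subject factorial ANOVA with
Greenhouse-Geisser correction and generalized eta squared, the Wilcoxon
signed-rank test with rank-biserial effect size, and the random-intercept
hierarchical regression comparison (Model 1 vs Model 2) judged by a
cross-validated ELPD difference against its standard error.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests

from .preprocess import EpochSet

__all__ = [
    "CorrTimecourse",
    "ClusterResult",
    "HLMResult",
    "ModelComparison",
    "CollinearityError",
    "correlation_timecourse",
    "group_average_fisher",
    "cluster_permutation_test",
    "fdr_adjust",
    "window_factorial_anova",
    "paired_nonparametric_test",
    "fit_hlm",
    "fit_and_compare_hlm",
    "compare_models",
]

_R_CLAMP = 1.0 - 1e-12


class CollinearityError(ValueError):
    pass


# --------------------------------------------------------------------------
# correlation time courses


@dataclass
class CorrTimecourse:
    """Participants x timepoints Fisher-z correlations for one variable."""

    z: np.ndarray
    variable: str
    time: np.ndarray
    subset: str = "all"
    subjects: np.ndarray | None = None

    def __post_init__(self):
        self.z = np.atleast_2d(np.asarray(self.z, dtype=float))
        self.time = np.asarray(self.time, dtype=float)


def _pearson_rows(x: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Pearson r between vector ``x`` and every column of ``Y``."""
    xc = x - x.mean()
    Yc = Y - Y.mean(axis=0)
    denom = np.sqrt((xc**2).sum() * (Yc**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ Yc) / denom
    return r


def correlation_timecourse(
    epochs: EpochSet,
    regressor: np.ndarray,
    variable: str = "x",
    subset: str = "all",
) -> CorrTimecourse:
    """Per-participant trial-wise Pearson r at each timepoint, Fisher-z'd.

    ``epochs.labels`` must carry a ``subject`` column and, when
    ``subset`` is ``"correct"`` or ``"error"``, an ``accuracy`` column.
    Participants whose regressor has zero variance in the subset are
    missing-coded (NaN row) and skipped by the group stage.
    """
    regressor = np.asarray(regressor, dtype=float)
    if regressor.size != epochs.n_trials:
        raise ValueError("regressor must align with epoch rows")
    labels = epochs.labels
    if subset == "all":
        sel_all = np.ones(epochs.n_trials, dtype=bool)
    elif subset in ("correct", "error"):
        acc = labels["accuracy"].to_numpy().astype(int)
        sel_all = acc == (1 if subset == "correct" else 0)
    else:
        raise ValueError(f"unknown subset {subset!r}")
    subjects = np.unique(labels["subject"])
    z = np.full((subjects.size, epochs.time.size), np.nan)
    for i, s in enumerate(subjects):
        sel = (labels["subject"] == s).to_numpy() & sel_all
        if sel.sum() < 3:
            warnings.warn(f"subject {s}: fewer than 3 trials in subset {subset!r}")
            continue
        x = regressor[sel]
        if np.ptp(x) == 0:
            warnings.warn(f"subject {s}: zero-variance regressor, missing-coded")
            continue
        r = _pearson_rows(x, epochs.data[sel])
        r = np.clip(np.nan_to_num(r), -_R_CLAMP, _R_CLAMP)
        z[i] = np.arctanh(r)
    return CorrTimecourse(z=z, variable=variable, time=epochs.time, subset=subset,
                          subjects=subjects)


def group_average_fisher(tc: CorrTimecourse) -> pd.DataFrame:
    """Across-participant mean of Fisher z with SEM; display r = tanh(mean z)."""
    rows = ~np.isnan(tc.z).any(axis=1)
    z = tc.z[rows]
    if z.shape[0] < 2:
        raise ValueError("need at least 2 participants for a group average")
    mean_z = z.mean(axis=0)
    sem = z.std(axis=0, ddof=1) / np.sqrt(z.shape[0])
    return pd.DataFrame(
        {
            "time_s": tc.time,
            "mean_z": mean_z,
            "mean_r": np.tanh(mean_z),
            "sem": sem,
        }
    )


# --------------------------------------------------------------------------
# cluster-based permutation test


@dataclass
class ClusterResult:
    """Clusters of suprathreshold timepoints with permutation p-values."""

    clusters: list[tuple[float, float, float, float]]  # start_s, end_s, mass, p
    n_permutations: int
    cluster_alpha: float
    seed: int | None
    threshold: float

    def significant(self, alpha: float = 0.05):
        return [c for c in self.clusters if c[3] < alpha]


def _t_rows(X: np.ndarray) -> np.ndarray:
    n = X.shape[0]
    m = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return m / (sd / np.sqrt(n))


def _runs(mask: np.ndarray):
    """(start, stop) index pairs of True runs in a 1-D boolean array."""
    d = np.diff(np.concatenate(([0], mask.view(np.int8), [0])))
    return list(zip(np.flatnonzero(d == 1), np.flatnonzero(d == -1)))


def _max_cluster_mass(T: np.ndarray, thr: float) -> np.ndarray:
    """Row-wise maximum |cluster mass| of a (n_perm x n_time) t matrix."""
    n_rows, n_cols = T.shape
    out = np.zeros(n_rows)
    for sign in (1.0, -1.0):
        mask = sign * T > thr
        padded = np.zeros((n_rows, n_cols + 2), dtype=np.int8)
        padded[:, 1:-1] = mask
        d = np.diff(padded, axis=1)
        starts = np.flatnonzero(d.ravel() == 1)
        stops = np.flatnonzero(d.ravel() == -1)
        if starts.size == 0:
            continue
        csum = np.concatenate(
            [np.zeros((n_rows, 1)), np.cumsum(np.abs(T), axis=1)], axis=1
        ).ravel()
        width = n_cols + 1
        row_of = starts // (n_cols + 1)
        s_col = starts % (n_cols + 1)
        e_col = stops % (n_cols + 1)
        masses = csum[row_of * width + e_col] - csum[row_of * width + s_col]
        np.maximum.at(out, row_of, masses)
    return out


def cluster_permutation_test(
    matrix: np.ndarray,
    n_perm: int = 10000,
    cluster_alpha: float = 0.05,
    seed: int | None = None,
    time: np.ndarray | None = None,
) -> ClusterResult:
    """One-sample cluster-based sign-flip permutation test against zero.

    A one-sample t statistic is formed at each timepoint; clusters are
    maximal contiguous runs exceeding the two-sided t critical value at
    ``cluster_alpha``; the cluster statistic is the summed |t| (mass).  The
    null distribution is the maximum cluster mass over random per-participant
    sign flips; each observed cluster's p is the fraction of the null at or
    above its mass (with the observed data counted once).
    """
    X = np.atleast_2d(np.asarray(matrix, dtype=float))
    n = X.shape[0]
    if n < 5:
        raise ValueError("need at least 5 participants")
    if n_perm < 100:
        raise ValueError("n_perm < 100 gives unstable p-values")
    if time is None:
        time = np.arange(X.shape[1], dtype=float)
    thr = sps.t.ppf(1 - cluster_alpha / 2, n - 1)
    t_obs = _t_rows(X)

    observed = []
    for sign in (1.0, -1.0):
        for i0, i1 in _runs(sign * t_obs > thr):
            observed.append((i0, i1, float(np.abs(t_obs[i0:i1]).sum()) * sign))
    rng = np.random.default_rng(seed)
    # sums/squares identity: sign flips leave per-timepoint sum of squares fixed
    ssq = (X**2).sum(axis=0)
    null = np.zeros(n_perm)
    chunk = 2000
    for lo in range(0, n_perm, chunk):
        hi = min(lo + chunk, n_perm)
        signs = rng.integers(0, 2, size=(hi - lo, n)) * 2 - 1
        m = signs @ X / n
        with np.errstate(invalid="ignore", divide="ignore"):
            sd = np.sqrt(np.maximum(ssq / n - m**2, 0.0) * n / (n - 1))
            Tp = m / (sd / np.sqrt(n))
        Tp = np.nan_to_num(Tp)
        null[lo:hi] = _max_cluster_mass(Tp, thr)
    clusters = []
    for i0, i1, mass in observed:
        p = (1 + np.sum(null >= abs(mass))) / (n_perm + 1)
        clusters.append((float(time[i0]), float(time[i1 - 1]), mass, float(p)))
    return ClusterResult(
        clusters=clusters,
        n_permutations=n_perm,
        cluster_alpha=cluster_alpha,
        seed=seed,
        threshold=float(thr),
    )


def fdr_adjust(p_values: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask at level ``q``."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, alpha=q, method="fdr_bh")[0]


# --------------------------------------------------------------------------
# factorial within-subject ANOVA


def _helmert(levels: int) -> np.ndarray:
    """Orthonormal contrast matrix (levels x levels-1), orthogonal to ones."""
    C = np.zeros((levels, levels - 1))
    for j in range(1, levels):
        C[:j, j - 1] = 1.0
        C[j, j - 1] = -j
        C[:, j - 1] /= np.linalg.norm(C[:, j - 1])
    return C


def window_factorial_anova(
    data: pd.DataFrame,
    dv: str,
    within: list[str],
    subject: str = "subject",
) -> pd.DataFrame:
    """Balanced repeated-measures ANOVA for fully within-subject designs.

    Works for any number of within factors (the typical uses here are the
    2x2 / 3x2 frequency-by-accuracy and the 2x3x2 window-by-frequency-by-
    accuracy designs).  Observations are first averaged to per-participant
    condition means; participants with missing cells are excluded (listed in
    the ``excluded`` attribute of the returned frame).  For every effect the
    error term is its interaction with subject.  Greenhouse-Geisser
    epsilon (from the covariance of the orthonormal effect scores) corrects
    the p-value whenever the effect has more than one numerator df;
    generalized eta squared uses all error strata in its denominator.
    """
    cells = data.groupby([subject] + within, observed=True)[dv].mean().reset_index()
    levels = [np.unique(cells[f]) for f in within]
    n_cells = int(np.prod([lv.size for lv in levels]))
    counts = cells.groupby(subject, observed=True).size()
    complete = counts[counts == n_cells].index
    excluded = sorted(set(counts.index) - set(complete))
    if excluded:
        warnings.warn(f"participants excluded for missing cells: {excluded}")
    cells = cells[cells[subject].isin(complete)]
    subs = np.unique(cells[subject])
    n_sub = subs.size
    if n_sub < 2:
        raise ValueError("need at least 2 complete participants")
    # pivot to n_sub x n_cells, cells ordered by factor-level product
    cells = cells.sort_values([subject] + within)
    Y = cells[dv].to_numpy().reshape(n_sub, n_cells)

    ones = [np.ones((lv.size, 1)) / np.sqrt(lv.size) for lv in levels]
    contrasts = [_helmert(lv.size) for lv in levels]

    def kron_all(mats):
        out = np.ones((1, 1))
        for m in mats:
            out = np.kron(out, m)
        return out

    # subject stratum
    v = (Y @ kron_all(ones)).ravel()
    ss_subject = float(((v - v.mean()) ** 2).sum())

    effects = []
    for r in range(1, len(within) + 1):
        for combo in itertools.combinations(range(len(within)), r):
            M = kron_all(
                [contrasts[i] if i in combo else ones[i] for i in range(len(within))]
            )
            S = Y @ M  # n_sub x df
            d = S.shape[1]
            sbar = S.mean(axis=0)
            ss_eff = float(n_sub * (sbar**2).sum())
            ss_err = float(((S - sbar) ** 2).sum())
            V = np.cov(S, rowvar=False).reshape(d, d)
            tr = np.trace(V)
            eps = 1.0 if d == 1 else float(tr**2 / (d * np.trace(V @ V)))
            eps = min(max(eps, 1.0 / d), 1.0)
            effects.append(
                {
                    "effect": " * ".join(within[i] for i in combo),
                    "ss": ss_eff,
                    "ss_error": ss_err,
                    "df1": d,
                    "df2": d * (n_sub - 1),
                    "eps_gg": eps,
                }
            )
    total_error = ss_subject + sum(e["ss_error"] for e in effects)
    rows = []
    for e in effects:
        ms_eff = e["ss"] / e["df1"]
        ms_err = e["ss_error"] / e["df2"]
        F = ms_eff / ms_err if ms_err > 0 else 0.0
        p = float(sps.f.sf(F, e["df1"], e["df2"])) if ms_err > 0 else 1.0
        p_gg = (
            float(sps.f.sf(F, e["eps_gg"] * e["df1"], e["eps_gg"] * e["df2"]))
            if ms_err > 0
            else 1.0
        )
        ges = e["ss"] / (e["ss"] + total_error) if (e["ss"] + total_error) > 0 else 0.0
        rows.append(
            {
                "effect": e["effect"],
                "F": F,
                "df1": e["df1"],
                "df2": e["df2"],
                "p": p,
                "eps_gg": e["eps_gg"],
                "p_gg": p_gg,
                "ges": ges,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["excluded"] = excluded
    out.attrs["n_subjects"] = int(n_sub)
    return out


# --------------------------------------------------------------------------
# Wilcoxon signed-rank


@dataclass
class WilcoxonResult:
    z: float
    p: float
    r_rb: float
    n: int
    method: str


def paired_nonparametric_test(x: np.ndarray, y: np.ndarray) -> WilcoxonResult:
    """Wilcoxon signed-rank test with matched rank-biserial effect size.

    Zero differences are dropped.  Exact p by enumeration for n <= 25,
    normal approximation otherwise.  ``r_rb = (W+ - W-) / (W+ + W-)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    d = x - y
    d = d[d != 0]
    n = d.size
    if n < 5:
        raise ValueError("need at least 5 nonzero paired differences")
    ranks = sps.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    w_neg = float(ranks[d < 0].sum())
    r_rb = (w_pos - w_neg) / (w_pos + w_neg)
    method = "exact" if n <= 25 else "approx"
    res = sps.wilcoxon(d, method=method)
    # normal-approximation z reported in either case
    mu = n * (n + 1) / 4
    sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24)
    z = (w_pos - mu) / sigma
    return WilcoxonResult(z=float(z), p=float(res.pvalue), r_rb=float(r_rb), n=n,
                          method=method)


# --------------------------------------------------------------------------
# hierarchical linear model comparison


@dataclass
class HLMResult:
    """Random-intercept regression fit with a cross-validated ELPD criterion.

    ``coefficients`` has one row per fixed effect with the estimate, its 95%
    interval and the direction probability (the posterior-style probability,
    under the normal approximation, that the effect has the sign of its
    estimate).  ``elpd`` is the summed K-fold out-of-sample log predictive
    density with standard error ``elpd_se``.
    """

    model_id: int
    formula: str
    coefficients: pd.DataFrame
    elpd: float
    elpd_se: float
    pointwise_lpd: np.ndarray
    n_obs: int
    group_var: float
    resid_var: float

    def summary(self) -> str:
        lines = [
            f"Model {self.model_id}: {self.formula}",
            f"n = {self.n_obs}, random-intercept var = {self.group_var:.4g}, "
            f"residual var = {self.resid_var:.4g}",
            f"ELPD (K-fold CV) = {self.elpd:.2f} (SE {self.elpd_se:.2f})",
            "",
            self.coefficients.to_string(float_format=lambda v: f"{v:.4f}"),
        ]
        return "\n".join(lines)


@dataclass
class ModelComparison:
    delta_elpd: float  # elpd(model b) - elpd(model a)
    se_delta: float
    ratio: float
    preferred: int | None
    meaningful: bool

    def summary(self) -> str:
        verdict = (
            f"Model {self.preferred} preferred"
            if self.meaningful
            else "no meaningful difference"
        )
        return (
            f"delta ELPD = {self.delta_elpd:.2f} (SE {self.se_delta:.2f}), "
            f"ratio = {self.ratio:.2f} -> {verdict}"
        )


_MODEL_FORMULAS = {
    1: "pupil ~ I + H + DKL + baseline + rt",
    2: "pupil ~ I + H + DKL + H:DKL + baseline + rt",
}


def _check_rank(X: np.ndarray, names: list[str]):
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        corr = np.corrcoef(X[:, 1:], rowvar=False)
        bad = []
        for i in range(corr.shape[0]):
            for j in range(i + 1, corr.shape[1]):
                if abs(corr[i, j]) > 1 - 1e-8:
                    bad.extend([names[i + 1], names[j + 1]])
        raise CollinearityError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]}); "
            f"offending columns: {sorted(set(bad)) or names}"
        )


def fit_hlm(
    trial_table: pd.DataFrame,
    model_id: int = 1,
    cv_folds: int = 5,
    zscore: bool = False,
) -> HLMResult:
    """Fit a random-intercept linear model of the windowed pupil response.

    Model 1 regresses the window-mean pupil response on surprise, entropy,
    information gain, the pre-feedback baseline and reaction time; Model 2
    adds the entropy-by-information-gain interaction.  ``subject`` enters as
    a random intercept.  Fixed effects are reported with Wald 95% intervals.
    The predictive criterion is a grouped K-fold cross-validated expected
    log predictive density (folds stratified within subject, Gaussian
    plug-in predictive).
    """
    if model_id not in _MODEL_FORMULAS:
        raise ValueError("model_id must be 1 or 2")
    df = trial_table.copy()
    required = {"pupil", "I", "H", "DKL", "baseline", "rt", "subject"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if df["subject"].nunique() < 2:
        raise ValueError("need at least 2 subjects for a random intercept")
    if zscore:
        for c in ("I", "H", "DKL", "baseline", "rt"):
            df[c] = (df[c] - df[c].mean()) / df[c].std(ddof=0)
    formula = _MODEL_FORMULAS[model_id]
    model = MixedLM.from_formula(formula, groups="subject", data=df)
    _check_rank(np.asarray(model.exog), list(model.exog_names))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit(reml=False)
    ci = fit.conf_int()
    fe = fit.fe_params
    rows = []
    for name in fe.index:
        est = float(fe[name])
        se = float(fit.bse[name])
        lo, hi = float(ci.loc[name, 0]), float(ci.loc[name, 1])
        p_dir = float(sps.norm.cdf(abs(est) / se)) if se > 0 else 1.0
        rows.append(
            {"term": name, "coef": est, "se": se, "ci_low": lo, "ci_high": hi,
             "p_direction": p_dir}
        )
    coeffs = pd.DataFrame(rows).set_index("term")

    lpd = _cv_pointwise_lpd(df, formula, cv_folds)
    elpd = float(lpd.sum())
    se = float(np.sqrt(lpd.size * lpd.var(ddof=1)))
    return HLMResult(
        model_id=model_id,
        formula=formula,
        coefficients=coeffs,
        elpd=elpd,
        elpd_se=se,
        pointwise_lpd=lpd,
        n_obs=len(df),
        group_var=float(fit.cov_re.iloc[0, 0]),
        resid_var=float(fit.scale),
    )


def _cv_pointwise_lpd(df: pd.DataFrame, formula: str, k: int) -> np.ndarray:
    df = df.reset_index(drop=True)
    fold = np.zeros(len(df), dtype=int)
    for _, idx in df.groupby("subject").groups.items():
        idx = np.asarray(list(idx))
        fold[idx] = np.arange(idx.size) % k
    lpd = np.zeros(len(df))
    for f in range(k):
        test = fold == f
        train = ~test
        model = MixedLM.from_formula(formula, groups="subject", data=df[train])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = model.fit(reml=False)
        mtest = MixedLM.from_formula(formula, groups="subject", data=df[test])
        mu = np.asarray(mtest.exog) @ fit.fe_params.to_numpy()
        try:
            re = fit.random_effects
        except (ValueError, np.linalg.LinAlgError):
            # random-effect variance shrank to zero: BLUPs are all zero
            re = {}
        u = np.array(
            [float(re[s].iloc[0]) if s in re else 0.0 for s in df.loc[test, "subject"]]
        )
        sigma = np.sqrt(fit.scale)
        lpd[test] = sps.norm.logpdf(np.asarray(mtest.endog), mu + u, sigma)
    return lpd


def compare_models(a: HLMResult, b: HLMResult) -> ModelComparison:
    """ELPD comparison; a ratio |dELPD| / SE(dELPD) > 2 is 'meaningful'."""
    if a.n_obs != b.n_obs:
        raise ValueError("models were fit on different data")
    d = b.pointwise_lpd - a.pointwise_lpd
    delta = float(d.sum())
    se = float(np.sqrt(d.size * d.var(ddof=1)))
    ratio = abs(delta) / se if se > 0 else np.inf
    meaningful = ratio > 2
    preferred = None
    if meaningful:
        preferred = b.model_id if delta > 0 else a.model_id
    return ModelComparison(
        delta_elpd=delta, se_delta=se, ratio=float(ratio),
        preferred=preferred, meaningful=meaningful,
    )


def fit_and_compare_hlm(
    trial_table: pd.DataFrame, cv_folds: int = 5, zscore: bool = False
) -> tuple[HLMResult, HLMResult, ModelComparison]:
    """Fit Model 1 and Model 2 on the same table and compare their ELPD."""
    r1 = fit_hlm(trial_table, 1, cv_folds=cv_folds, zscore=zscore)
    r2 = fit_hlm(trial_table, 2, cv_folds=cv_folds, zscore=zscore)
    return r1, r2, compare_models(r1, r2)
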