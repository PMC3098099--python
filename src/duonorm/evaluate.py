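"""Benchmarking of normalisation methods: ROC/AUC across simulation
runs and nearest-shrunken-centroid classification with .632 bootstrap
error estimation.

Antibodies are ranked by their raw moderated-t p-values against the
known spike-in truth; the empirical ROC curve and its area (equal to
the normalised Mann-Whitney U statistic; ties handled as midpoints)
measure how well a normalisation preserves true differential
expression.  Per scenario, runs are summarised by the median AUC, its
empirical 95% percentile interval, and a median ROC curve obtained by
vertical averaging (median sensitivity on a fixed 101-point
specificity grid).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

from .normalize_within import METHODS, RankInvariantParams
from .pipeline import background_correct_set, preprocess
from .simulate import BaselineModel, Scenario, generate_baseline, spike_in
from .diffexp import moderated_t_test

__all__ = [
    "roc_from_pvalues",
    "ROCSummary",
    "summarise_runs",
    "NearestShrunkenCentroid",
    "nsc_select_threshold",
    "bootstrap632",
    "ClassifierAssessment",
    "compare_methods",
    "summarise_results",
]

SPECIFICITY_GRID = np.linspace(0.0, 1.0, 101)


def roc_from_pvalues(p_raw: np.ndarray, truth: np.ndarray):
    """Empirical ROC of a p-value ranking against binary truth.

    Probes are ordered by ascending p; ties contribute as midpoints, so
    the trapezoidal AUC equals the rank-statistic (Mann-Whitney) AUC.
    Probes with undefined p are excluded.

    Returns
    -------
    fpr, tpr : ndarray
        ROC points over all thresholds.
    auc : float
    """
    p = np.asarray(p_raw, float)
    t = np.asarray(truth).astype(bool)
    ok = np.isfinite(p)
    p, t = p[ok], t[ok]
    if t.all() or not t.any():
        raise ValueError("truth needs at least one positive and one negative")
    score = -p
    fpr, tpr, _ = roc_curve(t, score, drop_intermediate=False)
    auc = float(roc_auc_score(t, score))
    return fpr, tpr, auc


@dataclass
class ROCSummary:
    """Across-run summary for one method in one scenario."""

    specificity_grid: np.ndarray
    median_sensitivity: np.ndarray
    aucs: np.ndarray
    median_auc: float
    ci_low: float | None
    ci_high: float | None


def summarise_runs(curves: list, aucs) -> ROCSummary:
    """Median ROC curve (vertical averaging on the specificity grid),
    median AUC and empirical 95% percentile interval across runs.

    The interval is suppressed (None) below 10 runs.
    """
    aucs = np.asarray(aucs, float)
    sens = np.empty((len(curves), SPECIFICITY_GRID.size))
    for i, (fpr, tpr) in enumerate(curves):
        sens[i] = np.interp(1.0 - SPECIFICITY_GRID[::-1], fpr, tpr)[::-1]
    median_curve = np.median(sens, axis=0)
    if aucs.size >= 10:
        ci_low, ci_high = np.percentile(aucs, [2.5, 97.5])
        ci_low, ci_high = float(ci_low), float(ci_high)
    else:
        warnings.warn("fewer than 10 runs; confidence interval suppressed")
        ci_low = ci_high = None
    return ROCSummary(
        specificity_grid=SPECIFICITY_GRID.copy(),
        median_sensitivity=median_curve,
        aucs=aucs,
        median_auc=float(np.median(aucs)),
        ci_low=ci_low,
        ci_high=ci_high,
    )


class NearestShrunkenCentroid(BaseEstimator, ClassifierMixin):
    """Nearest shrunken centroid classifier (PAM-style).

    Standardised class-centroid differences
    ``d_ik = (xbar_ik - xbar_i) / (m_k (s_i + s0))`` are soft-thresholded
    by ``threshold``; features whose differences all shrink to zero drop
    out of the classification.  ``s0`` is the median of the pooled
    within-class standard deviations; prediction is by smallest
    standardised distance to the shrunken centroids with a class-prior
    correction.  With every difference shrunk away, prediction falls
    back to the largest-prior class.
    """

    def __init__(self, threshold: float = 0.0, priors: str = "empirical"):
        self.threshold = threshold
        self.priors = priors

    def fit(self, X, y):
        if self.threshold < 0:
            raise ValueError("threshold must be >= 0")
        X = np.asarray(X, float)
        y = np.asarray(y)
        self.classes_, counts = np.unique(y, return_counts=True)
        K = self.classes_.size
        if K < 2 or counts.min() < 2:
            raise ValueError("need two classes with >= 2 samples each")
        n = X.shape[0]
        overall = X.mean(axis=0)
        centroids = np.vstack([X[y == c].mean(axis=0) for c in self.classes_])
        ss = np.zeros(X.shape[1])
        for k, c in enumerate(self.classes_):
            ss += ((X[y == c] - centroids[k]) ** 2).sum(axis=0)
        s = np.sqrt(ss / (n - K))
        s0 = float(np.median(s))
        mk = np.sqrt(1.0 / counts - 1.0 / n)
        denom = mk[:, None] * (s + s0)[None, :]
        d = (centroids - overall[None, :]) / denom
        d_shrunk = np.sign(d) * np.maximum(np.abs(d) - self.threshold, 0.0)
        self.overall_ = overall
        self.s_ = s
        self.s0_ = s0
        self.d_ = d
        self.d_shrunk_ = d_shrunk
        self.shrunken_centroids_ = overall[None, :] + denom * d_shrunk
        self.retained_ = np.any(d_shrunk != 0.0, axis=0)
        if self.priors == "empirical":
            self.priors_ = counts / n
        elif self.priors == "uniform":
            self.priors_ = np.full(K, 1.0 / K)
        else:
            self.priors_ = np.asarray(self.priors, float)
        return self

    def _scores(self, X):
        X = np.asarray(X, float)
        scale = (self.s_ + self.s0_) ** 2
        diffs = X[:, None, :] - self.shrunken_centroids_[None, :, :]
        scores = (diffs**2 / scale[None, None, :]).sum(axis=2)
        return scores - 2.0 * np.log(self.priors_)[None, :]

    def predict(self, X):
        scores = self._scores(X)
        return self.classes_[np.argmin(scores, axis=1)]

    @property
    def n_retained_(self) -> int:
        return int(self.retained_.sum())


def _threshold_grid(model: NearestShrunkenCentroid, n_thresholds: int) -> np.ndarray:
    return np.linspace(0.0, float(np.abs(model.d_).max()), n_thresholds)


def nsc_select_threshold(X, y, n_folds: int = 10, n_thresholds: int = 30,
                         seed: int = 0):
    """Choose the shrinkage threshold by stratified cross-validation.

    Grid of ``n_thresholds`` values from 0 to the largest standardised
    centroid difference; returns the threshold with the smallest CV
    error, ties resolved towards the largest (most parsimonious) value.
    Fold assignment is seeded, hence deterministic.
    """
    X = np.asarray(X, float)
    y = np.asarray(y)
    _, counts = np.unique(y, return_counts=True)
    if n_folds > counts.min():
        warnings.warn(f"reducing folds from {n_folds} to smallest class size {counts.min()}")
        n_folds = int(counts.min())
    full = NearestShrunkenCentroid().fit(X, y)
    grid = _threshold_grid(full, n_thresholds)
    errors = np.zeros(grid.size)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    for train, test in skf.split(X, y):
        for i, thr in enumerate(grid):
            clf = NearestShrunkenCentroid(threshold=thr).fit(X[train], y[train])
            errors[i] += np.sum(clf.predict(X[test]) != y[test])
    errors /= y.size
    best = errors.min()
    chosen = grid[np.nonzero(errors <= best + 1e-12)[0][-1]]
    return float(chosen), grid, errors


@dataclass
class ClassifierAssessment:
    """.632 bootstrap misclassification estimate for one dataset."""

    estimate: float
    apparent_error: float
    oob_errors: np.ndarray
    thresholds: np.ndarray = field(default_factory=lambda: np.array([]))


def bootstrap632(X, y, n_boot: int = 100, seed: int = 0, n_folds: int = 10,
                 n_thresholds: int = 30) -> ClassifierAssessment:
    """Estimate the misclassification error of the NSC classifier by the
    .632 bootstrap: 0.368 x apparent error + 0.632 x mean out-of-bag
    error over ``n_boot`` resamples, with the shrinkage threshold
    re-selected by internal cross-validation inside every resample.
    Degenerate resamples (single class or empty out-of-bag set) are
    redrawn (at most 50 times each)."""
    X = np.asarray(X, float)
    y = np.asarray(y)
    n = y.size
    rng = np.random.default_rng(seed)

    thr_full, _, _ = nsc_select_threshold(X, y, n_folds=n_folds,
                                          n_thresholds=n_thresholds, seed=seed)
    full = NearestShrunkenCentroid(threshold=thr_full).fit(X, y)
    apparent = float(np.mean(full.predict(X) != y))

    oob_errors = np.empty(n_boot)
    thresholds = np.empty(n_boot)
    for b in range(n_boot):
        for _attempt in range(50):
            idx = rng.integers(0, n, size=n)
            oob = np.setdiff1d(np.arange(n), idx)
            if np.unique(y[idx]).size == 2 and np.min(np.bincount(
                    np.searchsorted(np.unique(y[idx]), y[idx]))) >= 2 and oob.size:
                break
        else:
            raise RuntimeError("could not draw a two-class bootstrap sample in 50 tries")
        thr, _, _ = nsc_select_threshold(
            X[idx], y[idx], n_folds=n_folds, n_thresholds=n_thresholds,
            seed=int(rng.integers(2**31 - 1)),
        )
        clf = NearestShrunkenCentroid(threshold=thr).fit(X[idx], y[idx])
        oob_errors[b] = np.mean(clf.predict(X[oob]) != y[oob])
        thresholds[b] = thr
    estimate = 0.368 * apparent + 0.632 * float(np.mean(oob_errors))
    return ClassifierAssessment(estimate=float(estimate), apparent_error=apparent,
                                oob_errors=oob_errors, thresholds=thresholds)


def _run_seed(master: int, scen_idx: int, run: int) -> int:
    return int((master * 1_000_003 + scen_idx * 10_007 + run * 101 + 17) % (2**31 - 1))


def compare_methods(
    scenarios,
    methods=("gl", "invtseng", "invmod", "rdwgl", "nn"),
    model: BaselineModel | None = None,
    n_runs: int | None = None,
    seed: int = 0,
    background: str = "normexp",
    offset: float = 50.0,
    span: float = 0.3,
    params: dict | None = None,
    keep_curves: bool = False,
):
    """Run the full chain for each method on identical simulated inputs.

    One baseline is generated from ``model`` (seeded by ``seed``); each
    run of each scenario draws its own group assignment and spike-in.
    Background correction is shared across methods within a run.

    Returns
    -------
    results : DataFrame with columns scenario, run, method, auc.
    curves : dict {(scenario, method): [(fpr, tpr), ...]} if requested.
    """
    if isinstance(scenarios, Scenario):
        scenarios = [scenarios]
    for meth in methods:
        if meth not in METHODS:
            raise ValueError(f"unknown method {meth!r}; available: {', '.join(METHODS)}")
    model = model or BaselineModel()
    baseline = generate_baseline(model, rng=seed)
    rows = []
    curves: dict = {}
    for s_idx, scen in enumerate(scenarios):
        runs = n_runs if n_runs is not None else scen.n_runs
        for run in range(runs):
            ds = spike_in(baseline, scen, _run_seed(seed, s_idx, run))
            corrected = background_correct_set(ds.arrays, method=background,
                                               offset=offset)
            for meth in methods:
                if scen.prop_de == 0:
                    rows.append((scen.name, run, meth, np.nan))
                    continue
                p = _method_pvalues(corrected, meth, span=span, params=params)
                fpr, tpr, auc = roc_from_pvalues(p, ds.truth_de)
                rows.append((scen.name, run, meth, auc))
                if keep_curves:
                    curves.setdefault((scen.name, meth), []).append((fpr, tpr))
    results = pd.DataFrame(rows, columns=["scenario", "run", "method", "auc"])
    return (results, curves) if keep_curves else results


def _method_pvalues(corrected, method, span=0.3, params=None):
    meth_params = None
    if params and method in params:
        meth_params = params[method]
        if isinstance(meth_params, dict):
            meth_params = RankInvariantParams(**meth_params)
    collapsed = preprocess(corrected, method=method, span=span,
                           params=meth_params, corrected=True)
    res = moderated_t_test(collapsed.m_matrix(), corrected.group_label)
    return res.p_raw


def summarise_results(results: pd.DataFrame) -> pd.DataFrame:
    """Per scenario x method: median AUC and empirical 95% CI."""
    rows = []
    for (scen, meth), grp in results.groupby(["scenario", "method"], sort=False):
        aucs = grp["auc"].to_numpy()
        aucs = aucs[np.isfinite(aucs)]
        if aucs.size == 0:
            rows.append((scen, meth, np.nan, np.nan, np.nan, 0))
            continue
        lo, hi = (np.percentile(aucs, [2.5, 97.5]) if aucs.size >= 10
                  else (np.nan, np.nan))
        rows.append((scen, meth, float(np.median(aucs)), float(lo), float(hi),
                     aucs.size))
    return pd.DataFrame(
        rows, columns=["scenario", "method", "median_auc", "ci_lo", "ci_hi", "n_runs"]
    )


def plot_auc_boxplots(results: pd.DataFrame, path=None):
    """AUC boxplots per method, one panel per scenario."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    scens = results["scenario"].unique()
    fig, axes = plt.subplots(1, len(scens), figsize=(3.2 * len(scens), 3.4),
                             sharey=True, squeeze=False)
    for ax, scen in zip(axes[0], scens):
        sub = results[results["scenario"] == scen]
        methods = sub["method"].unique()
        data = [sub.loc[sub["method"] == m, "auc"].dropna() for m in methods]
        ax.boxplot(data, tick_labels=[m.upper() for m in methods])
        ax.axhline(0.5, color="grey", lw=0.8, ls="--")
        ax.set_title(scen)
        ax.tick_params(axis="x", rotation=45)
    axes[0][0].set_ylabel("AUC")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_median_roc(curves: dict, scenario: str, path=None):
    """Median ROC curves of every method for one scenario."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.2, 4.0))
    for (scen, meth), runs in curves.items():
        if scen != scenario:
            continue
        summ = summarise_runs(runs, [np.trapezoid(t, f) for f, t in runs])
        ax.plot(1.0 - summ.specificity_grid, summ.median_sensitivity,
                label=meth.upper())
    ax.plot([0, 1], [0, 1], color="grey", lw=0.8, ls="--")
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.set_title(scenario)
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
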