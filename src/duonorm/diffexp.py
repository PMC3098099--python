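"""Two-group differential expression with an empirical-Bayes moderated t.

Per probe, a two-sample linear model gives the group-mean difference,
the pooled within-group variance s_g^2 and its residual degrees of
freedom df_g = n1 + n2 − 2.  Borrowing strength across probes, the
variances are assumed to follow a scaled inverse chi-square prior with
parameters (d0, s0^2) estimated by matching the theoretical moments of
log s_g^2 under the scaled-F sampling distribution.  The posterior
variance

    s~_g^2 = (d0 * s0^2 + df_g * s_g^2) / (d0 + df_g)

replaces s_g^2 in the t statistic, which then has d0 + df_g degrees of
freedom.  Raw two-sided p-values (no multiplicity adjustment) are the
ranking statistic for the downstream ROC analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import special, stats
from sklearn.base import BaseEstimator

__all__ = ["fit_group_model", "ebayes_moderate", "moderated_t_test",
           "ModeratedTestResult", "ModeratedTTest"]


@dataclass
class GroupModelFit:
    """Per-probe two-sample linear model summaries."""

    effect: np.ndarray  # difference of group means (group1 − group2), log2 units
    s2: np.ndarray  # pooled residual variance
    df: np.ndarray  # residual degrees of freedom
    stdev_unscaled: float  # sqrt(1/n1 + 1/n2)
    groups: tuple


@dataclass
class ModeratedTestResult:
    """Moderated-t results; ``d0``/``s0_sq`` are the prior df/variance."""

    effect: np.ndarray
    ordinary_se: np.ndarray
    moderated_se: np.ndarray
    t_mod: np.ndarray
    p_raw: np.ndarray
    s0_sq: float
    d0: float


def fit_group_model(m_matrix: np.ndarray, groups) -> GroupModelFit:
    """Fit the per-probe two-sample model.

    ``m_matrix`` is probes x arrays of normalised log-ratios; ``groups``
    a two-class label per array.  Probes with fewer than two defined
    values in either group are NaN-marked throughout.
    """
    m = np.asarray(m_matrix, float)
    groups = np.asarray(groups)
    labels = sorted(set(groups.tolist()))
    if len(labels) != 2:
        raise ValueError(f"need exactly two groups, got {labels}")
    g1 = groups == labels[0]
    g2 = groups == labels[1]
    if g1.sum() < 2 or g2.sum() < 2:
        raise ValueError("both groups need >= 2 arrays")

    def _stats(sub):
        n = np.isfinite(sub).sum(axis=1).astype(float)
        mean = np.nanmean(np.where(np.isfinite(sub), sub, np.nan), axis=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            var = np.nanvar(sub, axis=1, ddof=1)
        return n, mean, var

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        n1, mean1, var1 = _stats(m[:, g1])
        n2, mean2, var2 = _stats(m[:, g2])
    ok = (n1 >= 2) & (n2 >= 2)
    effect = np.where(ok, mean1 - mean2, np.nan)
    df = np.where(ok, n1 + n2 - 2, np.nan)
    s2 = np.where(ok, ((n1 - 1) * var1 + (n2 - 1) * var2) / (n1 + n2 - 2), np.nan)
    c = float(np.sqrt(1.0 / g1.sum() + 1.0 / g2.sum()))
    return GroupModelFit(effect=effect, s2=s2, df=df, stdev_unscaled=c,
                         groups=(labels[0], labels[1]))


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton iteration)."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def estimate_prior(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Moment estimation of (d0, s0^2) from the log sample variances.

    Under the scaled-F model, z = log s^2 has
    E z = log s0^2 + psi(df/2) − log(df/2) − psi(d0/2) + log(d0/2) and
    Var z = psi'(df/2) + psi'(d0/2); solving the excess-variance
    equation gives d0.  Underdispersed variances (no excess) give
    d0 = inf: complete shrinkage to s0^2.
    """
    ok = np.isfinite(s2) & np.isfinite(df) & (s2 > 0) & (df > 0)
    s2f, dff = s2[ok], df[ok]
    if s2f.size < 20:
        raise ValueError(f"need >= 20 probes with positive df and variance, got {s2f.size}")
    z = np.log(s2f)
    e = z - special.digamma(dff / 2.0) + np.log(dff / 2.0)
    ebar = float(np.mean(e))
    n = e.size
    excess = float(np.mean((e - ebar) ** 2) * n / (n - 1)
                   - np.mean(special.polygamma(1, dff / 2.0)))
    if excess > 0:
        d0 = 2.0 * _trigamma_inverse(excess)
        s0_sq = float(np.exp(ebar + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        warnings.warn("underdispersed sample variances; prior df set to infinity")
        d0 = np.inf
        s0_sq = float(np.mean(s2f))  # all variances shrink to the common mean
    return d0, s0_sq


def ebayes_moderate(fit: GroupModelFit) -> ModeratedTestResult:
    """Shrink the per-probe variances and compute moderated t / p."""
    d0, s0_sq = estimate_prior(fit.s2, fit.df)
    s2 = fit.s2
    df = fit.df
    if np.isinf(d0):
        s2_post = np.where(np.isfinite(s2), s0_sq, np.nan)
        df_total = np.full_like(df, np.inf)
    else:
        s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
        df_total = d0 + df
    # total df capped at the pooled residual df across probes (the
    # information actually available about the common variance)
    df_pooled = float(np.nansum(df))
    df_total = np.minimum(df_total, df_pooled)
    c = fit.stdev_unscaled
    with np.errstate(invalid="ignore", divide="ignore"):
        t_mod = fit.effect / (np.sqrt(s2_post) * c)
        p = 2.0 * stats.t.sf(np.abs(t_mod),
                             np.where(np.isfinite(df_total), df_total, 1.0))
    p = np.where(np.isfinite(t_mod), p, np.nan)
    return ModeratedTestResult(
        effect=fit.effect,
        ordinary_se=np.sqrt(s2) * c,
        moderated_se=np.sqrt(s2_post) * c,
        t_mod=t_mod,
        p_raw=p,
        s0_sq=s0_sq,
        d0=d0,
    )


def moderated_t_test(m_matrix: np.ndarray, groups) -> ModeratedTestResult:
    """Convenience chain: two-sample fit + empirical-Bayes moderation."""
    return ebayes_moderate(fit_group_model(m_matrix, groups))


class ModeratedTTest(BaseEstimator):
    """Moderated two-sample t-test as a scikit-learn style estimator.

    ``fit(X, y)`` takes ``X`` of shape (n_arrays, n_probes) and binary
    labels ``y``; fitted attributes are ``effect_``, ``t_``,
    ``p_value_``, ``d0_`` and ``s0_sq_``.
    """

    def fit(self, X, y):
        X = np.asarray(X, float)
        res = moderated_t_test(X.T, np.asarray(y))
        self.effect_ = res.effect
        self.t_ = res.t_mod
        self.p_value_ = res.p_raw
        self.d0_ = res.d0
        self.s0_sq_ = res.s0_sq
        self.result_ = res
        return self
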