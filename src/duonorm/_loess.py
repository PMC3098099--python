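"""Weighted robust loess (local linear regression) in one dimension.

statsmodels' lowess accepts no prior observation weights, but the
rank-invariant normalisation family needs them: selection results enter
the MA regression as per-probe weights.  This module implements the
classic loess recipe — tricube kernel over a nearest-neighbour span,
local linear fit, Tukey-biweight robustifying iterations — with prior
weights multiplying the kernel.

For large fit sets the curve is evaluated at quantile-spaced knots and
linearly interpolated (the standard "delta" speed-up); below
``max_knots`` points every location is solved exactly.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = ["loess_fit", "WeightedLoess"]


def _solve_local_linear(x_eval, x, y, w, span):
    """Tricube-weighted local linear estimates at ``x_eval``.

    ``w`` are multiplicative observation weights (prior * robustness).
    Returns fitted values; NaN where no weighted point falls in the
    window (cannot happen for span-based windows with positive w).
    """
    n = x.size
    q = max(2, int(np.ceil(span * n)))
    q = min(q, n)
    d = np.abs(x_eval[:, None] - x[None, :])
    h = np.partition(d, q - 1, axis=1)[:, q - 1]
    h = np.maximum(h, 1e-12 * max(np.ptp(x), 1.0))
    u = d / h[:, None]
    k = np.clip(1.0 - u**3, 0.0, None) ** 3
    k *= w[None, :]
    dx = x[None, :] - x_eval[:, None]
    s0 = k.sum(axis=1)
    s1 = (k * dx).sum(axis=1)
    s2 = (k * dx * dx).sum(axis=1)
    t0 = k @ y
    t1 = (k * dx) @ y
    denom = s0 * s2 - s1 * s1
    scale = np.maximum(s0 * s2, 1e-300)
    fit = np.where(
        denom > 1e-10 * scale,
        (s2 * t0 - s1 * t1) / np.where(denom == 0, 1.0, denom),
        t0 / np.maximum(s0, 1e-300),
    )
    fit[s0 <= 0] = np.nan
    return fit


def loess_fit(
    x,
    y,
    weights=None,
    span: float = 0.3,
    robust_iters: int = 4,
    max_knots: int = 150,
):
    """Fit a robust weighted loess curve of y on x.

    Zero-weight observations are excluded from the fit entirely (they
    influence neither the span windows nor the local solves).

    Returns
    -------
    knots : ndarray
        Sorted x locations at which the curve was solved.
    values : ndarray
        Fitted curve at ``knots``.
    robustness : ndarray
        Final robustness weights for the fit points (in input order of
        the positively-weighted subset).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if weights is None:
        weights = np.ones_like(x)
    weights = np.asarray(weights, float)
    ok = (weights > 0) & np.isfinite(x) & np.isfinite(y)
    xf, yf, wf = x[ok], y[ok], weights[ok]
    if xf.size < 5:
        raise ValueError(f"too few weighted probes for loess: {xf.size}")
    if np.ptp(xf) == 0:
        mean = float(np.average(yf, weights=wf))
        return np.array([xf[0]]), np.array([mean]), np.ones_like(xf)

    if xf.size <= max_knots:
        knots = np.unique(xf)
    else:
        qs = np.linspace(0.0, 1.0, max_knots)
        knots = np.unique(np.quantile(xf, qs))

    robust = np.ones_like(xf)
    for it in range(robust_iters + 1):
        vals = _solve_local_linear(knots, xf, yf, wf * robust, span)
        if it == robust_iters:
            break
        resid = yf - np.interp(xf, knots, vals)
        s = np.median(np.abs(resid))
        if s <= 1e-12 * max(1.0, float(np.median(np.abs(yf))) if yf.size else 1.0):
            break
        r = np.clip(resid / (6.0 * s), -1.0, 1.0)
        robust = (1.0 - r * r) ** 2
    return knots, vals, robust


class WeightedLoess(BaseEstimator, RegressorMixin):
    """Robust weighted loess smoother with a scikit-learn interface.

    Parameters
    ----------
    span : float, default 0.3
        Fraction of (positively weighted) points in each local window.
    robust_iters : int, default 4
        Tukey-biweight robustifying iterations.
    max_knots : int, default 150
        Above this many fit points the curve is solved at quantile
        knots and interpolated.
    extrapolation : {'none', 'nearest', 'linear_tails'}, default 'none'
        Behaviour outside the weighted support: NaN, boundary value, or
        straight lines fitted through the ``tail_frac`` most extreme
        fit points on each side.
    tail_frac : float, default 0.1
        Fraction of fit points defining each extrapolation tail.

    Attributes
    ----------
    knots_, values_ : the fitted curve.
    support_ : (lo, hi) range of the weighted fit points.
    tail_coefs_ : {(slope, intercept) per side} when linear tails are used.
    """

    def __init__(self, span=0.3, robust_iters=4, max_knots=150,
                 extrapolation="none", tail_frac=0.1):
        self.span = span
        self.robust_iters = robust_iters
        self.max_knots = max_knots
        self.extrapolation = extrapolation
        self.tail_frac = tail_frac

    def fit(self, X, y, sample_weight=None):
        x = np.asarray(X, float).reshape(-1)
        y = np.asarray(y, float).reshape(-1)
        if self.extrapolation not in ("none", "nearest", "linear_tails"):
            raise ValueError(f"unknown extrapolation mode {self.extrapolation!r}")
        knots, vals, _rob = loess_fit(
            x, y, sample_weight, span=self.span,
            robust_iters=self.robust_iters, max_knots=self.max_knots,
        )
        self.knots_ = knots
        self.values_ = vals
        self.support_ = (float(knots[0]), float(knots[-1]))
        if self.extrapolation == "linear_tails":
            w = np.ones_like(x) if sample_weight is None else np.asarray(sample_weight, float)
            ok = (w > 0) & np.isfinite(x) & np.isfinite(y)
            xs, ys = x[ok], y[ok]
            k = max(2, int(np.ceil(self.tail_frac * xs.size)))
            order = np.argsort(xs)
            self.tail_coefs_ = {
                "lo": tuple(np.polyfit(xs[order[:k]], ys[order[:k]], 1)),
                "hi": tuple(np.polyfit(xs[order[-k:]], ys[order[-k:]], 1)),
            }
        else:
            self.tail_coefs_ = None
        return self

    def predict(self, X):
        x = np.asarray(X, float).reshape(-1)
        lo, hi = self.support_
        out = np.interp(x, self.knots_, self.values_)
        below, above = x < lo, x > hi
        if self.extrapolation == "none":
            out[below | above] = np.nan
        elif self.extrapolation == "linear_tails":
            slo, ilo = self.tail_coefs_["lo"]
            shi, ihi = self.tail_coefs_["hi"]
            out[below] = slo * x[below] + ilo
            out[above] = shi * x[above] + ihi
        # 'nearest': np.interp already clamps to boundary values
        out[~np.isfinite(x)] = np.nan
        return out
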