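"""Within-array normalisation for dual-colour arrays.

Boutique antibody arrays violate the classic loess assumptions (most
probes unchanged, symmetric regulation), so this module provides,
besides plain global loess (GL), normalisations restricted to
data-driven *rank-invariant* probe sets:

* ``InvTseng`` — the iterative rank-invariant selection of Tseng-style
  two-channel normalisation: start from probes whose Cy5/Cy3 ranks
  differ by less than ``d`` and whose average rank avoids the ``l`` most
  extreme ranks on either side; iterate with threshold ``p * |S|``
  (ranks recomputed within the current set) until the set size stops
  changing; binary loess weights; linear tail extrapolation outside the
  selected intensity range.

* ``InvMod`` — the modified selection: no boundary-rank exclusion in the
  initial step, slow high-retention iterations that keep the fraction
  ``p`` (default 0.99) of the current set with the smallest rank
  differences, stopping once at most ``k * G`` probes (default 25%)
  remain, and graded weights ``w_g = (max Δ − Δ_g) / max Δ`` from the
  standardised negative rank difference.  The selected set spans the
  full intensity range, so no extrapolation is needed.

* ``RDWGL`` — global loess with the graded rank-difference weights
  applied to all probes, without iterative selection.

* ``NN`` — no within-array normalisation (background-corrected M values
  used as-is).

Normalised M values are the residuals of a weighted robust loess
regression of M on A; their weighted mean over the fitting probes is
exactly zero (the curve is recentred by the residual weighted mean).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, TransformerMixin

from ._loess import WeightedLoess
from .arraydata import TwoColourArray, compute_ma

__all__ = [
    "RankInvariantParams",
    "SelectionResult",
    "LoessFit",
    "select_invariant_tseng",
    "select_invariant_mod",
    "rank_difference_weights",
    "loess_normalise",
    "normalise_gl",
    "normalise_invtseng",
    "normalise_invmod",
    "normalise_rdwgl",
    "normalise_none",
    "normalise",
    "MANormalizer",
    "METHODS",
]


@dataclass(frozen=True)
class RankInvariantParams:
    """Tuning parameters of the rank-invariant selection algorithms.

    ``d`` is the initial rank-difference threshold of the Tseng-style
    selection (default ``p * G``); ``l`` its boundary exclusion count;
    ``p`` the per-iteration selection proportion (0.02 for InvTseng,
    0.99 for InvMod); ``k`` the target selected proportion at which the
    modified algorithm stops (default 0.25).
    """

    d: float | None = None
    l: int = 25
    p: float = 0.02
    k: float = 0.25
    max_iter: int = 10_000
    min_size: int = 30

    def __post_init__(self):
        if not (0 < self.p < 1):
            raise ValueError("p must be in (0, 1)")
        if not (0 < self.k < 1):
            raise ValueError("k must be in (0, 1)")
        if self.l < 0:
            raise ValueError("l must be >= 0")
        if self.d is not None and self.d <= 0:
            raise ValueError("d must be > 0")


TSENG_DEFAULTS = RankInvariantParams(p=0.02, l=25)
INVMOD_DEFAULTS = RankInvariantParams(p=0.99, k=0.25, l=0)


@dataclass
class SelectionResult:
    """Outcome of a rank-invariant selection on one array.

    ``selected`` is a boolean mask over all probes; ``weights`` the
    loess weights (binary for the Tseng scheme, graded for the modified
    scheme, 0 outside the selection); ``rank_diffs`` the absolute rank
    differences Δ at the final iteration (NaN outside the final set);
    ``trace`` the selected-set sizes per iteration (nonincreasing).
    """

    selected: np.ndarray
    weights: np.ndarray
    rank_diffs: np.ndarray
    trace: list = field(default_factory=list)
    stalled: bool = False


class SelectionError(ValueError):
    pass


def _ranks(values: np.ndarray) -> np.ndarray:
    """Average-rank ties, 1-based."""
    return rankdata(values, method="average")


def select_invariant_tseng(
    array: TwoColourArray, params: RankInvariantParams = TSENG_DEFAULTS
) -> SelectionResult:
    """Iterative rank-invariant selection with boundary exclusion.

    Over the G unflagged probes (ranks with average ties): the initial
    set keeps probes with |r(cy5) − r(cy3)| < d and average rank
    strictly inside (l, G − l); each subsequent iteration re-ranks the
    channels within the current set and keeps members with rank
    difference < p·|S_prev|, stopping when the set size no longer
    changes.  An iteration that would shrink the set below
    ``params.min_size`` probes (too few to support a loess fit) is not
    applied: the previous set is kept and the result flagged
    ``stalled``.  With a small ``p`` the within-set threshold p·|S|
    eventually admits only exact rank ties, so this floor is what keeps
    the method usable on heavily regulated arrays.
    """
    mask = array.unflagged
    idx = np.nonzero(mask)[0]
    G = idx.size
    if G <= 2 * params.l + 10:
        raise SelectionError(f"too few unflagged probes ({G}) for boundary exclusion l={params.l}")
    d = params.d if params.d is not None else params.p * G
    r5 = _ranks(array.cy5[idx])
    r3 = _ranks(array.cy3[idx])
    delta0 = np.abs(r5 - r3)
    avg = 0.5 * (r5 + r3)
    current = (delta0 < d) & (avg > params.l) & (avg < G - params.l)
    if not current.any():
        raise SelectionError(f"empty initial rank-invariant set; increase d (= {d:g})")
    trace = [int(current.sum())]
    stalled = False
    for _ in range(params.max_iter):
        sub = np.nonzero(current)[0]
        r5s = _ranks(array.cy5[idx[sub]])
        r3s = _ranks(array.cy3[idx[sub]])
        delta_in = np.abs(r5s - r3s)
        keep = delta_in < params.p * sub.size
        if keep.sum() < min(params.min_size, G):
            warnings.warn(
                f"rank-invariant iteration would shrink the set to {int(keep.sum())} "
                f"(< {params.min_size}); keeping the previous set"
            )
            stalled = True
            break
        new = np.zeros_like(current)
        new[sub[keep]] = True
        trace.append(int(new.sum()))
        if new.sum() == current.sum():
            current = new
            break
        current = new

    sub = np.nonzero(current)[0]
    delta_fin = np.abs(_ranks(array.cy5[idx[sub]]) - _ranks(array.cy3[idx[sub]]))
    selected = np.zeros(array.n_probes, dtype=bool)
    selected[idx[sub]] = True
    weights = selected.astype(float)
    rank_diffs = np.full(array.n_probes, np.nan)
    rank_diffs[idx[sub]] = delta_fin
    return SelectionResult(selected, weights, rank_diffs, trace, stalled)


def select_invariant_mod(
    array: TwoColourArray, params: RankInvariantParams = INVMOD_DEFAULTS
) -> SelectionResult:
    """Modified rank-invariant selection with graded weights.

    Over the G unflagged probes: the initial set keeps probes with
    |r(cy5) − r(cy3)| < p·G (no boundary exclusion, so the extremes of
    the intensity range stay eligible).  Each iteration re-ranks the
    channels within the current set and keeps the proportion ``p`` of
    members with the smallest rank differences (quota ceil(p·|S|)).
    Ties at the boundary Δ value are all kept when that still shrinks
    the set; when keeping them would retain every member, boundary ties
    are broken by probe index down to the quota — unless every Δ in the
    set is equal, in which case no probe is distinguishable and the
    algorithm stops with the current set (degenerate, e.g. an exact
    self-self array).  Iteration ends at the first set of size <= k·G.
    Final weights are the standardised negative rank differences
    (max Δ − Δ_g)/max Δ within the final set, 0 outside; if every Δ is
    equal (max Δ = 0) all selected probes get weight 1.
    """
    mask = array.unflagged
    idx = np.nonzero(mask)[0]
    G = idx.size
    if G < 30:
        raise SelectionError(f"need >= 30 unflagged probes, got {G}")
    r5 = _ranks(array.cy5[idx])
    r3 = _ranks(array.cy3[idx])
    current = np.abs(r5 - r3) < params.p * G
    if not current.any():
        raise SelectionError("empty initial set; increase p")
    target = math.ceil(params.k * G)
    trace = [int(current.sum())]
    stalled = False
    it = 0
    while current.sum() > target and it < params.max_iter:
        it += 1
        sub = np.nonzero(current)[0]
        s = sub.size
        delta_in = np.abs(_ranks(array.cy5[idx[sub]]) - _ranks(array.cy3[idx[sub]]))
        quota = math.ceil(params.p * s)
        if quota >= s:
            # ceil(p*s) = s: the quota cannot shrink this set any further
            stalled = True
            warnings.warn(
                "modified rank-invariant selection cannot shrink below "
                f"{s} probes at p={params.p} (target {target})"
            )
            break
        boundary = np.partition(delta_in, quota - 1)[quota - 1]
        keep = delta_in <= boundary
        if keep.sum() == s:
            if delta_in.max() == delta_in.min():
                # perfect ties: no probe is less invariant than any other
                stalled = current.sum() > target
                if stalled:
                    warnings.warn(
                        "modified rank-invariant selection stopped on perfect ties "
                        f"above the target size ({int(current.sum())} > {target})"
                    )
                break
            # boundary ties span the whole set: break them by probe index
            below = delta_in < boundary
            at = np.nonzero(delta_in == boundary)[0]
            keep = below.copy()
            keep[at[: quota - int(below.sum())]] = True
        new = np.zeros_like(current)
        new[sub[keep]] = True
        current = new
        trace.append(int(current.sum()))

    sub = np.nonzero(current)[0]
    delta_fin = np.abs(_ranks(array.cy5[idx[sub]]) - _ranks(array.cy3[idx[sub]]))
    selected = np.zeros(array.n_probes, dtype=bool)
    selected[idx[sub]] = True
    weights = np.zeros(array.n_probes)
    weights[idx[sub]] = _standardised_neg_rank_diff(delta_fin)
    rank_diffs = np.full(array.n_probes, np.nan)
    rank_diffs[idx[sub]] = delta_fin
    return SelectionResult(selected, weights, rank_diffs, trace, stalled)


def _standardised_neg_rank_diff(delta: np.ndarray) -> np.ndarray:
    """(max Δ − Δ)/max Δ; all ones when max Δ = 0 (perfect ties)."""
    maxd = float(np.max(delta)) if delta.size else 0.0
    if maxd == 0.0:
        return np.ones_like(delta, dtype=float)
    return (maxd - delta) / maxd


def rank_difference_weights(array: TwoColourArray) -> np.ndarray:
    """Graded weights over *all* unflagged probes (the RDWGL scheme):
    Δ computed once from the full-array channel ranks."""
    mask = array.unflagged
    idx = np.nonzero(mask)[0]
    delta = np.abs(_ranks(array.cy5[idx]) - _ranks(array.cy3[idx]))
    weights = np.zeros(array.n_probes)
    weights[idx] = _standardised_neg_rank_diff(delta)
    return weights


@dataclass
class LoessFit:
    """Fitted MA curve of one within-array normalisation."""

    x_knots: np.ndarray
    y_knots: np.ndarray
    y_fit: np.ndarray  # curve evaluated at every probe (NaN where undefined)
    span: float
    weights_used: np.ndarray
    extrapolation: str


def loess_normalise(
    array: TwoColourArray,
    weights: np.ndarray,
    span: float = 0.3,
    extrapolation: str = "none",
    robust_iters: int = 4,
    max_knots: int = 150,
) -> tuple[TwoColourArray, LoessFit]:
    """Replace M by the residual from a weighted loess regression of M on A.

    Probes where the fit is undefined (outside the weighted support with
    ``extrapolation='none'``) get NaN M.  The weighted mean of the
    residuals over positively weighted probes is exactly 0 (recentred).
    """
    w = np.asarray(weights, float) * (array.weight > 0)
    ok = (w > 0) & np.isfinite(array.m) & np.isfinite(array.a)
    n_ok = int(ok.sum())
    if n_ok < 30:
        raise ValueError(f"too few positively weighted probes for loess: {n_ok}")
    smoother = WeightedLoess(
        span=span, robust_iters=robust_iters, max_knots=max_knots,
        extrapolation=extrapolation,
    )
    smoother.fit(array.a[ok], array.m[ok], sample_weight=w[ok])
    fitted = smoother.predict(array.a)
    resid = array.m - fitted
    shift = np.average(resid[ok], weights=w[ok])
    out = array.copy()
    out.m = resid - shift
    out.m[~np.isfinite(fitted) | ~np.isfinite(array.m)] = np.nan
    fit = LoessFit(
        x_knots=smoother.knots_, y_knots=smoother.values_ + shift,
        y_fit=fitted + shift, span=span, weights_used=w, extrapolation=extrapolation,
    )
    return out, fit


def _ensure_ma(array: TwoColourArray) -> TwoColourArray:
    if not np.any(np.isfinite(array.m)):
        return compute_ma(array)
    return array


def normalise_gl(array: TwoColourArray, span: float = 0.3, **loess_kw):
    """Global loess: equal weight on every unflagged probe."""
    array = _ensure_ma(array)
    out, fit = loess_normalise(array, array.weight, span=span,
                               extrapolation="none", **loess_kw)
    out.provenance.update(method="GL", span=span)
    return out, fit


def normalise_invtseng(
    array: TwoColourArray,
    params: RankInvariantParams = TSENG_DEFAULTS,
    span: float = 0.3,
    **loess_kw,
):
    """Rank-invariant loess with binary weights and linear tail
    extrapolation beyond the selected intensity range."""
    array = _ensure_ma(array)
    sel = select_invariant_tseng(array, params)
    out, fit = loess_normalise(array, sel.weights, span=span,
                               extrapolation="linear_tails", **loess_kw)
    out.provenance.update(method="InvTseng", span=span,
                          d=params.d if params.d is not None else "pG",
                          l=params.l, p=params.p)
    return out, fit, sel


def normalise_invmod(
    array: TwoColourArray,
    params: RankInvariantParams = INVMOD_DEFAULTS,
    span: float = 0.3,
    **loess_kw,
):
    """Modified rank-invariant loess with graded weights.

    The selected set spans the full intensity range by construction, so
    no extrapolation is required; any probe falling outside the
    selected support (pathological inputs only) is normalised by the
    nearest fitted value.
    """
    array = _ensure_ma(array)
    sel = select_invariant_mod(array, params)
    out, fit = loess_normalise(array, sel.weights, span=span,
                               extrapolation="nearest", **loess_kw)
    out.provenance.update(method="InvMod", span=span, k=params.k, p=params.p)
    return out, fit, sel


def normalise_rdwgl(array: TwoColourArray, span: float = 0.3, **loess_kw):
    """Rank-difference weighted global loess: graded weights on all
    probes, single weighted fit, no selection iterations."""
    array = _ensure_ma(array)
    weights = rank_difference_weights(array)
    out, fit = loess_normalise(array, weights, span=span,
                               extrapolation="none", **loess_kw)
    out.provenance.update(method="RDWGL", span=span)
    return out, fit


def normalise_none(array: TwoColourArray) -> TwoColourArray:
    """No within-array normalisation; M values pass through unchanged."""
    out = _ensure_ma(array).copy()
    out.provenance["method"] = "NN"
    return out


METHODS = ("gl", "invtseng", "invmod", "rdwgl", "nn")


def normalise(array: TwoColourArray, method: str, span: float = 0.3,
              params: RankInvariantParams | None = None, **loess_kw) -> TwoColourArray:
    """Dispatch a within-array normalisation by name; returns the
    normalised array (fit diagnostics discarded)."""
    method = method.lower()
    if method == "gl":
        return normalise_gl(array, span=span, **loess_kw)[0]
    if method == "invtseng":
        return normalise_invtseng(array, params or TSENG_DEFAULTS, span=span, **loess_kw)[0]
    if method == "invmod":
        return normalise_invmod(array, params or INVMOD_DEFAULTS, span=span, **loess_kw)[0]
    if method == "rdwgl":
        return normalise_rdwgl(array, span=span, **loess_kw)[0]
    if method == "nn":
        return normalise_none(array)
    raise ValueError(f"unknown method {method!r}; available: {', '.join(METHODS)}")


class MANormalizer(BaseEstimator, TransformerMixin):
    """Within-array MA normalisation as a scikit-learn transformer.

    ``X`` is an ``(n_probes, 2)`` matrix of background-corrected channel
    intensities, columns ``(cy5, cy3)``.  ``transform`` returns an
    ``(n_probes, 2)`` matrix with columns ``(a, m_normalised)``.

    Fitted attributes: ``selection_`` (rank-invariant SelectionResult,
    when the method selects), ``loess_`` (LoessFit, for the loess
    methods), ``weights_`` (loess weights actually used).
    """

    def __init__(self, method="invmod", span=0.3, params=None,
                 robust_iters=4, max_knots=150):
        self.method = method
        self.span = span
        self.params = params
        self.robust_iters = robust_iters
        self.max_knots = max_knots

    def _to_array(self, X, sample_weight=None) -> TwoColourArray:
        X = np.asarray(X, float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be (n_probes, 2) with columns (cy5, cy3)")
        from .arraydata import ProbeLayout

        layout = ProbeLayout.from_antibodies([f"p{i}" for i in range(X.shape[0])])
        arr = TwoColourArray(layout=layout, cy5=X[:, 0], cy3=X[:, 1],
                             weight=sample_weight)
        return compute_ma(arr)

    def fit(self, X, y=None, sample_weight=None):
        method = self.method.lower()
        if method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; available: {', '.join(METHODS)}")
        arr = self._to_array(X, sample_weight)
        kw = dict(span=self.span, robust_iters=self.robust_iters,
                  max_knots=self.max_knots)
        self.selection_ = None
        self.loess_ = None
        if method == "gl":
            out, self.loess_ = normalise_gl(arr, **kw)
        elif method == "invtseng":
            out, self.loess_, self.selection_ = normalise_invtseng(
                arr, self.params or TSENG_DEFAULTS, **kw)
        elif method == "invmod":
            out, self.loess_, self.selection_ = normalise_invmod(
                arr, self.params or INVMOD_DEFAULTS, **kw)
        elif method == "rdwgl":
            out, self.loess_ = normalise_rdwgl(arr, **kw)
        else:
            out = normalise_none(arr)
        self.weights_ = (self.loess_.weights_used if self.loess_ is not None
                         else arr.weight)
        self._fitted_output = np.column_stack([out.a, out.m])
        return self

    def transform(self, X):
        if not hasattr(self, "_fitted_output"):
            raise RuntimeError("MANormalizer must be fitted before transform")
        X = np.asarray(X, float)
        if X.shape[0] != self._fitted_output.shape[0]:
            raise ValueError("transform input must match the fitted array")
        return self._fitted_output.copy()
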