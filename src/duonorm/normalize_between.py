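"""A-quantile between-array normalisation.

Quantile-transforms the A-values so that their empirical distribution
is identical across all arrays of a set, while leaving the M-values
untouched.  The common target distribution is the across-array mean of
the sorted A-vectors; within-array A-ranks are preserved exactly and
the operation is idempotent.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.stats import rankdata

from .arraydata import ArraySet, intensities_from_ma

__all__ = ["aquantile_normalise"]


def _target_quantiles(sorted_vectors: list[np.ndarray], n: int) -> np.ndarray:
    """Mean of the sorted A-vectors, rank-interpolated to length n when
    arrays have unequal defined-probe counts."""
    grid = np.linspace(0.0, 1.0, n)
    acc = np.zeros(n)
    for vec in sorted_vectors:
        if vec.size == n:
            acc += vec
        else:
            acc += np.interp(grid, np.linspace(0.0, 1.0, vec.size), vec)
    return acc / len(sorted_vectors)


def aquantile_normalise(aset: ArraySet) -> ArraySet:
    """Equalise the A-value distribution across arrays.

    Ties in A map to the mean of the corresponding target quantiles;
    probes with undefined (NaN) A are skipped.  Channel intensities are
    recomputed from the new (m, a).  Arrays with unequal numbers of
    defined probes are handled by rank interpolation (with a warning).
    """
    if aset.n_arrays < 2:
        raise ValueError("A-quantile normalisation needs >= 2 arrays")
    defined = [np.isfinite(arr.a) for arr in aset.arrays]
    counts = {int(d.sum()) for d in defined}
    if len(counts) > 1:
        warnings.warn("arrays have unequal defined-probe counts; using rank interpolation")
    sorted_vecs = [np.sort(arr.a[d]) for arr, d in zip(aset.arrays, defined)]

    out = aset.copy()
    for arr, d, vec in zip(out.arrays, defined, sorted_vecs):
        n = int(d.sum())
        target = _target_quantiles(sorted_vecs, n)
        a_def = arr.a[d]
        ranks = rankdata(a_def, method="average")  # 1..n, ties -> average
        # average rank r maps to mean of target values at the tied positions,
        # which for average ties equals linear interpolation of target at r-1
        new_a = np.interp(ranks - 1.0, np.arange(n), target)
        a_full = arr.a.copy()
        a_full[d] = new_a
        arr.a = a_full
        # m untouched; refresh intensities for consistency with (m, a)
        ok = np.isfinite(arr.a) & np.isfinite(arr.m)
        cy5, cy3 = intensities_from_ma(arr.m[ok], arr.a[ok])
        arr.cy5[ok] = cy5
        arr.cy3[ok] = cy3
        arr.provenance["between_array"] = "aquantile"
    return out
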