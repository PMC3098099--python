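"""The full pre-processing + testing chain for one array set.

Order of operations: spot filtering (weights from flags) -> background
correction (normexp + offset) -> within-array normalisation (one of
GL / InvTseng / InvMod / RDWGL / NN) -> A-quantile between-array
normalisation -> duplicate-spot aggregation -> moderated-t differential
expression between the two sample groups.
"""

from __future__ import annotations

import numpy as np

from .arraydata import ArraySet, collapse_duplicates, compute_ma
from .background import normexp_correct
from .diffexp import ModeratedTestResult, moderated_t_test
from .normalize_between import aquantile_normalise
from .normalize_within import METHODS, RankInvariantParams, normalise

__all__ = ["background_correct_set", "preprocess", "run_pipeline"]


def background_correct_set(aset: ArraySet, method: str = "normexp",
                           offset: float = 50.0) -> ArraySet:
    """Background-correct every array of a set (and populate M/A)."""
    if method == "normexp":
        arrays = [normexp_correct(arr, offset=offset) for arr in aset.arrays]
    elif method == "none":
        arrays = [compute_ma(arr) for arr in aset.arrays]
    else:
        raise ValueError(f"unknown background method {method!r}")
    return ArraySet(arrays=arrays, group_label=aset.group_label,
                    replicate_of=aset.replicate_of)


def preprocess(
    aset: ArraySet,
    method: str = "invmod",
    span: float = 0.3,
    background: str = "normexp",
    offset: float = 50.0,
    between: str = "aquantile",
    collapse: str = "mean",
    params: RankInvariantParams | None = None,
    corrected: bool = False,
    **loess_kw,
) -> ArraySet:
    """Run the chain up to (and including) duplicate aggregation.

    Returns one row per antibody per array.  Set ``corrected=True`` when
    ``aset`` is already background-corrected with M/A populated (the
    background step is then skipped, allowing several within-array
    methods to share one corrected dataset).
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; available: {', '.join(METHODS)}")
    if not corrected:
        aset = background_correct_set(aset, method=background, offset=offset)
    arrays = [normalise(arr, method, span=span, params=params, **loess_kw)
              for arr in aset.arrays]
    out = ArraySet(arrays=arrays, group_label=aset.group_label,
                   replicate_of=aset.replicate_of)
    if between == "aquantile":
        out = aquantile_normalise(out)
    elif between != "none":
        raise ValueError(f"unknown between-array method {between!r}")
    return collapse_duplicates(out, method=collapse)


def run_pipeline(aset: ArraySet, method: str = "invmod", groups=None,
                 **kwargs) -> tuple[ModeratedTestResult, np.ndarray]:
    """Full chain ending in the moderated-t test.

    Returns the test result and the antibody identifiers (row order of
    the result vectors).  ``groups`` defaults to the set's group labels.
    """
    if groups is None:
        groups = aset.group_label
    if groups is None:
        raise ValueError("no group labels available for differential expression")
    collapsed = preprocess(aset, method=method, **kwargs)
    res = moderated_t_test(collapsed.m_matrix(), groups)
    return res, collapsed.layout.antibody_id.astype(str)
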