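"""Data model and I/O for two-channel antibody-microarray data.

A spotted dual-colour array carries, per spot (probe): two foreground
fluorescence intensities (Cy5, Cy3), optional local background estimates,
and a quality flag.  Downstream analysis works in MA coordinates,

    M = log2(Cy5 / Cy3),        A = (log2 Cy5 + log2 Cy3) / 2,

the log-ratio and average log-intensity of the two channels.  Flagged
spots are never dropped from the matrices; they carry weight 0 so that
probe layouts stay aligned across arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ProbeLayout",
    "TwoColourArray",
    "ArraySet",
    "Dialect",
    "GENEPIX_DIALECT",
    "read_array_table",
    "compute_ma",
    "intensities_from_ma",
    "collapse_duplicates",
    "write_ma_tables",
]


class ArrayFormatError(ValueError):
    """Raised for malformed input tables (missing columns, bad values)."""


@dataclass(frozen=True)
class ProbeLayout:
    """Spot layout shared by every array of an experiment.

    Parameters
    ----------
    antibody_id : array of str
        Name of the capture antibody printed at each spot.
    duplicate_group : array
        Identifier linking replicate spots of the same antibody.  Each
        probe belongs to exactly one group; group sizes are >= 1.
    is_control : array of str
        Control class per probe: ``none``, ``positional``, ``negative``
        or ``housekeeping``.
    """

    antibody_id: np.ndarray
    duplicate_group: np.ndarray
    is_control: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        aid = np.asarray(self.antibody_id, dtype=object)
        object.__setattr__(self, "antibody_id", aid)
        dg = np.asarray(self.duplicate_group, dtype=object)
        if dg.shape != aid.shape:
            raise ValueError("duplicate_group and antibody_id must have equal length")
        object.__setattr__(self, "duplicate_group", dg)
        if self.is_control is None:
            ic = np.full(aid.shape, "none", dtype=object)
        else:
            ic = np.asarray(self.is_control, dtype=object)
        object.__setattr__(self, "is_control", ic)

    @property
    def n_probes(self) -> int:
        return self.antibody_id.size

    @classmethod
    def from_antibodies(cls, antibody_ids: Sequence[str]) -> "ProbeLayout":
        """Layout where spots of the same antibody form one duplicate group."""
        aid = np.asarray(antibody_ids, dtype=object)
        return cls(antibody_id=aid, duplicate_group=aid.copy())


@dataclass
class TwoColourArray:
    """One two-channel array: intensities, weights and MA values.

    ``weight`` lies in [0, 1]; 0 marks a flagged/excluded spot.  ``m``
    and ``a`` are NaN until :func:`compute_ma` is applied and NaN for
    flagged spots afterwards.  ``provenance`` accumulates the processing
    history (background correction, normalisation method, parameters).
    """

    layout: ProbeLayout
    cy5: np.ndarray
    cy3: np.ndarray
    cy5_bg: np.ndarray = None  # type: ignore[assignment]
    cy3_bg: np.ndarray = None  # type: ignore[assignment]
    weight: np.ndarray = None  # type: ignore[assignment]
    m: np.ndarray = None  # type: ignore[assignment]
    a: np.ndarray = None  # type: ignore[assignment]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        n = self.layout.n_probes
        self.cy5 = np.asarray(self.cy5, dtype=float)
        self.cy3 = np.asarray(self.cy3, dtype=float)
        if self.cy5.shape != (n,) or self.cy3.shape != (n,):
            raise ValueError("intensity vectors must match the layout size")
        self.cy5_bg = (
            np.zeros(n) if self.cy5_bg is None else np.asarray(self.cy5_bg, float)
        )
        self.cy3_bg = (
            np.zeros(n) if self.cy3_bg is None else np.asarray(self.cy3_bg, float)
        )
        self.weight = (
            np.ones(n) if self.weight is None else np.asarray(self.weight, float)
        )
        if np.any((self.weight < 0) | (self.weight > 1)):
            raise ValueError("weights must lie in [0, 1]")
        self.m = np.full(n, np.nan) if self.m is None else np.asarray(self.m, float)
        self.a = np.full(n, np.nan) if self.a is None else np.asarray(self.a, float)

    @property
    def n_probes(self) -> int:
        return self.layout.n_probes

    @property
    def unflagged(self) -> np.ndarray:
        return self.weight > 0

    def copy(self) -> "TwoColourArray":
        return replace(
            self,
            cy5=self.cy5.copy(),
            cy3=self.cy3.copy(),
            cy5_bg=self.cy5_bg.copy(),
            cy3_bg=self.cy3_bg.copy(),
            weight=self.weight.copy(),
            m=self.m.copy(),
            a=self.a.copy(),
            provenance=dict(self.provenance),
        )


@dataclass
class ArraySet:
    """Ordered collection of arrays sharing one probe layout."""

    arrays: list
    group_label: list = None  # type: ignore[assignment]
    replicate_of: list = None  # type: ignore[assignment]

    def __post_init__(self):
        if not self.arrays:
            raise ValueError("ArraySet needs at least one array")
        lay = self.arrays[0].layout
        for arr in self.arrays[1:]:
            if arr.layout is not lay and not (
                np.array_equal(arr.layout.antibody_id, lay.antibody_id)
                and np.array_equal(arr.layout.duplicate_group, lay.duplicate_group)
            ):
                raise ValueError("all arrays must share an identical ProbeLayout")
        if self.group_label is not None and len(self.group_label) != len(self.arrays):
            raise ValueError("group_label length must match the number of arrays")

    @property
    def layout(self) -> ProbeLayout:
        return self.arrays[0].layout

    @property
    def n_arrays(self) -> int:
        return len(self.arrays)

    def m_matrix(self) -> np.ndarray:
        """Probes x arrays matrix of M values."""
        return np.column_stack([arr.m for arr in self.arrays])

    def a_matrix(self) -> np.ndarray:
        return np.column_stack([arr.a for arr in self.arrays])

    def weight_matrix(self) -> np.ndarray:
        return np.column_stack([arr.weight for arr in self.arrays])

    def copy(self) -> "ArraySet":
        return ArraySet(
            arrays=[a.copy() for a in self.arrays],
            group_label=None if self.group_label is None else list(self.group_label),
            replicate_of=None if self.replicate_of is None else list(self.replicate_of),
        )


@dataclass(frozen=True)
class Dialect:
    """Column-name mapping for tab-delimited array result tables.

    ``flag_bad`` receives the flag column values and returns a boolean
    mask of failed spots.  ``cy5_bg``/``cy3_bg``/``flag`` may be None
    ("no background" / "no flags" in the file).
    """

    id: str = "ID"
    name: str = "Name"
    cy5: str = "F635 Median"
    cy3: str = "F532 Median"
    cy5_bg: str | None = "B635 Median"
    cy3_bg: str | None = "B532 Median"
    flag: str | None = "Flags"

    @staticmethod
    def flag_bad(values: np.ndarray) -> np.ndarray:
        # GenePix convention: negative flags mark failed spots
        return np.asarray(values, dtype=float) < 0


#: Default GenePix-results-like column naming.
GENEPIX_DIALECT = Dialect()


def read_array_table(path, dialect: Dialect = GENEPIX_DIALECT) -> TwoColourArray:
    """Read one array from a tab-delimited results table.

    Spots whose flag column marks failure get weight 0 (spot filtering);
    all others weight 1.  Intensities are returned unmodified.

    Raises
    ------
    ArrayFormatError
        If a mandatory column is missing or an intensity fails to parse
        (the error names the column / 1-based file row).
    """
    df = pd.read_csv(path, sep="\t")
    for col in (dialect.id, dialect.cy5, dialect.cy3):
        if col is not None and col not in df.columns:
            raise ArrayFormatError(f"missing mandatory column {col!r} in {path}")

    def _numeric(colname):
        raw = df[colname]
        vals = pd.to_numeric(raw, errors="coerce").to_numpy(dtype=float)
        bad = np.nonzero(np.isnan(vals) & ~raw.isna().to_numpy())[0]
        if bad.size:
            # +2: header line plus 1-based counting
            raise ArrayFormatError(
                f"non-numeric value in column {colname!r} at file row {bad[0] + 2}"
            )
        return vals

    cy5 = _numeric(dialect.cy5)
    cy3 = _numeric(dialect.cy3)
    n = len(df)
    cy5_bg = _numeric(dialect.cy5_bg) if dialect.cy5_bg in df.columns else np.zeros(n)
    cy3_bg = _numeric(dialect.cy3_bg) if dialect.cy3_bg in df.columns else np.zeros(n)

    weight = np.ones(n)
    if dialect.flag is not None and dialect.flag in df.columns:
        weight[dialect.flag_bad(df[dialect.flag].to_numpy())] = 0.0

    if dialect.name in df.columns:
        names = df[dialect.name].astype(str).to_numpy()
    else:
        names = df[dialect.id].astype(str).to_numpy()
    layout = ProbeLayout.from_antibodies(names)
    return TwoColourArray(
        layout=layout, cy5=cy5, cy3=cy3, cy5_bg=cy5_bg, cy3_bg=cy3_bg, weight=weight,
        provenance={"source": str(path)},
    )


def compute_ma(array: TwoColourArray) -> TwoColourArray:
    """Populate M and A from the channel intensities.

    Flagged probes get NaN.  A nonpositive intensity on an unflagged
    probe is a domain error (after background correction with a positive
    offset this cannot occur).
    """
    out = array.copy()
    ok = out.unflagged
    bad = ok & ((out.cy5 <= 0) | (out.cy3 <= 0))
    if np.any(bad):
        idx = int(np.nonzero(bad)[0][0])
        raise ValueError(
            f"nonpositive intensity at unflagged probe {idx} "
            f"({out.layout.antibody_id[idx]!r}); background-correct first"
        )
    out.m = np.full(out.n_probes, np.nan)
    out.a = np.full(out.n_probes, np.nan)
    l5 = np.log2(out.cy5[ok])
    l3 = np.log2(out.cy3[ok])
    out.m[ok] = l5 - l3
    out.a[ok] = 0.5 * (l5 + l3)
    return out


def intensities_from_ma(m: np.ndarray, a: np.ndarray):
    """Inverse MA transform: cy5 = 2^(A + M/2), cy3 = 2^(A - M/2)."""
    m = np.asarray(m, float)
    a = np.asarray(a, float)
    return 2.0 ** (a + m / 2.0), 2.0 ** (a - m / 2.0)


def collapse_duplicates(aset: ArraySet, method: str = "mean") -> ArraySet:
    """Aggregate duplicate spots of each antibody into one row per array.

    ``m`` and ``a`` are aggregated by ``method`` ('mean' or 'median')
    over unflagged spots; groups with every spot flagged are NaN.
    Intensities are back-computed from the aggregated (m, a).  Happens
    after normalisation, before differential expression.
    """
    if method not in ("mean", "median"):
        raise ValueError("method must be 'mean' or 'median'")
    groups = aset.layout.duplicate_group.astype(str)
    uniq, first_idx, inv = np.unique(groups, return_index=True, return_inverse=True)
    order = np.argsort(first_idx)  # preserve layout order
    uniq = uniq[order]
    rank_of = np.empty(order.size, dtype=int)
    rank_of[order] = np.arange(order.size)
    gidx = rank_of[inv]  # spot -> output row
    sel = first_idx[order]
    new_layout = ProbeLayout(
        antibody_id=aset.layout.antibody_id[sel].copy(),
        duplicate_group=uniq.astype(object),
        is_control=aset.layout.is_control[sel].copy(),
    )
    n_groups = uniq.size
    new_arrays = []
    for arr in aset.arrays:
        ok = arr.unflagged & np.isfinite(arr.m) & np.isfinite(arr.a)
        counts = np.bincount(gidx[ok], minlength=n_groups)
        m_new = np.full(n_groups, np.nan)
        a_new = np.full(n_groups, np.nan)
        has = counts > 0
        if method == "mean":
            with np.errstate(invalid="ignore"):
                m_new[has] = (np.bincount(gidx[ok], weights=arr.m[ok],
                                          minlength=n_groups)[has] / counts[has])
                a_new[has] = (np.bincount(gidx[ok], weights=arr.a[ok],
                                          minlength=n_groups)[has] / counts[has])
        else:
            df = pd.DataFrame({"g": gidx[ok], "m": arr.m[ok], "a": arr.a[ok]})
            med = df.groupby("g").median()
            m_new[med.index.to_numpy()] = med["m"].to_numpy()
            a_new[med.index.to_numpy()] = med["a"].to_numpy()
        w_new = has.astype(float)
        cy5, cy3 = intensities_from_ma(m_new, a_new)
        new_arrays.append(
            TwoColourArray(
                layout=new_layout, cy5=cy5, cy3=cy3, weight=w_new, m=m_new, a=a_new,
                provenance={**arr.provenance, "collapsed": method},
            )
        )
    return ArraySet(
        arrays=new_arrays,
        group_label=None if aset.group_label is None else list(aset.group_label),
        replicate_of=None if aset.replicate_of is None else list(aset.replicate_of),
    )


def write_ma_tables(aset: ArraySet, m_path, a_path=None, provenance_path=None,
                    array_names=None):
    """Write normalised M (and optionally A) matrices as TSV plus a
    plain-text key=value provenance sidecar."""
    if array_names is None:
        array_names = [f"array_{j + 1}" for j in range(aset.n_arrays)]
    idx = pd.Index(aset.layout.antibody_id.astype(str), name="probe")
    pd.DataFrame(aset.m_matrix(), index=idx, columns=array_names).to_csv(
        m_path, sep="\t", float_format="%.10g"
    )
    if a_path is not None:
        pd.DataFrame(aset.a_matrix(), index=idx, columns=array_names).to_csv(
            a_path, sep="\t", float_format="%.10g"
        )
    if provenance_path is not None:
        prov = aset.arrays[0].provenance
        with open(provenance_path, "w") as fh:
            for key, val in sorted(prov.items()):
                fh.write(f"{key}={val}\n")
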