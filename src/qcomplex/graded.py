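"""Graded parameter sets: per-level summaries of a simplicial complex.

A graded parameter set assigns one value to every dimensional level
``q = 0..d_max``.  The classical trio are the structure vectors:

* FSV ``Q_q`` — number of q-connected components,
* SSV ``n_q`` — number of simplices of dimension ≥ q,
* TSV ``Q̄_q = 1 − Q_q/n_q`` — normalised connectedness in ``[0, 1)``.

Topological entropy adds an information-theoretic view: with ``Q_i^q``
the number of dimension-q simplices containing vertex i,
``p_i^q = Q_i^q / Σ_i Q_i^q`` and ``M_q`` the number of participating
vertices,

    S_Q(q) = −Σ_i p_i^q ln p_i^q / ln M_q ,

so 1 means perfectly even participation and 0 a single dominating
vertex.  Two per-level counts round out the bundle: simplices of
dimension exactly q, and unordered simplex pairs sharing a face of
dimension ≥ q.

Vectors are stored q-ascending with explicit q keys; the paper-style
descending display is a formatting convenience only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .complexes import SimplicialComplex

__all__ = [
    "GradedSeries",
    "GradedBundle",
    "SERIES_NAMES",
    "fsv",
    "ssv",
    "tsv",
    "topological_entropy",
    "simplex_count_per_dim",
    "shared_face_count",
    "graded_parameters",
    "to_tidy_table",
]

#: Supported series names, in stable output order.
SERIES_NAMES = ("FSV", "SSV", "TSV", "Entropy", "SimplexCount", "SharedFaces")

_RESERVED_COLUMNS = ("Vector", "q", "Value")


@dataclass(frozen=True)
class GradedSeries:
    """One named per-q vector over the levels ``0..d_max`` of a complex."""

    name: str
    values: np.ndarray  # q-ascending, index = q

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))

    @property
    def q_levels(self) -> np.ndarray:
        return np.arange(len(self.values))

    def as_dict(self) -> dict[int, float]:
        return {int(q): float(v) for q, v in enumerate(self.values)}

    def descending(self) -> np.ndarray:
        """Values ordered from q = d_max down to 0 (display convention)."""
        return self.values[::-1].copy()


@dataclass
class GradedBundle:
    """A named collection of :class:`GradedSeries` from one complex."""

    series: dict[str, GradedSeries]
    provenance: dict = field(default_factory=dict)

    def __getitem__(self, name: str) -> GradedSeries:
        return self.series[name]

    def __contains__(self, name: str) -> bool:
        return name in self.series

    def names(self) -> list[str]:
        return list(self.series)

    def to_dataframe(
        self,
        extra_columns: Mapping[str, object] | None = None,
        drop_undefined: bool = True,
    ) -> pd.DataFrame:
        return to_tidy_table(self, extra_columns, drop_undefined=drop_undefined)


def fsv(K: SimplicialComplex) -> GradedSeries:
    """First Structure Vector: q-connected component counts Q_q."""
    vals = [K.q_connected_components(q) for q in range(K.d_max + 1)]
    return GradedSeries("FSV", np.array(vals, dtype=float))


def ssv(K: SimplicialComplex) -> GradedSeries:
    """Second Structure Vector: counts n_q of simplices with dim ≥ q."""
    dims = np.array([len(s) - 1 for s in K.simplices])
    vals = [(dims >= q).sum() for q in range(K.d_max + 1)]
    return GradedSeries("SSV", np.array(vals, dtype=float))


def tsv(K: SimplicialComplex) -> GradedSeries:
    """Third Structure Vector Q̄_q = 1 − Q_q/n_q, in [0, 1)."""
    q_vals = fsv(K).values
    n_vals = ssv(K).values
    return GradedSeries("TSV", 1.0 - q_vals / n_vals)


def _participation(K: SimplicialComplex, q: int, cumulative: bool) -> np.ndarray:
    """Q_v^q: per-vertex count of simplices of dimension exactly (or ≥) q."""
    counts = np.zeros(K.n_vertices, dtype=np.int64)
    for s in K.simplices:
        d = len(s) - 1
        if (d >= q) if cumulative else (d == q):
            counts[list(s)] += 1
    return counts


def topological_entropy(
    K: SimplicialComplex, cumulative: bool = False
) -> GradedSeries:
    """Normalised entropy of vertex participation per dimension level.

    Participation counts use dimension *exactly* q by default, which
    makes them sum over q to each vertex's simplex-membership count (the
    topological dimensionality).  Set ``cumulative=True`` to count
    simplices of dimension ≥ q instead.

    Degenerate levels: when no simplex has the required dimension the
    value is NaN (nothing participates); when only one vertex
    participates (``M_q ≤ 1``) the value is 0.
    """
    out = np.empty(K.d_max + 1)
    for q in range(K.d_max + 1):
        counts = _participation(K, q, cumulative)
        total = counts.sum()
        if total == 0:
            out[q] = np.nan
            continue
        participating = counts[counts > 0]
        m_q = participating.size
        if m_q <= 1:
            out[q] = 0.0
            continue
        p = participating / total
        out[q] = float(-(p * np.log(p)).sum() / np.log(m_q))
    return GradedSeries("Entropy", out)


def simplex_count_per_dim(K: SimplicialComplex) -> GradedSeries:
    """Number of stored simplices of dimension exactly q."""
    dims = np.array([len(s) - 1 for s in K.simplices])
    vals = [(dims == q).sum() for q in range(K.d_max + 1)]
    return GradedSeries("SimplexCount", np.array(vals, dtype=float))


def shared_face_count(K: SimplicialComplex, cumulative: bool = True) -> GradedSeries:
    """Unordered simplex pairs sharing a face of dimension ≥ q (or exactly q)."""
    pi = K.connectivity_matrix()
    iu = np.triu_indices(K.m, k=1)
    off = pi[iu]
    if cumulative:
        vals = [(off >= q).sum() for q in range(K.d_max + 1)]
    else:
        vals = [(off == q).sum() for q in range(K.d_max + 1)]
    return GradedSeries("SharedFaces", np.array(vals, dtype=float))


_COMPUTERS = {
    "FSV": fsv,
    "SSV": ssv,
    "TSV": tsv,
    "Entropy": topological_entropy,
    "SimplexCount": simplex_count_per_dim,
    "SharedFaces": shared_face_count,
}


_CANONICAL = {name.lower(): name for name in SERIES_NAMES}


def graded_parameters(
    K: SimplicialComplex, desired: Sequence[str] | None = None
) -> GradedBundle:
    """Compute the requested graded series (all six when unspecified).

    Names are matched case-insensitively ("fsv" and "FSV" both work).
    """
    requested = list(desired) if desired else list(SERIES_NAMES)
    unknown = [n for n in requested if str(n).lower() not in _CANONICAL]
    if unknown:
        raise ValueError(
            f"unknown series name(s) {unknown}; supported: {list(SERIES_NAMES)}"
        )
    names = [_CANONICAL[str(n).lower()] for n in requested]
    series = {name: _COMPUTERS[name](K) for name in names}
    return GradedBundle(series, provenance={"m": K.m, "n_vertices": K.n_vertices})


def to_tidy_table(
    bundle: GradedBundle,
    extra_columns: Mapping[str, object] | None = None,
    drop_undefined: bool = True,
) -> pd.DataFrame:
    """Long-format table with one row per (series, q).

    Columns are (Vector, q, Value) plus any caller-supplied constant
    columns.  Undefined (NaN) entries — entropy at levels with no
    simplex of that exact dimension — are dropped by default.
    """
    extra = dict(extra_columns or {})
    clash = [c for c in extra if c in _RESERVED_COLUMNS]
    if clash:
        raise ValueError(f"extra column name(s) {clash} collide with reserved columns")
    rows = []
    for name, s in bundle.series.items():
        for q, v in enumerate(s.values):
            rows.append({"Vector": name, "q": q, "Value": v})
    df = pd.DataFrame(rows, columns=list(_RESERVED_COLUMNS))
    if drop_undefined:
        df = df.dropna(subset=["Value"]).reset_index(drop=True)
    for col, val in extra.items():
        df[col] = val
    return df
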