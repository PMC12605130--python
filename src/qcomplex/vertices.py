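"""Per-vertex and per-simplex secondary metrics.

Topological dimensionality D(v) counts the simplices containing vertex
v — the higher-order analogue of node degree, equal to the diagonal of
ΛᵀΛ.  Eccentricity ecc(σ|σ′) = |σ∖σ′| / |σ| measures how much of σ lies
outside σ′ (0 when σ ⊆ σ′, 1 when disjoint); family eccentricity takes
the minimum over a family of comparison simplices.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Iterable, Sequence

import numpy as np
import pandas as pd

from .complexes import SimplicialComplex

__all__ = [
    "NodeValues",
    "topological_dimensionality",
    "eccentricity",
    "family_eccentricity",
]

SimplexRef = "int | Iterable[Hashable]"


@dataclass
class NodeValues:
    """Per-vertex metric values keyed by vertex label."""

    values: dict
    metric_name: str

    def __getitem__(self, label):
        return self.values[label]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"Node": list(self.values), self.metric_name: list(self.values.values())}
        )


def topological_dimensionality(
    K: SimplicialComplex, node_names: Sequence[Hashable] | None = None
) -> NodeValues:
    """Number of stored simplices containing each vertex, diag(ΛᵀΛ)."""
    lam = K.incidence_matrix()
    diag = lam.sum(axis=0)  # = diag(ΛᵀΛ) for a binary matrix
    if node_names is not None:
        if len(node_names) != K.n_vertices:
            raise ValueError(
                f"node_names has length {len(node_names)}, expected {K.n_vertices}"
            )
        labels = list(node_names)
    else:
        labels = K.vertex_labels
    return NodeValues(
        {lab: int(d) for lab, d in zip(labels, diag)},
        metric_name="Topological Dimensionality",
    )


def eccentricity(K: SimplicialComplex, a, b) -> float:
    """Fraction of a's vertices not shared with b: |a∖b| / |a|.

    ``a`` and ``b`` are simplex references — position indices or vertex
    label sets matching a stored simplex.  Asymmetric in general.
    """
    sa = K.simplices[K.simplex_index(a)]
    sb = K.simplices[K.simplex_index(b)]
    return len(sa - sb) / len(sa)


def family_eccentricity(K: SimplicialComplex, s, family=None) -> float:
    """Minimum eccentricity of ``s`` against a family of simplices.

    The family defaults to every other simplex in the complex (the query
    itself is excluded: including it would make the result trivially 0).
    """
    i = K.simplex_index(s)
    if family is None:
        refs = [j for j in range(K.m) if j != i]
        if not refs:
            raise ValueError(
                "default family is empty: the complex has a single simplex"
            )
    else:
        refs = list(family)
        if not refs:
            raise ValueError("family must be non-empty")
    return min(eccentricity(K, i, f) for f in refs)
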