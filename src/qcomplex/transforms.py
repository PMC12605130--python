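"""Graph↔complex transformations and batch feature extraction.

Projections take a complex back to a pairwise graph (vertices co-occur
in a simplex of dimension ≥ q), the clique filter keeps only edges that
sit inside sufficiently large maximal cliques, and the batch helpers map
collections of networks or simplex lists to aligned numeric arrays of
graded parameters — features ready for downstream statistics or machine
learning.  Thin estimator-style wrappers (fit/transform) are provided
for pipeline use; they are stateless apart from the learned q-domain.
"""

from __future__ import annotations

from typing import Hashable, Iterable, Sequence

import numpy as np

from .complexes import SimplicialComplex
from .graded import SERIES_NAMES, graded_parameters

__all__ = [
    "simplex_projection",
    "clique_filter",
    "batch_graded_parameters",
    "batch_component_labels",
    "GradedParametersTransformer",
    "SimplexProjection",
    "GraphCliqueFilter",
    "QConnectedComponents",
]


def simplex_projection(
    K: SimplicialComplex, q: int = 0, weighted: bool = False
) -> np.ndarray:
    """Project a complex to a graph on its vertices.

    Every stored simplex of dimension ≥ q contributes all vertex pairs
    inside it; the weighted variant counts contributing simplices per
    pair (co-occurrence count), the unweighted one is a 0/1 indicator.
    ``q > d_max`` yields an empty graph.
    """
    if q < 0:
        raise ValueError(f"q must be non-negative, got {q}")
    n = K.n_vertices
    adj = np.zeros((n, n), dtype=np.int64)
    for s in K.simplices:
        if len(s) - 1 < q:
            continue
        idx = sorted(s)
        for a_pos, u in enumerate(idx):
            for v in idx[a_pos + 1 :]:
                adj[u, v] += 1
                adj[v, u] += 1
    if not weighted:
        adj = (adj > 0).astype(np.int64)
    return adj


def clique_filter(adj: np.ndarray, q: int) -> np.ndarray:
    """Keep only edges lying inside a maximal clique of ≥ q+1 vertices.

    Builds the clique complex, projects it at level q, and masks the
    projection with the original edge set, so the output edges are a
    subset of the input's and the operation is idempotent at fixed q.
    """
    adj = np.asarray(adj)
    K = SimplicialComplex.from_adjacency_matrix(adj)
    proj = simplex_projection(K, q=q, weighted=False) if q <= K.d_max else np.zeros_like(adj, dtype=np.int64)
    original = (adj - np.diag(np.diag(adj))) != 0
    return (proj.astype(bool) & original).astype(np.int64)


def batch_graded_parameters(
    networks: Sequence[np.ndarray],
    desired: Sequence[str] | None = None,
    max_order: int | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Graded parameters for a collection of graphs as one aligned array.

    Each adjacency matrix becomes a clique complex whose graded series
    are zero-padded to a common q-domain ``0..max_order`` (default: the
    largest d_max in the collection).  Returns the array of shape
    ``(n_networks, n_series, max_order + 1)`` and the series order.
    Undefined entropy levels are reported as 0 in the array.
    """
    if len(networks) == 0:
        raise ValueError("empty network collection")
    names = list(desired) if desired else list(SERIES_NAMES)
    complexes = [SimplicialComplex.from_adjacency_matrix(a) for a in networks]
    common = max(K.d_max for K in complexes)
    if max_order is None:
        max_order = common
    elif max_order < common:
        raise ValueError(
            f"max_order={max_order} is smaller than the largest complex dimension {common}"
        )
    out = np.zeros((len(complexes), len(names), max_order + 1))
    for i, K in enumerate(complexes):
        bundle = graded_parameters(K, names)
        for j, name in enumerate(names):
            vals = np.nan_to_num(bundle[name].values, nan=0.0)
            out[i, j, : len(vals)] = vals
    return out, names


def batch_component_labels(
    complexes: Sequence[Iterable[Iterable[Hashable]]], q: int
) -> list[list[set[int]]]:
    """q-connected component labelings for a collection of simplex lists."""
    if len(complexes) == 0:
        raise ValueError("empty complex collection")
    out = []
    for i, simplex_list in enumerate(complexes):
        try:
            K = SimplicialComplex(simplex_list)
            out.append(K.q_connected_components_labeled(q))
        except (ValueError, IndexError) as exc:
            raise ValueError(f"item {i}: {exc}") from exc
    return out


# -- estimator-style wrappers (scikit-learn transformer protocol) -----


class GradedParametersTransformer:
    """fit/transform wrapper around :func:`batch_graded_parameters`.

    ``fit`` records only the common q-domain of the fitted collection;
    ``transform`` is otherwise pure.
    """

    def __init__(self, desired: Sequence[str] | None = None, max_order: int | None = None):
        self.desired = desired
        self.max_order = max_order

    def fit(self, X: Sequence[np.ndarray], y=None):
        if self.max_order is None:
            self.max_order_ = max(
                SimplicialComplex.from_adjacency_matrix(a).d_max for a in X
            )
        else:
            self.max_order_ = self.max_order
        return self

    def transform(self, X: Sequence[np.ndarray]) -> np.ndarray:
        max_order = getattr(self, "max_order_", self.max_order)
        arr, self.series_names_ = batch_graded_parameters(X, self.desired, max_order)
        return arr

    def fit_transform(self, X: Sequence[np.ndarray], y=None) -> np.ndarray:
        return self.fit(X).transform(X)


class SimplexProjection:
    """fit/transform wrapper around :func:`simplex_projection`."""

    def __init__(self, q: int = 0, weighted: bool = False):
        self.q = q
        self.weighted = weighted

    def fit(self, X, y=None):
        return self

    def transform(self, X: Sequence[SimplicialComplex]) -> list[np.ndarray]:
        return [
            simplex_projection(K, q=self.q, weighted=self.weighted)
            if self.q <= K.d_max
            else np.zeros((K.n_vertices, K.n_vertices), dtype=np.int64)
            for K in X
        ]

    def fit_transform(self, X, y=None):
        return self.fit(X).transform(X)


class GraphCliqueFilter:
    """fit/transform wrapper around :func:`clique_filter`."""

    def __init__(self, q: int):
        self.q = q

    def fit(self, X, y=None):
        return self

    def transform(self, X: Sequence[np.ndarray]) -> list[np.ndarray]:
        return [clique_filter(a, self.q) for a in X]

    def fit_transform(self, X, y=None):
        return self.fit(X).transform(X)


class QConnectedComponents:
    """fit/transform wrapper around :func:`batch_component_labels`."""

    def __init__(self, q: int):
        self.q = q

    def fit(self, X, y=None):
        return self

    def transform(self, X) -> list[list[set[int]]]:
        return batch_component_labels(X, self.q)

    def fit_transform(self, X, y=None):
        return self.fit(X).transform(X)
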