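"""Simplicial complexes and q-connectivity.

A simplicial complex is stored as an ordered list of simplices (vertex
sets) over a contiguously indexed vertex set.  Stored simplices are the
analysis units: faces are implicit and maximality is *not* enforced, so a
simplex whose vertex set is a subset of another's is kept as a distinct
record (two papers by nested author teams are two interactions).

Q-analysis reads higher-order structure off two matrices.  The incidence
matrix ``Λ`` (m simplices × n vertices) records membership.  The
connectivity matrix

    Π = Λ·Λᵀ − Ω          (Ω the all-ones matrix)

has ``Π[i, j]`` equal to the dimension of the largest face shared by
simplices i and j (shared-vertex count minus one; −1 when disjoint) and
``Π[i, i] = dim σ_i``.  Two simplices are *q-near* when ``Π[i, j] ≥ q``;
chains of q-nearness partition the simplices of dimension ≥ q into
*q-connected components*, the central objects of the method.
"""

from __future__ import annotations

from typing import Hashable, Iterable, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components as _cc

__all__ = ["SimplicialComplex", "build_complex", "complex_from_adjacency"]


class SimplicialComplex:
    """An immutable simplicial complex over an indexed vertex set.

    Parameters
    ----------
    simplices
        One collection of vertex labels per simplex.  Labels may be any
        hashable objects; they are mapped to contiguous integer indices
        in order of first appearance.  Duplicate labels *within* a
        simplex are removed (set semantics).
    keep_duplicates
        When True (default) duplicate simplices — identical vertex sets —
        are retained as distinct records; when False they are collapsed
        to the first occurrence.
    vertex_labels
        Optional explicit vertex universe fixing the label→index
        mapping (index = position in this sequence).  Without it, labels
        are indexed in first-appearance order.  A simplex label outside
        the universe is an error.

    Attributes
    ----------
    simplices : list of frozenset of int
        Vertex-index sets, in input order.
    vertex_labels : list
        Label for each vertex index (index ``i`` ↔ ``vertex_labels[i]``).
    m, n_vertices, d_max, s_max : int
        Simplex count, vertex count, maximum dimension, maximum simplex
        size.
    """

    def __init__(
        self,
        simplices: Iterable[Iterable[Hashable]],
        keep_duplicates: bool = True,
        vertex_labels: Sequence[Hashable] | None = None,
    ) -> None:
        records = list(simplices)
        if not records:
            raise ValueError("cannot build a complex from an empty simplex list")

        fixed_universe = vertex_labels is not None
        labels: list[Hashable] = list(vertex_labels) if fixed_universe else []
        label_to_index: dict[Hashable, int] = {lab: i for i, lab in enumerate(labels)}
        if fixed_universe and len(label_to_index) != len(labels):
            raise ValueError("vertex_labels contains duplicates")
        sets: list[frozenset[int]] = []
        seen: set[frozenset[int]] = set()
        for pos, record in enumerate(records):
            members = list(record)
            if not members:
                raise ValueError(f"simplex at position {pos} is empty")
            idx = []
            for lab in members:
                if lab not in label_to_index:
                    if fixed_universe:
                        raise ValueError(
                            f"simplex at position {pos} uses vertex {lab!r} "
                            "outside the declared vertex universe"
                        )
                    label_to_index[lab] = len(labels)
                    labels.append(lab)
                idx.append(label_to_index[lab])
            s = frozenset(idx)
            if not keep_duplicates and s in seen:
                continue
            seen.add(s)
            sets.append(s)

        self.simplices: list[frozenset[int]] = sets
        self.vertex_labels: list[Hashable] = labels
        self.label_to_index: dict[Hashable, int] = label_to_index
        self.m: int = len(sets)
        self.n_vertices: int = len(labels)
        self.d_max: int = max(len(s) for s in sets) - 1
        self.s_max: int = self.d_max + 1
        self._incidence: np.ndarray | None = None
        self._connectivity: np.ndarray | None = None
        # q -> array of component ids (-1 for ineligible simplices)
        self._component_labels: list[np.ndarray] | None = None

    # -- construction -------------------------------------------------

    @classmethod
    def from_adjacency_matrix(cls, adj: np.ndarray) -> "SimplicialComplex":
        """Build the clique complex of an undirected graph.

        Every maximal clique (Bron–Kerbosch enumeration) becomes one
        simplex; isolated vertices become 0-simplices.  Cliques are
        sorted lexicographically on their sorted vertex indices so the
        simplex order is deterministic.

        The matrix must be square and symmetric; nonzero entries are
        edges, the diagonal is ignored, negative entries are rejected.
        """
        import networkx as nx

        adj = np.asarray(adj, dtype=float)
        if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
            raise ValueError(f"adjacency matrix must be square, got shape {adj.shape}")
        if (adj < 0).any():
            raise ValueError("adjacency matrix has negative entries")
        off = adj - np.diag(np.diag(adj))
        if not np.allclose(off, off.T):
            raise ValueError("adjacency matrix is not symmetric")
        n = adj.shape[0]
        graph = nx.Graph()
        graph.add_nodes_from(range(n))
        rows, cols = np.nonzero(off)
        graph.add_edges_from((int(i), int(j)) for i, j in zip(rows, cols) if i < j)
        cliques = sorted(sorted(c) for c in nx.find_cliques(graph))
        # fix the vertex universe so simplex indices equal graph node ids
        return cls(cliques, vertex_labels=range(n))

    # -- matrices ------------------------------------------------------

    def incidence_matrix(self) -> np.ndarray:
        """Binary m×n membership matrix Λ (rows simplices, columns vertices)."""
        if self._incidence is None:
            lam = np.zeros((self.m, self.n_vertices), dtype=np.int64)
            for i, s in enumerate(self.simplices):
                lam[i, list(s)] = 1
            self._incidence = lam
        return self._incidence

    def connectivity_matrix(self) -> np.ndarray:
        """Shared-face dimension matrix Π = Λ·Λᵀ − Ω (m×m, entries ≥ −1)."""
        if self._connectivity is None:
            lam = self.incidence_matrix()
            self._connectivity = lam @ lam.T - 1
        return self._connectivity

    def q_nearness(self, i: int, j: int) -> int:
        """Dimension of the largest face shared by simplices i and j (Π_ij)."""
        if not (0 <= i < self.m and 0 <= j < self.m):
            raise IndexError(
                f"simplex index out of range: ({i}, {j}) for m={self.m}"
            )
        return int(self.connectivity_matrix()[i, j])

    # -- q-connected components ---------------------------------------

    def _compute_all_components(self) -> list[np.ndarray]:
        """Label q-connected components for every q in 0..d_max at once.

        At level q only simplices of dimension ≥ q are eligible; edges
        join eligible pairs with Π_ij ≥ q.  Component ids are assigned in
        ascending order of each component's smallest simplex index;
        ineligible simplices carry −1.  Results are cached: the complex
        is immutable, so the cache never invalidates.
        """
        pi = self.connectivity_matrix()
        dims = np.array([len(s) - 1 for s in self.simplices])
        out: list[np.ndarray] = []
        for q in range(self.d_max + 1):
            eligible = np.flatnonzero(dims >= q)
            sub = pi[np.ix_(eligible, eligible)] >= q
            n_comp, raw = _cc(csr_matrix(sub), directed=False)
            labels = np.full(self.m, -1, dtype=np.int64)
            # relabel by smallest member index for determinism
            order: dict[int, int] = {}
            for pos, simplex_idx in enumerate(eligible):
                r = int(raw[pos])
                if r not in order:
                    order[r] = len(order)
                labels[simplex_idx] = order[r]
            out.append(labels)
        return out

    def _labels_at(self, q: int) -> np.ndarray:
        if not (0 <= q <= self.d_max):
            raise ValueError(f"q={q} outside valid range 0..{self.d_max}")
        if self._component_labels is None:
            self._component_labels = self._compute_all_components()
        return self._component_labels[q]

    def q_connected_components(self, q: int) -> int:
        """Number of q-connected components (the FSV entry Q_q)."""
        labels = self._labels_at(q)
        return int(labels.max()) + 1

    def q_connected_components_labeled(self, q: int) -> list[set[int]]:
        """q-connected components as sets of simplex indices.

        Components are ordered by their smallest member; simplices of
        dimension < q do not appear.
        """
        labels = self._labels_at(q)
        n_comp = int(labels.max()) + 1
        comps: list[set[int]] = [set() for _ in range(n_comp)]
        for idx, lab in enumerate(labels):
            if lab >= 0:
                comps[lab].add(idx)
        return comps

    # -- misc ----------------------------------------------------------

    def simplex_index(self, ref: int | Iterable[Hashable]) -> int:
        """Resolve a simplex reference (position index or vertex-label set)."""
        if isinstance(ref, (int, np.integer)):
            i = int(ref)
            if not 0 <= i < self.m:
                raise IndexError(f"simplex index {i} out of range for m={self.m}")
            return i
        labels = list(ref)
        try:
            target = frozenset(self.label_to_index[lab] for lab in labels)
        except KeyError as exc:
            raise KeyError(f"unknown vertex label {exc.args[0]!r}") from None
        for i, s in enumerate(self.simplices):
            if s == target:
                return i
        raise KeyError(f"no stored simplex with vertex set {sorted(labels, key=repr)}")

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"SimplicialComplex(m={self.m}, n_vertices={self.n_vertices}, "
            f"d_max={self.d_max})"
        )


def build_complex(
    simplex_list: Sequence[Iterable[Hashable]], keep_duplicates: bool = True
) -> SimplicialComplex:
    """Construct a :class:`SimplicialComplex` from a list of label records."""
    return SimplicialComplex(simplex_list, keep_duplicates=keep_duplicates)


def complex_from_adjacency(adj: np.ndarray) -> SimplicialComplex:
    """Clique complex of a graph given by its adjacency matrix."""
    return SimplicialComplex.from_adjacency_matrix(adj)
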