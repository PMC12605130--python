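"""Independent oracles and random-input generators shared across tests.

The component oracle here deliberately avoids the package's matrix
pipeline: it works on raw vertex sets with breadth-first search, so it
can cross-check the cached all-levels algorithm.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def oracle_q_components(simplices: list[set], q: int) -> list[set[int]]:
    """q-connected components by direct BFS over vertex-set intersections.

    Eligible simplices have at least q+1 vertices; an edge joins a pair
    sharing at least q+1 vertices.  Components are returned ordered by
    smallest member index.
    """
    sets = [set(s) for s in simplices]
    eligible = [i for i, s in enumerate(sets) if len(s) - 1 >= q]
    unvisited = set(eligible)
    comps = []
    for start in eligible:
        if start not in unvisited:
            continue
        comp = {start}
        unvisited.discard(start)
        queue = deque([start])
        while queue:
            i = queue.popleft()
            for j in list(unvisited):
                if len(sets[i] & sets[j]) - 1 >= q:
                    unvisited.discard(j)
                    comp.add(j)
                    queue.append(j)
        comps.append(comp)
    return comps


def oracle_component_counts(simplices: list[set]) -> list[int]:
    """Component count for every q from 0 to the maximum dimension."""
    d_max = max(len(s) for s in simplices) - 1
    return [len(oracle_q_components(simplices, q)) for q in range(d_max + 1)]


def random_simplex_list(
    rng: np.random.Generator,
    max_simplices: int = 12,
    max_vertices: int = 10,
    max_size: int = 5,
) -> list[list[int]]:
    """A random simplex list over a small vertex pool (duplicates allowed)."""
    m = int(rng.integers(1, max_simplices + 1))
    out = []
    for _ in range(m):
        size = int(rng.integers(1, max_size + 1))
        out.append(sorted(rng.choice(max_vertices, size=size, replace=False).tolist()))
    return out


def brute_force_graphical(seq: list[int]) -> bool:
    """Is there a simple graph with this degree sequence?  (n ≤ 6 only.)

    Exhaustive search over all edge subsets — the independent check for
    the Erdős–Gallai validation used by the generators.
    """
    from itertools import combinations

    n = len(seq)
    assert n <= 6
    if sum(seq) % 2:
        return False
    pairs = list(combinations(range(n), 2))
    for mask in range(2 ** len(pairs)):
        deg = [0] * n
        for b, (i, j) in enumerate(pairs):
            if mask >> b & 1:
                deg[i] += 1
                deg[j] += 1
        if deg == list(seq):
            return True
    return False
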