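"""Seeded network generators and reference fixtures.

The simulation study that these generators support contrasts scale-free
(preferential-attachment) networks with configurational networks that
realize the *same* degree sequence via the Havel–Hakimi construction.
Identical degree distributions, very different higher-order structure:
the configurational graphs concentrate high-degree vertices into a
dense core that sustains large cliques, and hence q-connected
components at levels where the paired scale-free graphs have none.

Preferential attachment follows the Barabási–Albert rule with a star on
``m_parameter + 1`` nodes as the seed graph, so every generated graph
has exactly ``(n_nodes − m_parameter) · m_parameter`` edges.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np

from .complexes import SimplicialComplex

__all__ = [
    "GeneratorSpec",
    "DEFAULT_STUDY",
    "SMALL_STUDY",
    "generate_scale_free",
    "generate_configurational",
    "paired_study_ensembles",
    "worked_example_complex",
    "reference_complex",
    "save_ensemble",
    "load_ensemble",
]


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of one simulated ensemble.

    n_nodes: vertices per graph; m_parameter: edges attached by each new
    node during preferential attachment; n_samples: ensemble size; seed:
    base seed for reproducibility.
    """

    n_nodes: int
    m_parameter: int
    n_samples: int
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.m_parameter < self.n_nodes:
            raise ValueError(
                f"need 1 <= m_parameter < n_nodes, got m={self.m_parameter}, n={self.n_nodes}"
            )
        if self.n_samples < 1:
            raise ValueError(f"n_samples must be ≥ 1, got {self.n_samples}")


#: Full-scale study conditions (100 networks of 100 nodes, m = 8).
DEFAULT_STUDY = GeneratorSpec(n_nodes=100, m_parameter=8, n_samples=100, seed=0)
#: Alternative preset with fewer nodes and heavier attachment (m = 10).
SMALL_STUDY = GeneratorSpec(n_nodes=50, m_parameter=10, n_samples=100, seed=0)


def generate_scale_free(spec: GeneratorSpec) -> list[np.ndarray]:
    """Seeded Barabási–Albert ensemble as dense adjacency matrices."""
    rng = np.random.default_rng(spec.seed)
    out = []
    for _ in range(spec.n_samples):
        graph_seed = int(rng.integers(0, 2**31 - 1))
        g = nx.barabasi_albert_graph(
            spec.n_nodes,
            spec.m_parameter,
            seed=graph_seed,
            initial_graph=nx.star_graph(spec.m_parameter),
        )
        out.append(nx.to_numpy_array(g, nodelist=range(spec.n_nodes), dtype=np.int64))
    return out


def generate_configurational(
    degree_sequences: Sequence[Sequence[int]],
    randomize: bool = False,
    seed: int | None = None,
) -> list[np.ndarray]:
    """Havel–Hakimi realization of each degree sequence.

    Every sequence is checked for graphicality (Erdős–Gallai); a
    non-graphical sequence raises an error naming its position.  The
    deterministic Havel–Hakimi graph is returned as-is by default; with
    ``randomize=True`` it is followed by seeded degree-preserving
    double-edge swaps (10× the edge count attempted), which shuffles the
    wiring while keeping the degree sequence exact.
    """
    rng = np.random.default_rng(seed)
    out = []
    for i, seq in enumerate(degree_sequences):
        seq = [int(d) for d in seq]
        if not nx.is_graphical(seq):
            raise ValueError(f"degree sequence at position {i} is not graphical: {seq}")
        g = nx.havel_hakimi_graph(seq)
        if randomize and g.number_of_edges() > 1:
            nswap = 10 * g.number_of_edges()
            swap_seed = int(rng.integers(0, 2**31 - 1))
            nx.double_edge_swap(g, nswap=nswap, max_tries=50 * nswap, seed=swap_seed)
        out.append(nx.to_numpy_array(g, nodelist=range(len(seq)), dtype=np.int64))
    return out


def paired_study_ensembles(
    spec: GeneratorSpec, randomize: bool = False
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Scale-free ensemble plus index-paired configurational ensemble.

    The i-th configurational network realizes the exact degree sequence
    of the i-th scale-free network.
    """
    scale_free = generate_scale_free(spec)
    sequences = [a.sum(axis=0).astype(int).tolist() for a in scale_free]
    configurational = generate_configurational(
        sequences, randomize=randomize, seed=spec.seed + 1
    )
    return scale_free, configurational


def worked_example_complex() -> SimplicialComplex:
    """The two-triangle complex {⟨v1,v2,v3⟩, ⟨v2,v3,v4⟩}.

    The standard hand-checkable example: the simplices share the edge
    ⟨v2,v3⟩ (a 1-face), so FSV = [2,1,1], SSV = [2,2,2] and
    TSV = [0,0.5,0.5] in descending-q display.
    """
    return SimplicialComplex([["v1", "v2", "v3"], ["v2", "v3", "v4"]])


def reference_complex() -> SimplicialComplex:
    """A four-simplex documentation complex over seven vertices.

    Synthetic fixture built to satisfy a standard set of published
    constraints on a 4×7 incidence matrix: σ1 is a 3-simplex, σ1 and σ2
    share the 2-face {V1,V5,V6}, σ1 and σ3 share only V6, σ2 and σ3
    share a 1-face, σ4 is an edge touching the rest only at q = 0.  Its
    component counts are 2 at q = 3, 2 at q = 2, 2 at q = 1 and 1 at
    q = 0 (FSV [2,2,2,1] descending).
    """
    return SimplicialComplex(
        [
            ["V1", "V4", "V5", "V6"],
            ["V1", "V5", "V6", "V7"],
            ["V2", "V6", "V7"],
            ["V2", "V3"],
        ]
    )


def save_ensemble(
    directory: str | Path, networks: Sequence[np.ndarray], spec: GeneratorSpec
) -> None:
    """Write one adjacency CSV per network plus a JSON manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    width = len(str(len(networks) - 1))
    files = []
    for i, a in enumerate(networks):
        name = f"network_{i:0{width}d}.csv"
        np.savetxt(directory / name, np.asarray(a, dtype=int), fmt="%d", delimiter=",")
        files.append(name)
    manifest = {"spec": asdict(spec), "files": files}
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")


def load_ensemble(directory: str | Path) -> tuple[list[np.ndarray], dict]:
    """Read back an ensemble written by :func:`save_ensemble`."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    networks = [
        np.loadtxt(directory / name, delimiter=",", ndmin=2)
        for name in manifest["files"]
    ]
    return networks, manifest
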