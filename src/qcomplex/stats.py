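"""Consensus networks and group-level permutation testing.

To compare two groups of same-node-set networks, each group is reduced
to a *consensus network*: the binary graph of edges present in at least
an inclusion-threshold fraction of the group's (binarized) networks.
The test statistic is the element-wise absolute difference between the
graded-parameter arrays of the two consensus clique complexes, padded to
a common q-domain — one statistic per (series, q) cell.  A null
distribution comes from permuting group labels (group sizes preserved)
and recomputing; p-values use the add-one estimator

    p = (1 + #{permuted ≥ observed}) / (1 + n_resamples)

so they are never exactly zero.  No multiple-testing correction is
applied by default; Benjamini–Hochberg is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .complexes import SimplicialComplex
from .graded import SERIES_NAMES, graded_parameters

__all__ = [
    "NetworkEnsemble",
    "PermutationResult",
    "consensus_adjacency",
    "pad_structure_vectors",
    "consensus_statistic",
    "permutation_test",
]


@dataclass
class NetworkEnsemble:
    """Same-shape adjacency matrices with optional per-network labels."""

    networks: list
    group_labels: list | None = None

    def __post_init__(self) -> None:
        self.networks = [np.asarray(a) for a in self.networks]
        _check_shapes(self.networks)
        if self.group_labels is not None and len(self.group_labels) != len(
            self.networks
        ):
            raise ValueError("group_labels length must match number of networks")

    def __len__(self) -> int:
        return len(self.networks)


def _as_networks(group) -> list[np.ndarray]:
    if isinstance(group, NetworkEnsemble):
        return group.networks
    return [np.asarray(a) for a in group]


def _check_shapes(networks: Sequence[np.ndarray]) -> None:
    if len(networks) == 0:
        raise ValueError("empty network ensemble")
    shape = networks[0].shape
    if len(shape) != 2 or shape[0] != shape[1]:
        raise ValueError(f"adjacency matrices must be square, got shape {shape}")
    for i, a in enumerate(networks):
        if a.shape != shape:
            raise ValueError(
                f"network {i} has shape {a.shape}, expected {shape}"
            )


def consensus_adjacency(
    networks: Sequence[np.ndarray], edge_inclusion_threshold: float = 0.95
) -> np.ndarray:
    """Binary consensus graph of an ensemble.

    Each network is binarized (nonzero → 1); an edge enters the
    consensus iff its occurrence frequency across the ensemble is ≥ the
    inclusion threshold (inclusive).  Threshold 1.0 gives the
    intersection of all edge sets.
    """
    nets = _as_networks(networks)
    _check_shapes(nets)
    if not 0.0 < edge_inclusion_threshold <= 1.0:
        raise ValueError(
            f"edge_inclusion_threshold must be in (0, 1], got {edge_inclusion_threshold}"
        )
    stack = np.stack([(a != 0).astype(float) for a in nets])
    freq = stack.mean(axis=0)
    consensus = (freq >= edge_inclusion_threshold).astype(np.int64)
    np.fill_diagonal(consensus, 0)
    return consensus


def pad_structure_vectors(
    vectors: Sequence[np.ndarray], max_order: int
) -> np.ndarray:
    """Zero-pad q-ascending vectors at high q to a common length.

    ``max_order`` must be at least every input length − 1; the result
    has shape ``(len(vectors), max_order + 1)``.
    """
    arrs = [np.asarray(v, dtype=float).ravel() for v in vectors]
    too_long = [i for i, v in enumerate(arrs) if len(v) > max_order + 1]
    if too_long:
        raise ValueError(
            f"max_order={max_order} too small for vector(s) at position(s) {too_long}"
        )
    out = np.zeros((len(arrs), max_order + 1))
    for i, v in enumerate(arrs):
        out[i, : len(v)] = v
    return out


def consensus_statistic(
    group_a,
    group_b,
    max_order: int,
    edge_inclusion_threshold: float = 0.95,
    desired: Sequence[str] | None = None,
) -> np.ndarray:
    """|graded parameters of consensus(A) − consensus(B)| per (series, q).

    Each group is collapsed to its consensus network, the clique complex
    of each consensus is summarised by its graded series (zero for
    undefined entropy levels), both arrays are padded to
    ``0..max_order``, and the element-wise absolute difference is
    returned with shape ``(n_series, max_order + 1)``.  Symmetric under
    group swap.
    """
    names = list(desired) if desired else list(SERIES_NAMES)
    sides = []
    for group in (group_a, group_b):
        consensus = consensus_adjacency(group, edge_inclusion_threshold)
        K = SimplicialComplex.from_adjacency_matrix(consensus)
        bundle = graded_parameters(K, names)
        rows = [np.nan_to_num(bundle[n].values, nan=0.0) for n in names]
        padded = pad_structure_vectors(rows, max_order)
        sides.append(padded)
    return np.abs(sides[0] - sides[1])


@dataclass
class PermutationResult:
    """Observed statistic, permutation p-values and test metadata."""

    observed: np.ndarray
    p_values: np.ndarray
    n_resamples: int
    seed: int | None
    series_names: list[str] | None = None

    def to_dataframe(self) -> pd.DataFrame:
        """Tidy table with one row per (series, q) cell."""
        names = self.series_names or [
            f"series{i}" for i in range(self.observed.shape[0])
        ]
        rows = []
        for i, name in enumerate(names):
            for q in range(self.observed.shape[1]):
                rows.append(
                    {
                        "Vector": name,
                        "q": q,
                        "Statistic": self.observed[i, q],
                        "p": self.p_values[i, q],
                    }
                )
        return pd.DataFrame(rows)


def permutation_test(
    group_a,
    group_b,
    statistic: Callable | None = None,
    n_resamples: int = 999,
    seed: int | None = None,
    max_order: int | None = None,
    edge_inclusion_threshold: float = 0.95,
    adjust: str | None = None,
) -> PermutationResult:
    """Label-permutation test between two groups of networks.

    ``statistic(group_a, group_b) -> array`` defaults to
    :func:`consensus_statistic` with the given ``max_order`` (required in
    that case) and threshold.  Null resamples reassign networks to
    groups uniformly at random without replacement, preserving group
    sizes.  Larger statistic = larger group difference (one-sided on the
    absolute-difference statistic, i.e. a two-sided test on the
    underlying difference).

    ``adjust="bh"`` applies a Benjamini–Hochberg correction across all
    (series, q) cells; default is unadjusted per-cell p-values.
    """
    nets_a = _as_networks(group_a)
    nets_b = _as_networks(group_b)
    if len(nets_a) + len(nets_b) < 2:
        raise ValueError("need at least two networks in total")
    if n_resamples < 1:
        raise ValueError(f"n_resamples must be ≥ 1, got {n_resamples}")

    series_names: list[str] | None = None
    if statistic is None:
        if max_order is None:
            raise ValueError("max_order is required with the default consensus statistic")
        series_names = list(SERIES_NAMES)

        def statistic(a, b):  # noqa: F811 - deliberate default binding
            return consensus_statistic(
                a, b, max_order=max_order,
                edge_inclusion_threshold=edge_inclusion_threshold,
            )

    observed = np.asarray(statistic(nets_a, nets_b), dtype=float)
    pooled = nets_a + nets_b
    n_a = len(nets_a)
    rng = np.random.default_rng(seed)
    exceed = np.zeros_like(observed)
    for _ in range(n_resamples):
        perm = rng.permutation(len(pooled))
        perm_a = [pooled[i] for i in perm[:n_a]]
        perm_b = [pooled[i] for i in perm[n_a:]]
        s = np.asarray(statistic(perm_a, perm_b), dtype=float)
        exceed += s >= observed
    p = (1.0 + exceed) / (1.0 + n_resamples)

    if adjust is not None:
        if adjust != "bh":
            raise ValueError(f"unknown adjustment {adjust!r}; supported: 'bh'")
        from statsmodels.stats.multitest import multipletests

        flat = p.ravel()
        p = multipletests(flat, method="fdr_bh")[1].reshape(p.shape)

    return PermutationResult(
        observed=observed,
        p_values=p,
        n_resamples=n_resamples,
        seed=seed,
        series_names=series_names,
    )
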