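"""File ingestion and result serialization.

Three plain-text input formats are supported:

* simplex list — one simplex per line, whitespace-separated vertex
  labels, ``#`` comments and blank lines ignored;
* adjacency matrix — numeric CSV or whitespace-delimited square matrix,
  optionally with a header row and/or label column;
* edge list — 2- or 3-column TSV (source, target, optional weight),
  undirected.

Parse failures name the offending line.  Outputs (tidy tables, component
labelings) are written as CSV elsewhere in the package; vertex labels
stay strings externally and map to contiguous integers internally.
"""

from __future__ import annotations

from pathlib import Path
from typing import Hashable

import numpy as np

__all__ = ["read_simplex_list", "read_adjacency", "read_edge_list"]


def read_simplex_list(path: str | Path) -> list[list[str]]:
    """Read a simplex-list file into a list of label records."""
    records: list[list[str]] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        records.append(stripped.split())
    if not records:
        raise ValueError(f"{path}: no simplices found")
    return records


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def read_adjacency(path: str | Path) -> tuple[np.ndarray, list[str] | None]:
    """Read a square symmetric adjacency matrix, with optional labels.

    Returns ``(matrix, labels)`` where labels come from a header
    row/column when present, else None.  Ragged rows, non-square shape
    and asymmetry are errors that name the offending line.
    """
    path = Path(path)
    lines = [
        (i, ln.strip())
        for i, ln in enumerate(path.read_text().splitlines(), start=1)
        if ln.strip() and not ln.strip().startswith("#")
    ]
    if not lines:
        raise ValueError(f"{path}: empty matrix file")
    delimiter = "," if "," in lines[0][1] else None
    rows = [(i, [t.strip() for t in ln.split(delimiter)]) for i, ln in lines]

    labels: list[str] | None = None
    # header row: any non-numeric token in the first row
    if any(not _is_number(t) for t in rows[0][1] if t):
        header = [t for t in rows[0][1] if t]
        rows = rows[1:]
        if not rows:
            raise ValueError(f"{path}: header without data rows")
        # header may carry a leading corner cell over a label column
        labels = header
    # label column: first token of a data row non-numeric
    has_label_col = any(not _is_number(r[0]) for _, r in rows)
    data = []
    row_labels = []
    for lineno, tokens in rows:
        if has_label_col:
            row_labels.append(tokens[0])
            tokens = tokens[1:]
        try:
            data.append([float(t) for t in tokens])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-numeric entry ({exc})") from None
    widths = {len(r) for r in data}
    if len(widths) != 1:
        raise ValueError(f"{path}: ragged rows (widths {sorted(widths)})")
    mat = np.array(data)
    if mat.shape[0] != mat.shape[1]:
        raise ValueError(f"{path}: matrix is {mat.shape[0]}×{mat.shape[1]}, not square")
    if not np.allclose(mat, mat.T):
        i, j = np.argwhere(~np.isclose(mat, mat.T))[0]
        raise ValueError(
            f"{path}: asymmetric at entries ({i + 1},{j + 1})/({j + 1},{i + 1})"
        )
    if has_label_col:
        labels = row_labels
    elif labels is not None and len(labels) == mat.shape[0] + 1:
        labels = labels[1:]
    if labels is not None and len(labels) != mat.shape[0]:
        raise ValueError(
            f"{path}: {len(labels)} labels for a {mat.shape[0]}-node matrix"
        )
    return mat, labels


def read_edge_list(path: str | Path) -> tuple[np.ndarray, list[str]]:
    """Read an undirected 2/3-column TSV edge list to adjacency + labels."""
    path = Path(path)
    edges: list[tuple[str, str, float]] = []
    labels: list[str] = []
    index: dict[Hashable, int] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        parts = stripped.split("\t") if "\t" in stripped else stripped.split()
        if len(parts) not in (2, 3):
            raise ValueError(
                f"{path}:{lineno}: expected 2 or 3 columns, got {len(parts)}"
            )
        w = float(parts[2]) if len(parts) == 3 else 1.0
        for lab in parts[:2]:
            if lab not in index:
                index[lab] = len(labels)
                labels.append(lab)
        edges.append((parts[0], parts[1], w))
    if not edges:
        raise ValueError(f"{path}: no edges found")
    n = len(labels)
    adj = np.zeros((n, n))
    for u, v, w in edges:
        i, j = index[u], index[v]
        adj[i, j] = w
        adj[j, i] = w
    return adj, labels
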