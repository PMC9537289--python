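"""Containers, validation and text I/O for weighted network layers and multiplexes.

A *layer* is an undirected, non-negative weighted network on ``N`` nodes stored
as a dense symmetric matrix with zero diagonal and (by default) weights
normalised to ``[0, 1]``.  A *multiplex* is an ordered sequence of layers that
share one node set; layers interact only through shared node identity — there
are no explicit interlayer edges.

File formats
------------
Dense matrix
    CSV or TSV, ``N`` rows by ``N`` columns, full matrix (not a triangle).
    Comma or tab delimiter is auto-detected; lines starting with ``#`` are
    ignored; no header row by default.
Edge list
    Whitespace-delimited ``i j w`` triples, 0-based node indices, undirected,
    each unordered pair listed once (a duplicate with equal weight is
    tolerated; unequal duplicates are an error).
"""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: entries below this magnitude are treated as exact zeros for topology/density
ZERO_TOL = 1e-15
#: tolerance for symmetry / bound validation
SYM_TOL = 1e-10
_BOUND_SLACK = 1e-12


class LayerMatrix:
    """One undirected network layer.

    Parameters
    ----------
    weights : (N, N) array_like
        Symmetric, non-negative, zero-diagonal weight matrix.  Weights must
        lie in ``[0, 1]`` unless ``allow_unnormalised=True`` (raw matrices
        prior to degree normalisation).
    node_labels : sequence of str, optional
        One identifier per node.
    allow_unnormalised : bool
        Permit weights above 1 (still non-negative).

    Raises
    ------
    ValueError
        On non-square, asymmetric, negative, NaN, out-of-range or
        nonzero-diagonal input.
    """

    def __init__(
        self,
        weights,
        node_labels: Sequence[str] | None = None,
        allow_unnormalised: bool = False,
    ) -> None:
        w = np.array(weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError(f"weights must be a square matrix, got shape {w.shape}")
        if np.isnan(w).any():
            raise ValueError("weights contain NaN entries")
        if not np.isfinite(w).all():
            raise ValueError("weights contain non-finite entries")
        if not np.allclose(w, w.T, rtol=0.0, atol=SYM_TOL):
            raise ValueError("weights matrix is not symmetric")
        if w.size and w.min() < -SYM_TOL:
            raise ValueError(f"negative weight found: {w.min()}")
        if not allow_unnormalised and w.size and w.max() > 1.0 + SYM_TOL:
            raise ValueError(
                f"weight {w.max()} exceeds 1; pass allow_unnormalised=True for raw matrices"
            )
        d = np.abs(np.diagonal(w))
        if d.size and d.max() > SYM_TOL:
            raise ValueError("diagonal entries must be zero")
        # canonicalise: exact symmetry, exact bounds, floating dust -> exact 0
        w = 0.5 * (w + w.T)
        w[np.abs(w) < ZERO_TOL] = 0.0
        np.clip(w, 0.0, None if allow_unnormalised else 1.0, out=w)
        np.fill_diagonal(w, 0.0)
        if node_labels is not None:
            node_labels = list(node_labels)
            if len(node_labels) != w.shape[0]:
                raise ValueError("node_labels length does not match matrix size")
        self.weights = w
        self.node_labels = node_labels
        self.allow_unnormalised = allow_unnormalised

    # -- basic protocol ------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    def __len__(self) -> int:
        return self.n_nodes

    def __eq__(self, other) -> bool:
        return isinstance(other, LayerMatrix) and np.array_equal(
            self.weights, other.weights
        )

    def __repr__(self) -> str:
        return (
            f"LayerMatrix(n_nodes={self.n_nodes}, "
            f"n_edges={int(np.count_nonzero(np.triu(self.weights, 1)))})"
        )

    def is_binary(self) -> bool:
        w = self.weights
        return bool(np.all((w == 0.0) | (w == 1.0)))

    def copy(self) -> "LayerMatrix":
        return LayerMatrix(
            self.weights.copy(), self.node_labels, self.allow_unnormalised
        )


class MultiplexNetwork:
    """Ordered sequence of layers sharing a single node set.

    The two-layer structure/function multiplex used throughout the pipeline is
    the ``M = 2`` special case with layer 1 structural and layer 2 functional.
    """

    def __init__(
        self,
        layers: Sequence[LayerMatrix],
        layer_names: Sequence[str] | None = None,
    ) -> None:
        layers = list(layers)
        if len(layers) < 1:
            raise ValueError("a multiplex needs at least one layer")
        n = layers[0].n_nodes
        for k, layer in enumerate(layers):
            if layer.n_nodes != n:
                raise ValueError(
                    f"layer {k} has {layer.n_nodes} nodes, expected {n}"
                )
        if layer_names is None:
            layer_names = [f"layer{k + 1}" for k in range(len(layers))]
        layer_names = list(layer_names)
        if len(layer_names) != len(layers):
            raise ValueError("layer_names length does not match number of layers")
        self.layers = layers
        self.layer_names = layer_names

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    @property
    def n_nodes(self) -> int:
        return self.layers[0].n_nodes

    def __getitem__(self, k: int) -> LayerMatrix:
        return self.layers[k]


def strength(layer: LayerMatrix) -> np.ndarray:
    """Generalised degree (node strength): row sums of the weight matrix.

    For a binary layer this is the ordinary integer degree.
    """
    return layer.weights.sum(axis=1)


def density(layer: LayerMatrix) -> float:
    """Fraction of unordered node pairs joined by a nonzero weight."""
    n = layer.n_nodes
    if n < 2:
        raise ValueError("density undefined for fewer than 2 nodes")
    iu = np.triu_indices(n, k=1)
    vals = layer.weights[iu]
    return float(np.count_nonzero(np.abs(vals) >= ZERO_TOL) / vals.size)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

_FORMATS = ("dense-csv", "dense-tsv", "edge-list", "auto")


def _parse_rows(path: Path) -> list[list[str]]:
    rows = []
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "," in line:
            fields = [f.strip() for f in line.split(",")]
        else:
            fields = line.split()
        rows.append(fields)
    return rows


def read_layer(
    path,
    format: str = "auto",
    allow_unnormalised: bool = False,
    node_labels: Sequence[str] | None = None,
) -> LayerMatrix:
    """Read a layer from a dense matrix file or an undirected edge list.

    ``format='auto'`` treats a square numeric table as a dense matrix and a
    3-column table as an ``i j w`` edge list (a square 3x3 table is read as
    dense; pass ``format='edge-list'`` explicitly for 3-row edge lists).
    Nonzero diagonal entries are forced to zero with a logged warning.
    """
    path = Path(path)
    if format not in _FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {_FORMATS}")
    rows = _parse_rows(path)
    if not rows:
        raise ValueError(f"{path}: no data found")
    if format == "auto":
        if len(rows) == len(rows[0]):
            format = "dense-csv"
        elif all(len(r) == 3 for r in rows):
            format = "edge-list"
        else:
            raise ValueError(
                f"{path}: cannot auto-detect format "
                f"({len(rows)} rows x {len(rows[0])} columns)"
            )
    if format.startswith("dense"):
        try:
            w = np.array([[float(x) for x in r] for r in rows])
        except ValueError as exc:
            raise ValueError(f"{path}: non-numeric entry in dense matrix") from exc
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError(
                f"{path}: dense matrix is not square (shape {w.shape})"
            )
    else:
        w = _edges_to_matrix(rows, path)
    if np.abs(np.diagonal(w)).max(initial=0.0) > ZERO_TOL:
        logger.warning("%s: nonzero diagonal entries forced to zero", path)
        np.fill_diagonal(w, 0.0)
    return LayerMatrix(w, node_labels=node_labels, allow_unnormalised=allow_unnormalised)


def _edges_to_matrix(rows: list[list[str]], path: Path) -> np.ndarray:
    triples = []
    for r in rows:
        if len(r) != 3:
            raise ValueError(f"{path}: edge-list rows must be 'i j w' triples")
        i, j, w = int(r[0]), int(r[1]), float(r[2])
        if i < 0 or j < 0:
            raise ValueError(f"{path}: negative node index ({i}, {j})")
        triples.append((i, j, w))
    n = max(max(i, j) for i, j, _ in triples) + 1
    mat = np.zeros((n, n))
    seen: dict[tuple[int, int], float] = {}
    for i, j, w in triples:
        key = (min(i, j), max(i, j))
        if key in seen:
            if not math.isclose(seen[key], w, rel_tol=0.0, abs_tol=SYM_TOL):
                raise ValueError(
                    f"{path}: conflicting duplicate edge {key}: "
                    f"{seen[key]} vs {w}"
                )
            continue
        seen[key] = w
        mat[i, j] = w
        mat[j, i] = w
    return mat


def write_layer(layer: LayerMatrix, path, format: str = "dense-csv") -> None:
    """Write a layer; round-trips through :func:`read_layer` exactly."""
    path = Path(path)
    if format in ("dense-csv", "dense-tsv"):
        sep = "," if format == "dense-csv" else "\t"
        lines = [
            sep.join(repr(float(x)) for x in row) for row in layer.weights
        ]
    elif format == "edge-list":
        i_idx, j_idx = np.triu_indices(layer.n_nodes, k=1)
        lines = [
            f"{i} {j} {float(layer.weights[i, j])!r}"
            for i, j in zip(i_idx, j_idx)
            if layer.weights[i, j] != 0.0
        ]
    else:
        raise ValueError(f"unknown format {format!r}")
    path.write_text("\n".join(lines) + "\n")


def read_labels(path) -> list[str]:
    """Read a one-label-per-line sidecar file."""
    return [
        line.strip()
        for line in Path(path).read_text().splitlines()
        if line.strip()
    ]
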