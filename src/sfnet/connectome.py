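"""Structural-connectome preparation: normalisation, thresholding, binarisation.

A raw anatomical connectivity matrix (tract strengths, arbitrary scale) is
turned into up to three cortical representations:

1. *weighted* — degree-normalised ``W = D^{-1/2} A D^{-1/2}`` with
   ``D = diag(k_i)``, which bounds weights in ``[0, 1]`` and damps the
   influence of promiscuous high-strength nodes;
2. *weighted-topological* — the normalised matrix with all but the strongest
   fraction of connections (default 23%) set to zero, surviving weights kept;
3. *binary* — the thresholded matrix with surviving edges set to 1.

Variants 2 and 3 share the same support by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .netmodel import ZERO_TOL, LayerMatrix, strength

VARIANT_KINDS = ("weighted", "weighted-topological", "binary")

#: fraction of strongest connections retained by the default thresholding
DEFAULT_FRACTION = 0.23


@dataclass
class ConnectomeVariant:
    """One cortical representation of the structural connectome."""

    kind: str
    matrix: LayerMatrix
    retained_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in VARIANT_KINDS:
            raise ValueError(f"unknown variant kind {self.kind!r}")
        if not (0.0 < self.retained_fraction <= 1.0):
            raise ValueError("retained_fraction must lie in (0, 1]")
        if self.kind == "binary" and not self.matrix.is_binary():
            raise ValueError("binary variant must have {0,1} weights")


def normalize(raw: LayerMatrix) -> LayerMatrix:
    """Symmetric degree normalisation ``W = D^{-1/2} A D^{-1/2}``.

    Every node must have positive strength.  Entrywise this divides ``a_ij``
    by ``sqrt(k_i k_j)``, bounding all weights in ``[0, 1]`` for non-negative
    input (validated post hoc).
    """
    a = raw.weights
    k = strength(raw)
    if np.any(k <= 0.0):
        bad = np.flatnonzero(k <= 0.0)
        raise ValueError(f"nodes with zero strength cannot be normalised: {bad}")
    inv_sqrt = 1.0 / np.sqrt(k)
    w = a * np.outer(inv_sqrt, inv_sqrt)
    if w.max(initial=0.0) > 1.0 + 1e-12:
        raise ValueError(
            f"normalisation produced weight {w.max()} > 1; input is not a valid "
            "non-negative symmetric matrix"
        )
    return LayerMatrix(np.clip(w, 0.0, 1.0), node_labels=raw.node_labels)


def _ranked_pairs(w: np.ndarray) -> list[tuple[float, int, int]]:
    """Nonzero upper-triangle entries sorted by descending weight, then (i, j)."""
    i_idx, j_idx = np.triu_indices(w.shape[0], k=1)
    vals = w[i_idx, j_idx]
    keep = np.abs(vals) >= ZERO_TOL
    entries = [
        (float(v), int(i), int(j))
        for v, i, j in zip(vals[keep], i_idx[keep], j_idx[keep])
    ]
    entries.sort(key=lambda e: (-e[0], e[1], e[2]))
    return entries


def threshold_topweights(
    w: LayerMatrix, fraction: float, base: str = "nonzero"
) -> LayerMatrix:
    """Keep only the strongest fraction of connections, preserving weights.

    The retained count is ``ceil(fraction * E)`` where ``E`` is, by default,
    the number of nonzero unordered pairs (``base='nonzero'``); with
    ``base='all-pairs'`` it is ``N (N - 1) / 2``.  Ties at the cut weight are
    resolved in lexicographic ``(i, j)`` order and the retained count is
    exact.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must lie in (0, 1]")
    if base not in ("nonzero", "all-pairs"):
        raise ValueError(f"unknown base {base!r}")
    entries = _ranked_pairs(w.weights)
    n = w.n_nodes
    pool = len(entries) if base == "nonzero" else n * (n - 1) // 2
    m = min(math.ceil(fraction * pool), len(entries))
    out = np.zeros_like(w.weights)
    for v, i, j in entries[:m]:
        out[i, j] = v
        out[j, i] = v
    return LayerMatrix(out, node_labels=w.node_labels,
                       allow_unnormalised=w.allow_unnormalised)


def binarise(w: LayerMatrix) -> LayerMatrix:
    """Map every surviving edge weight to 1, preserving the support."""
    out = (np.abs(w.weights) >= ZERO_TOL).astype(float)
    np.fill_diagonal(out, 0.0)
    return LayerMatrix(out, node_labels=w.node_labels)


def make_variants(
    raw: LayerMatrix, fraction: float = DEFAULT_FRACTION, base: str = "nonzero"
) -> dict[str, ConnectomeVariant]:
    """Build the three cortical representations from a raw connectome.

    Pipeline: normalise, then threshold the normalised matrix, then binarise
    the thresholded one.  Returns a dict keyed by variant kind.
    """
    weighted = normalize(raw)
    topological = threshold_topweights(weighted, fraction, base=base)
    binary = binarise(topological)
    return {
        "weighted": ConnectomeVariant("weighted", weighted, 1.0),
        "weighted-topological": ConnectomeVariant(
            "weighted-topological", topological, fraction
        ),
        "binary": ConnectomeVariant("binary", binary, fraction),
    }
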