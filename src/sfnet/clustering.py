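"""Clustering coefficients and similarity for weighted multiplex networks.

All per-node measures share one algebraic pattern: a triangle-type numerator,
read off the diagonal of a product of weight matrices, over a tuple-type
denominator built from node strengths.  With weights in ``[0, 1]`` every
measure lies in ``[0, 1]`` and reduces exactly to its binary counterpart on
``{0, 1}`` weights.

Measures
--------
``clustering_binary``
    Classic local clustering ``(A^3)_ii / [k_i (k_i - 1)]`` — the fraction of
    ordered neighbour pairs of ``i`` that are themselves connected.
``clustering_weighted``
    ``(W^3)_ii / (k_i^2 - (W^2)_ii)`` with ``k_i`` the node strength.
``clustering_multiplex_weighted``
    Multi-layer generalisation: triangles whose two wing edges live in one
    layer and whose closing edge lives in a *different* layer, normalised by
    per-layer tuple strength and the number of layer pairs.
``sf_clustering_binary`` / ``sf_clustering_weighted``
    Structure-function clustering: structural tuples centred on ``i`` that are
    closed by a functional edge where *no* structural edge exists — the
    functional connectivity that emerges between anatomically unconnected
    regions.
``jaccard_weighted``
    Ruzicka (weighted Jaccard) overlap ``sum(min) / sum(max)`` of two weight
    matrices.

Nodes whose denominator is numerically degenerate (isolated nodes, degree 1,
or a fully clustered structural neighbourhood in the SF measures) receive a
coefficient of 0 and are included in the node average.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .netmodel import LayerMatrix, MultiplexNetwork

#: denominators at or below this value are treated as degenerate -> 0
DEGENERATE_TOL = 1e-12

_MEASURES = ("binary", "weighted", "weighted-multiplex", "sf-binary", "sf-weighted")


@dataclass
class ClusteringResult:
    """Per-node clustering values plus their node average."""

    per_node: np.ndarray
    measure_name: str
    mean: float = field(init=False)

    def __post_init__(self) -> None:
        self.per_node = np.asarray(self.per_node, dtype=float)
        if self.measure_name not in _MEASURES:
            raise ValueError(f"unknown measure name {self.measure_name!r}")
        self.mean = float(self.per_node.mean()) if self.per_node.size else 0.0


def average(result: ClusteringResult) -> float:
    """Node average of a clustering result (degenerate-zero nodes included)."""
    return float(np.asarray(result.per_node).mean())


def _safe_ratio(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    out = np.zeros_like(num, dtype=float)
    ok = den > DEGENERATE_TOL
    out[ok] = num[ok] / den[ok]
    # clip floating dust straddling the exact bounds
    return np.clip(out, 0.0, 1.0)


def _check_binary(layer: LayerMatrix, name: str) -> None:
    if not layer.is_binary():
        raise ValueError(f"{name} requires binary {{0,1}} weights")


def _triple_diag(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Diagonal of ``a @ b @ c`` without forming the full product."""
    return np.einsum("ij,jk,ki->i", a, b, c, optimize=True)


def clustering_binary(layer: LayerMatrix) -> ClusteringResult:
    """Local clustering coefficient of a binary layer."""
    _check_binary(layer, "clustering_binary")
    a = layer.weights
    k = a.sum(axis=1)
    num = _triple_diag(a, a, a)
    den = k * (k - 1.0)
    return ClusteringResult(_safe_ratio(num, den), "binary")


def clustering_weighted(layer: LayerMatrix) -> ClusteringResult:
    """Weighted local clustering; equals ``clustering_binary`` on binary input."""
    w = layer.weights
    k = w.sum(axis=1)
    num = _triple_diag(w, w, w)
    den = k**2 - np.einsum("ij,ji->i", w, w)
    return ClusteringResult(_safe_ratio(num, den), "weighted")


def clustering_multiplex_weighted(mx: MultiplexNetwork) -> ClusteringResult:
    """Weighted multiplex clustering over all ordered pairs of distinct layers.

    Numerator: two wing edges in layer ``alpha`` closed by an edge in layer
    ``alpha' != alpha``.  Denominator: ``(M - 1)`` times the summed per-layer
    tuple strength ``k_i^2 - (W^2)_ii``.
    """
    m = mx.n_layers
    if m < 2:
        raise ValueError("multiplex clustering needs at least 2 layers")
    mats = [layer.weights for layer in mx.layers]
    num = np.zeros(mx.n_nodes)
    den = np.zeros(mx.n_nodes)
    for a_idx, wa in enumerate(mats):
        ka = wa.sum(axis=1)
        den += ka**2 - np.einsum("ij,ji->i", wa, wa)
        for b_idx, wb in enumerate(mats):
            if b_idx == a_idx:
                continue
            num += _triple_diag(wa, wb, wa)
    den *= m - 1.0
    return ClusteringResult(_safe_ratio(num, den), "weighted-multiplex")


def sf_clustering_binary(
    structural: LayerMatrix, functional: LayerMatrix
) -> ClusteringResult:
    """Binary structure-function clustering.

    Counts structural tuples centred on each node closed by a functional —
    but not structural — edge, over structural tuples not already closed
    structurally.
    """
    _check_binary(structural, "sf_clustering_binary")
    _check_binary(functional, "sf_clustering_binary")
    a1, a2 = _check_same_shape(structural, functional)
    k = a1.sum(axis=1)
    inner = a2 * (1.0 - a1)
    num = _triple_diag(a1, inner, a1)
    c1 = clustering_binary(structural).per_node
    den = k * (k - 1.0) * (1.0 - c1)
    return ClusteringResult(_safe_ratio(num, den), "sf-binary")


def sf_clustering_weighted(
    structural: LayerMatrix, functional: LayerMatrix
) -> ClusteringResult:
    """Weighted structure-function clustering.

    Equals :func:`sf_clustering_binary` exactly on binary inputs.
    """
    w1, w2 = _check_same_shape(structural, functional)
    k = w1.sum(axis=1)
    inner = w2 * (1.0 - w1)
    num = _triple_diag(w1, inner, w1)
    cw1 = clustering_weighted(structural).per_node
    den = (k**2 - np.einsum("ij,ji->i", w1, w1)) * (1.0 - cw1)
    return ClusteringResult(_safe_ratio(num, den), "sf-weighted")


def _check_same_shape(a: LayerMatrix, b: LayerMatrix) -> tuple[np.ndarray, np.ndarray]:
    if a.n_nodes != b.n_nodes:
        raise ValueError(
            f"layer size mismatch: {a.n_nodes} vs {b.n_nodes} nodes"
        )
    return a.weights, b.weights


def jaccard_weighted(
    a: LayerMatrix, b: LayerMatrix, variant: str = "ratio-of-sums"
) -> float:
    """Weighted Jaccard (Ruzicka) similarity of two layers.

    ``ratio-of-sums`` (default) returns ``sum(min) / sum(max)`` over all
    entries; it lies in ``[0, 1]``, equals 1 iff the matrices are identical,
    0 iff their supports are disjoint, and reduces to the edge-set Jaccard
    index on binary input.  ``sum-of-ratios`` is the literal per-entry
    ``min/max`` sum (with 0/0 terms contributing 0), kept for auditability;
    it is *not* bounded by 1.
    """
    wa, wb = _check_same_shape(a, b)
    mins = np.minimum(wa, wb)
    maxs = np.maximum(wa, wb)
    total_max = maxs.sum()
    if total_max <= 0.0:
        raise ValueError("Jaccard undefined: both matrices are all-zero")
    if variant == "ratio-of-sums":
        return float(mins.sum() / total_max)
    if variant == "sum-of-ratios":
        ok = maxs > 0.0
        return float((mins[ok] / maxs[ok]).sum())
    raise ValueError(f"unknown variant {variant!r}")
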