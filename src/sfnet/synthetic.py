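"""Synthetic structural connectomes and degree-preserving null models.

The generator emulates the statistical shape of a DTI-derived cortical
connectivity matrix: symmetric, non-negative, zero diagonal, heavy-tailed
(log-normal) positive weights, and a modular block structure with two
hemisphere-like communities that are denser within than between.  It is a
synthetic stand-in for empirical tractography data, not a biophysical model
of it.

Null models:

``maslov_sneppen``
    Classic degree-preserving randomisation of a binary network by repeated
    double-edge swaps.
``weighted_rewire``
    Weighted variant: the support is randomised by Maslov-Sneppen swaps and
    the original multiset of edge weights is redistributed over the new
    support, preserving the binary degree sequence and the global weight
    distribution exactly (node strengths are generally *not* preserved).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from . import funconn
from .connectome import ConnectomeVariant
from .dynamics import SimulationConfig, WCParameters, coupling_strength, simulate
from .netmodel import LayerMatrix, MultiplexNetwork, density

logger = logging.getLogger(__name__)

_MAX_RETRIES = 50


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic-connectome generator.

    Defaults target the empirical regime studied by the pipeline: 78
    cortical regions in two hemisphere-like blocks, overall density between
    the between- and within-block densities, log-normal weights.
    """

    N: int = 78
    n_blocks: int = 2
    within_block_density: float = 0.35
    between_block_density: float = 0.10
    weight_distribution: str = "lognormal"
    lognormal_mu: float = 0.0
    lognormal_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N < 4:
            raise ValueError("N must be at least 4")
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be at least 1")
        for name in ("within_block_density", "between_block_density"):
            val = getattr(self, name)
            if not (0.0 < val <= 1.0):
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.weight_distribution not in ("lognormal", "uniform"):
            raise ValueError(
                f"unknown weight_distribution {self.weight_distribution!r}"
            )


def _block_of(spec: SyntheticSpec) -> np.ndarray:
    return np.arange(spec.N) * spec.n_blocks // spec.N


def generate_sc(spec: SyntheticSpec) -> LayerMatrix:
    """Draw a connected synthetic structural connectome (raw, unnormalised).

    Deterministic per seed; resampled (bounded retries) until connected.
    """
    rng = np.random.default_rng(spec.seed)
    blocks = _block_of(spec)
    n = spec.N
    iu = np.triu_indices(n, k=1)
    same_block = blocks[iu[0]] == blocks[iu[1]]
    p_edge = np.where(
        same_block, spec.within_block_density, spec.between_block_density
    )
    for _ in range(_MAX_RETRIES):
        present = rng.random(p_edge.size) < p_edge
        if spec.weight_distribution == "lognormal":
            weights = rng.lognormal(
                spec.lognormal_mu, spec.lognormal_sigma, p_edge.size
            )
        else:
            weights = rng.random(p_edge.size)
        vals = np.where(present, weights, 0.0)
        mat = np.zeros((n, n))
        mat[iu] = vals
        mat = mat + mat.T
        n_comp, _ = connected_components(csr_matrix(mat != 0.0), directed=False)
        if n_comp == 1:
            return LayerMatrix(mat, allow_unnormalised=True)
    raise RuntimeError(
        f"could not generate a connected network in {_MAX_RETRIES} attempts"
    )


def _edges_of(layer: LayerMatrix) -> list[tuple[int, int]]:
    i_idx, j_idx = np.nonzero(np.triu(layer.weights, 1))
    return list(zip(i_idx.tolist(), j_idx.tolist()))


def maslov_sneppen(
    binary_layer: LayerMatrix, n_swaps_per_edge: int = 10, seed: int = 0
) -> LayerMatrix:
    """Degree-preserving randomisation of a binary layer by double-edge swaps.

    Attempts ``n_swaps_per_edge * E`` swaps; a proposed swap is rejected (and
    counted) if it would create a self-loop or a multi-edge.  The degree
    sequence of every node is preserved exactly.
    """
    if not binary_layer.is_binary():
        raise ValueError("maslov_sneppen requires a binary layer")
    edges = _edges_of(binary_layer)
    n_edges = len(edges)
    if n_edges < 2:
        raise ValueError("need at least 2 edges to rewire")
    edge_set = set(edges)
    rng = np.random.default_rng(seed)
    attempts = n_swaps_per_edge * n_edges
    rejected = 0
    for _ in range(attempts):
        e1, e2 = rng.integers(0, n_edges, size=2)
        if e1 == e2:
            rejected += 1
            continue
        a, b = edges[e1]
        c, d = edges[e2]
        if rng.random() < 0.5:
            c, d = d, c
        # propose (a, d) and (c, b)
        if a == d or c == b:
            rejected += 1
            continue
        new1 = (min(a, d), max(a, d))
        new2 = (min(c, b), max(c, b))
        if new1 in edge_set or new2 in edge_set or new1 == new2:
            rejected += 1
            continue
        edge_set.discard((min(a, b), max(a, b)))
        edge_set.discard((min(c, d), max(c, d)))
        edge_set.add(new1)
        edge_set.add(new2)
        edges[e1] = new1
        edges[e2] = new2
    logger.info(
        "maslov_sneppen: %d/%d swap attempts rejected", rejected, attempts
    )
    n = binary_layer.n_nodes
    out = np.zeros((n, n))
    for i, j in edge_set:
        out[i, j] = 1.0
        out[j, i] = 1.0
    return LayerMatrix(out, node_labels=binary_layer.node_labels)


def weighted_rewire(
    layer: LayerMatrix, n_swaps_per_edge: int = 10, seed: int = 0
) -> LayerMatrix:
    """Randomise topology on the support, then shuffle the weight multiset.

    Preserves exactly the binary degree sequence (via Maslov-Sneppen swaps on
    the support) and the global multiset of edge weights (redistributed over
    the rewired support by a seeded permutation).  Node strengths are
    generally not preserved.
    """
    w = layer.weights
    support = LayerMatrix((np.abs(w) > 0).astype(float))
    rewired = maslov_sneppen(support, n_swaps_per_edge=n_swaps_per_edge, seed=seed)
    weights = w[np.nonzero(np.triu(w, 1))]
    rng = np.random.default_rng(seed + 1)
    shuffled = rng.permutation(weights)
    new_edges = sorted(_edges_of(rewired))
    n = layer.n_nodes
    out = np.zeros((n, n))
    for (i, j), wt in zip(new_edges, shuffled):
        out[i, j] = wt
        out[j, i] = wt
    return LayerMatrix(
        out, node_labels=layer.node_labels,
        allow_unnormalised=layer.allow_unnormalised,
    )


def randomise_variant(
    sc_variant: ConnectomeVariant, n_swaps_per_edge: int = 10, seed: int = 0
) -> ConnectomeVariant:
    """Randomise a cortical representation with the null model matching its kind."""
    if sc_variant.kind == "binary":
        rand = maslov_sneppen(sc_variant.matrix, n_swaps_per_edge, seed)
    else:
        rand = weighted_rewire(sc_variant.matrix, n_swaps_per_edge, seed)
    return ConnectomeVariant(sc_variant.kind, rand, sc_variant.retained_fraction)


def build_null_multiplex(
    sc_variant: ConnectomeVariant,
    params: WCParameters,
    config: SimulationConfig,
    n_swaps_per_edge: int = 10,
    seed: int = 0,
) -> MultiplexNetwork:
    """Two-layer null multiplex: randomised structure plus FC simulated on it.

    Layer 1 is the randomised structural layer (null model chosen by variant
    kind); layer 2 is the functional layer obtained by simulating the neural
    dynamics *on the randomised structure* and density-matching the
    correlations to it.
    """
    null_variant = randomise_variant(sc_variant, n_swaps_per_edge, seed)
    params = params.replace(epsilon=coupling_strength(null_variant))
    traj = simulate(null_variant.matrix, params, config)
    fc = funconn.functional_layer(
        traj,
        target_density=density(null_variant.matrix),
        burn_in=config.burn_in,
        binarise=(sc_variant.kind == "binary"),
    )
    return MultiplexNetwork(
        [null_variant.matrix, fc.thresholded],
        layer_names=["structural-null", "functional"],
    )
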