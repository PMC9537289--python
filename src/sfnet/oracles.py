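"""Exhaustive enumeration oracles for every clustering/similarity measure.

Each function evaluates the defining double (or triple) sum over ordered node
triples — and ordered layer pairs for the multiplex measure — with explicit
loops, deliberately avoiding the matrix-product formulation used by
:mod:`sfnet.clustering`.  They exist as an independent cross-check: the test
suite and the ``cluster --oracle`` CLI flag compare the two routes entry by
entry.
"""

from __future__ import annotations

import numpy as np

from ._compat import njit
from .clustering import DEGENERATE_TOL


@njit(cache=True)
def _clustering_weighted_loops(w: np.ndarray) -> np.ndarray:
    n = w.shape[0]
    out = np.zeros(n)
    for i in range(n):
        num = 0.0
        den = 0.0
        for j in range(n):
            for k in range(n):
                if k == j:
                    continue
                num += w[i, j] * w[j, k] * w[k, i]
                den += w[i, j] * w[k, i]
        if den > DEGENERATE_TOL:
            out[i] = num / den
    return out


@njit(cache=True)
def _multiplex_loops(ws: np.ndarray) -> np.ndarray:
    m, n, _ = ws.shape
    out = np.zeros(n)
    for i in range(n):
        num = 0.0
        den = 0.0
        for a in range(m):
            for b in range(m):
                if b == a:
                    continue
                for j in range(n):
                    for k in range(n):
                        num += ws[a, i, j] * ws[b, j, k] * ws[a, k, i]
        for a in range(m):
            for j in range(n):
                for k in range(n):
                    if k == j:
                        continue
                    den += ws[a, i, j] * ws[a, k, i]
        den *= m - 1.0
        if den > DEGENERATE_TOL:
            out[i] = num / den
    return out


@njit(cache=True)
def _sf_loops(w1: np.ndarray, w2: np.ndarray) -> np.ndarray:
    # literal double sum of the structure-function definition: numerator and
    # denominator both carry the (1 - w1_jk) no-structural-closure factor
    n = w1.shape[0]
    out = np.zeros(n)
    for i in range(n):
        num = 0.0
        den = 0.0
        for j in range(n):
            for k in range(n):
                if k == j:
                    continue
                open_f = 1.0 - w1[j, k]
                num += w1[i, j] * w2[j, k] * w1[k, i] * open_f
                den += w1[i, j] * w1[k, i] * open_f
        if den > DEGENERATE_TOL:
            out[i] = num / den
    return out


def clustering_weighted_oracle(weights: np.ndarray) -> np.ndarray:
    """Per-node weighted clustering by brute-force ordered-triple enumeration."""
    return _clustering_weighted_loops(np.ascontiguousarray(weights, dtype=float))


def clustering_binary_oracle(weights: np.ndarray) -> np.ndarray:
    """Per-node binary clustering: closed ordered triples over ordered pairs."""
    return _clustering_weighted_loops(np.ascontiguousarray(weights, dtype=float))


def clustering_multiplex_oracle(layer_stack: np.ndarray) -> np.ndarray:
    """Multiplex clustering by enumerating ordered triples and layer pairs.

    ``layer_stack`` has shape ``(M, N, N)``.
    """
    return _multiplex_loops(np.ascontiguousarray(layer_stack, dtype=float))


def sf_clustering_oracle(structural: np.ndarray, functional: np.ndarray) -> np.ndarray:
    """Structure-function clustering by direct evaluation of its double sum."""
    return _sf_loops(
        np.ascontiguousarray(structural, dtype=float),
        np.ascontiguousarray(functional, dtype=float),
    )


def jaccard_oracle(a: np.ndarray, b: np.ndarray) -> float:
    """Weighted Jaccard by explicit entrywise min/max accumulation."""
    num = 0.0
    den = 0.0
    for i in range(a.shape[0]):
        for j in range(a.shape[1]):
            num += min(a[i, j], b[i, j])
            den += max(a[i, j], b[i, j])
    if den <= 0.0:
        raise ValueError("Jaccard undefined: both matrices are all-zero")
    return num / den
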