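"""Functional connectivity from simulated activity.

FC is the matrix of Pearson correlations between per-region excitatory time
series (post burn-in), thresholded so that its edge density matches that of
the structural network used in the simulation; matched to a binary
structural network, surviving entries are additionally set to one.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .dynamics import Trajectory
from .netmodel import LayerMatrix

logger = logging.getLogger(__name__)


@dataclass
class FCMatrix:
    """Raw correlation matrix plus its density-matched thresholded layer."""

    raw_correlations: np.ndarray
    thresholded: LayerMatrix
    target_density: float


def pearson_fc(traj: Trajectory, burn_in: float = 1000.0) -> np.ndarray:
    """Pairwise Pearson correlation of excitatory series with ``t >= burn_in``.

    Returns a symmetric matrix with unit diagonal.  Nodes with zero variance
    after burn-in are reported with a warning and get zero off-diagonal
    correlations.
    """
    keep = traj.times >= burn_in
    if keep.sum() < 2:
        raise ValueError(
            f"trajectory has {int(keep.sum())} samples at t >= {burn_in}; "
            "need at least 2"
        )
    data = traj.u[:, keep]
    sd = data.std(axis=1)
    # rounding dust in a constant series still yields sd ~ 1e-17 * |mean|
    degenerate = np.flatnonzero(
        sd <= 1e-12 * np.maximum(1.0, np.abs(data.mean(axis=1)))
    )
    if degenerate.size:
        logger.warning(
            "zero-variance nodes in FC estimation: %s", degenerate.tolist()
        )
        data = data.copy()
        # give flat nodes unit variance noiseless placeholder to avoid 0/0,
        # then zero their correlations explicitly below
        data[degenerate] += np.arange(data.shape[1]) * 1e-9
    corr = np.corrcoef(data)
    corr = np.clip(0.5 * (corr + corr.T), -1.0, 1.0)
    for i in degenerate:
        corr[i, :] = 0.0
        corr[:, i] = 0.0
    np.fill_diagonal(corr, 1.0)
    return corr


def fc_to_layer(
    raw: np.ndarray,
    target_density: float,
    binarise: bool = False,
    ranking: str = "signed",
) -> LayerMatrix:
    """Threshold a correlation matrix to a target edge density.

    The diagonal is removed first, then the strongest
    ``ceil(target_density * N(N-1)/2)`` unordered pairs by ``ranking``
    (``'signed'``: largest correlation first; ``'absolute'``: largest
    magnitude first) are retained with ties broken in lexicographic
    ``(i, j)`` order.  Surviving weights are the correlation values clipped
    to ``[0, 1]`` (surviving negatives are clipped to 0 and logged);
    ``binarise`` maps survivors to 1.
    """
    if not (0.0 < target_density <= 1.0):
        raise ValueError("target_density must lie in (0, 1]")
    if ranking not in ("signed", "absolute"):
        raise ValueError(f"unknown ranking {ranking!r}")
    c = np.asarray(raw, dtype=float)
    n = c.shape[0]
    i_idx, j_idx = np.triu_indices(n, k=1)
    vals = c[i_idx, j_idx]
    m = math.ceil(target_density * vals.size)
    if m < 1:
        raise ValueError("target_density yields zero edges")
    key = -vals if ranking == "signed" else -np.abs(vals)
    order = np.lexsort((j_idx, i_idx, key))[:m]
    out = np.zeros((n, n))
    kept = vals[order]
    negatives = int((kept < 0.0).sum())
    if negatives:
        logger.warning(
            "%d surviving FC entries were negative and clipped to 0", negatives
        )
    w = np.clip(kept, 0.0, 1.0)
    if binarise:
        w = np.ones_like(w)
    out[i_idx[order], j_idx[order]] = w
    out[j_idx[order], i_idx[order]] = w
    return LayerMatrix(out)


def functional_layer(
    traj: Trajectory,
    target_density: float,
    burn_in: float = 1000.0,
    binarise: bool = False,
    ranking: str = "signed",
) -> FCMatrix:
    """Convenience wrapper: correlation estimation plus density matching."""
    raw = pearson_fc(traj, burn_in=burn_in)
    layer = fc_to_layer(raw, target_density, binarise=binarise, ranking=ranking)
    return FCMatrix(raw, layer, target_density)
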