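"""End-to-end experiment orchestration.

For a structural representation and a grid of basal inputs ``(P, Q)`` the
sweep simulates the neural dynamics at every cell (several stochastic
realisations, each with fresh initial conditions and noise), derives the
density-matched functional layer, assembles the two-layer structure/function
multiplex and records the weighted Jaccard similarity and the node-averaged
weighted structure-function clustering, together with across-realisation
dispersion statistics and a bifurcation overlay.

Seeding: the seed of realisation ``r`` at grid cell ``(pi, qi)`` is derived
from ``(base_seed, pi, qi, r)`` through ``numpy.random.SeedSequence``, so
results are independent of execution order and sweeps are resumable (a
completed cell is cached on disk, keyed by a hash of the full configuration).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.spatial.distance import cdist
from scipy.stats import mannwhitneyu

from .bifurcation import (
    BifurcationSet,
    StabilityMap,
    network_stability_map,
    single_node_bifurcation_sets,
)
from .clustering import jaccard_weighted, sf_clustering_weighted
from .connectome import ConnectomeVariant
from .dynamics import (
    SimulationConfig,
    SimulationError,
    WCParameters,
    coupling_strength,
    simulate,
)
from .funconn import functional_layer
from .netmodel import LayerMatrix, density

logger = logging.getLogger(__name__)


def cell_seed(base_seed: int, p_index: int, q_index: int, realisation: int) -> int:
    """Deterministic, execution-order-independent per-realisation seed."""
    ss = np.random.SeedSequence(
        base_seed, spawn_key=(p_index, q_index, realisation)
    )
    return int(ss.generate_state(1)[0] % (2**31))


def _dispersion(values: np.ndarray) -> tuple[float, float, float]:
    """(sd, relative sd, max relative deviation) of a sample."""
    values = np.asarray(values, dtype=float)
    mean = values.mean()
    sd = values.std(ddof=1) if values.size > 1 else 0.0
    if abs(mean) < 1e-300:
        return float(sd), 0.0, 0.0
    rel_sd = sd / abs(mean)
    max_rel = float(np.abs(values - mean).max() / abs(mean)) if values.size else 0.0
    return float(sd), float(rel_sd), max_rel


@dataclass
class RealisationEnsemble:
    """Per-seed outcomes at one fixed ``(P, Q)`` cell."""

    P: float
    Q: float
    jaccard_values: np.ndarray
    sf_values: np.ndarray
    seeds: list[int]
    failures: list[int] = field(default_factory=list)
    fc_layers: Optional[list[LayerMatrix]] = None

    @property
    def n_realisations(self) -> int:
        return len(self.jaccard_values)

    def summary(self) -> dict:
        j_sd, j_rel, j_max = _dispersion(self.jaccard_values)
        c_sd, c_rel, c_max = _dispersion(self.sf_values)
        return {
            "jaccard_mean": float(np.mean(self.jaccard_values)),
            "jaccard_sd": j_sd,
            "jaccard_rel_sd": j_rel,
            "jaccard_max_rel_dev": j_max,
            "sf_clustering_mean": float(np.mean(self.sf_values)),
            "sf_clustering_sd": c_sd,
            "sf_clustering_rel_sd": c_rel,
            "sf_clustering_max_rel_dev": c_max,
            "n_realisations": self.n_realisations,
            "n_failures": len(self.failures),
        }


def run_cell(
    sc_variant: ConnectomeVariant,
    P: float,
    Q: float,
    n_realisations: int,
    base_seed: int,
    params: WCParameters | None = None,
    config: SimulationConfig | None = None,
    p_index: int = 0,
    q_index: int = 0,
    keep_fc: bool = False,
) -> RealisationEnsemble:
    """Simulate one grid cell: ``n_realisations`` stochastic runs.

    Each realisation draws fresh initial conditions and noise from its own
    derived seed, builds the density-matched functional layer, and records
    the SC-FC Jaccard similarity and node-mean weighted structure-function
    clustering.  Individual simulation failures are recorded; the cell fails
    only if every realisation fails.
    """
    params = (params or WCParameters()).replace(
        P=float(P), Q=float(Q), epsilon=coupling_strength(sc_variant)
    )
    config = config or SimulationConfig()
    sc = sc_variant.matrix
    target_density = density(sc)
    binarise = sc_variant.kind == "binary"

    jaccards: list[float] = []
    sfs: list[float] = []
    seeds: list[int] = []
    failures: list[int] = []
    fc_layers: list[LayerMatrix] = [] if keep_fc else None
    from dataclasses import replace as _replace

    for r in range(n_realisations):
        seed = cell_seed(base_seed, p_index, q_index, r)
        run_cfg = _replace(config, seed=seed, initial_state=config.initial_state)
        try:
            traj = simulate(sc, params, run_cfg)
        except SimulationError as exc:
            logger.warning(
                "realisation %d at (P=%.3f, Q=%.3f) failed: %s", r, P, Q, exc
            )
            failures.append(r)
            continue
        fc = functional_layer(
            traj, target_density, burn_in=config.burn_in, binarise=binarise
        )
        jaccards.append(jaccard_weighted(sc, fc.thresholded))
        sfs.append(sf_clustering_weighted(sc, fc.thresholded).mean)
        seeds.append(seed)
        if keep_fc:
            fc_layers.append(fc.thresholded)
    if not jaccards:
        raise RuntimeError(
            f"all {n_realisations} realisations failed at (P={P}, Q={Q})"
        )
    return RealisationEnsemble(
        float(P), float(Q), np.array(jaccards), np.array(sfs),
        seeds, failures, fc_layers,
    )


@dataclass
class SweepResult:
    """Grid of SC-FC statistics over basal inputs with bifurcation overlay."""

    P_grid: np.ndarray
    Q_grid: np.ndarray
    jaccard: np.ndarray  # (nP, nQ) mean over realisations
    sf_clustering: np.ndarray  # (nP, nQ)
    jaccard_dispersion: np.ndarray  # relative sd across realisations
    sf_dispersion: np.ndarray
    n_realisations: int
    bifurcation_overlay: BifurcationSet
    stability_map: StabilityMap
    provenance: dict = field(default_factory=dict)

    def boundary_distance(self) -> np.ndarray:
        """Chebyshev distance (in grid cells) to the stability boundary.

        The boundary is taken on the destabilised side: unstable cells with a
        stable 4-neighbour.
        """
        boundary = self.stability_map.boundary_mask() & self.stability_map.unstable_mask
        cells = np.argwhere(boundary)
        if cells.size == 0:
            return np.full(self.jaccard.shape, np.inf)
        all_cells = np.argwhere(np.ones_like(self.jaccard, dtype=bool))
        d = cdist(all_cells, cells, metric="chebyshev").min(axis=1)
        return d.reshape(self.jaccard.shape)

    def top_decile_jaccard_mask(self) -> np.ndarray:
        cut = np.quantile(self.jaccard, 0.9)
        return self.jaccard >= cut

    def argmax_cell(self, grid_name: str = "sf_clustering") -> tuple[int, int]:
        grid = getattr(self, grid_name)
        return tuple(int(x) for x in np.unravel_index(np.argmax(grid), grid.shape))


def _config_key(provenance: dict) -> str:
    blob = json.dumps(provenance, sort_keys=True, default=str)
    return hashlib.sha1(blob.encode()).hexdigest()[:12]


def run_sweep(
    sc_variant: ConnectomeVariant,
    P_range: tuple[float, float] = (-6.0, 2.0),
    Q_range: tuple[float, float] = (-12.0, 0.0),
    resolution: int = 30,
    n_realisations: int = 3,
    base_seed: int = 0,
    params: WCParameters | None = None,
    config: SimulationConfig | None = None,
    cache_dir: str | Path | None = None,
    map_resolution: int | None = None,
    progress: bool = False,
) -> SweepResult:
    """Run the full ``(P, Q)`` sweep for one cortical representation.

    Completed cells are cached as JSON (keyed by a configuration hash) so
    interrupted sweeps resume bitwise-identically.  The network stability map
    is computed on the same grid (or ``map_resolution``) and the closed-form
    single-node sets are attached as overlay.
    """
    params = params or WCParameters()
    config = config or SimulationConfig()
    p_vals = np.linspace(*P_range, resolution)
    q_vals = np.linspace(*Q_range, resolution)
    provenance = {
        "variant": sc_variant.kind,
        "retained_fraction": sc_variant.retained_fraction,
        "P_range": list(P_range),
        "Q_range": list(Q_range),
        "resolution": resolution,
        "n_realisations": n_realisations,
        "base_seed": base_seed,
        "params": asdict(params),
        "config": {
            k: v for k, v in asdict(config).items() if k != "initial_state"
        },
        "sc_checksum": hashlib.sha1(
            sc_variant.matrix.weights.tobytes()
        ).hexdigest()[:12],
    }
    key = _config_key(provenance)
    cache = Path(cache_dir) if cache_dir is not None else None
    if cache is not None:
        cache.mkdir(parents=True, exist_ok=True)

    jaccard = np.zeros((resolution, resolution))
    sf = np.zeros((resolution, resolution))
    j_disp = np.zeros((resolution, resolution))
    c_disp = np.zeros((resolution, resolution))

    cells = [(pi, qi) for pi in range(resolution) for qi in range(resolution)]
    iterator = cells
    if progress:
        from tqdm import tqdm

        iterator = tqdm(cells, desc=f"sweep[{sc_variant.kind}]")
    for pi, qi in iterator:
        cell_path = (
            cache / f"cell_{pi:03d}_{qi:03d}_{key}.json" if cache else None
        )
        if cell_path is not None and cell_path.exists():
            payload = json.loads(cell_path.read_text())
            ens = RealisationEnsemble(
                payload["P"], payload["Q"],
                np.array(payload["jaccard_values"]),
                np.array(payload["sf_values"]),
                payload["seeds"], payload["failures"],
            )
        else:
            ens = run_cell(
                sc_variant, p_vals[pi], q_vals[qi], n_realisations,
                base_seed, params=params, config=config,
                p_index=pi, q_index=qi,
            )
            if cell_path is not None:
                cell_path.write_text(json.dumps({
                    "P": ens.P, "Q": ens.Q,
                    "jaccard_values": ens.jaccard_values.tolist(),
                    "sf_values": ens.sf_values.tolist(),
                    "seeds": ens.seeds, "failures": ens.failures,
                }))
        s = ens.summary()
        jaccard[pi, qi] = s["jaccard_mean"]
        sf[pi, qi] = s["sf_clustering_mean"]
        j_disp[pi, qi] = s["jaccard_rel_sd"]
        c_disp[pi, qi] = s["sf_clustering_rel_sd"]

    overlay = single_node_bifurcation_sets(params)
    smap = network_stability_map(
        sc_variant.matrix,
        params.replace(epsilon=coupling_strength(sc_variant)),
        P_range=P_range,
        Q_range=Q_range,
        resolution=map_resolution or resolution,
    )
    return SweepResult(
        p_vals, q_vals, jaccard, sf, j_disp, c_disp,
        n_realisations, overlay, smap, provenance,
    )


def choose_contrast_cells(sweep: SweepResult) -> dict:
    """Pick the two cells contrasted by the multistability analysis.

    The on-boundary cell is the Jaccard-maximising cell (strongest SC-FC
    similarity, expected at criticality); the beyond-boundary cell is the
    structure-function-clustering-maximising cell (expected just beyond the
    oscillatory onset).
    """
    pj, qj = sweep.argmax_cell("jaccard")
    pc, qc = sweep.argmax_cell("sf_clustering")
    return {
        "on_boundary": {
            "p_index": pj, "q_index": qj,
            "P": float(sweep.P_grid[pj]), "Q": float(sweep.Q_grid[qj]),
        },
        "beyond_boundary": {
            "p_index": pc, "q_index": qc,
            "P": float(sweep.P_grid[pc]), "Q": float(sweep.Q_grid[qc]),
        },
    }


@dataclass
class MultistabilityReport:
    """Dispersion of functional states across realisations at one cell."""

    pairwise_jaccard: np.ndarray  # (n, n) FC-to-FC similarity
    mean_pairwise_jaccard: float
    jaccard_rel_sd: float  # of SC-to-FC Jaccard across realisations
    jaccard_max_rel_dev: float
    sf_clustering_mean: float
    sf_clustering_rel_sd: float


def multistability_report(ensemble: RealisationEnsemble) -> MultistabilityReport:
    """Quantify the variety of functional states accessed at fixed ``(P, Q)``.

    Requires ``run_cell(..., keep_fc=True)``: the report includes all
    pairwise Jaccard similarities between realisation FC layers (low values
    mean distinct functional states, i.e. multistability) alongside the
    across-seed dispersion of SC-FC similarity and clustering.
    """
    if ensemble.n_realisations < 2:
        raise ValueError("multistability analysis needs at least 2 realisations")
    if not ensemble.fc_layers:
        raise ValueError("ensemble was built without keep_fc=True")
    n = len(ensemble.fc_layers)
    pw = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                val = jaccard_weighted(ensemble.fc_layers[i], ensemble.fc_layers[j])
            except ValueError:  # both layers all-zero
                val = 1.0
            pw[i, j] = pw[j, i] = val
    iu = np.triu_indices(n, k=1)
    _, j_rel, j_max = _dispersion(ensemble.jaccard_values)
    _, c_rel, _ = _dispersion(ensemble.sf_values)
    return MultistabilityReport(
        pw, float(pw[iu].mean()), j_rel, j_max,
        float(np.mean(ensemble.sf_values)), c_rel,
    )


def dispersion_rank_test(
    high_dispersion: RealisationEnsemble, low_dispersion: RealisationEnsemble
) -> float:
    """One-sided Mann-Whitney p-value that SC-FC Jaccard is more dispersed
    (relative to its mean) in the first ensemble than in the second."""

    def rel_devs(ens: RealisationEnsemble) -> np.ndarray:
        vals = ens.jaccard_values
        mean = vals.mean()
        return np.abs(vals - mean) / abs(mean)

    stat = mannwhitneyu(
        rel_devs(high_dispersion), rel_devs(low_dispersion),
        alternative="greater",
    )
    return float(stat.pvalue)
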