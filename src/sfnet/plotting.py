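"""Minimal heat-map export for sweep results (matplotlib, Agg backend)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .pipeline import SweepResult  # noqa: E402


def save_sweep_heatmaps(sweep: SweepResult, path: str, overlay: bool = True) -> None:
    """Write side-by-side Jaccard and SC-FC clustering heat maps.

    The closed-form single-node bifurcation sets are overlaid in white
    (solid markers: Hopf; open markers: saddle-node), mirroring how sweep
    results are conventionally presented.
    """
    fig, axes = plt.subplots(1, 2, figsize=(11, 4.5), constrained_layout=True)
    extent = [
        sweep.Q_grid[0], sweep.Q_grid[-1], sweep.P_grid[0], sweep.P_grid[-1]
    ]
    for ax, grid, title in (
        (axes[0], sweep.jaccard, "Jaccard(SC, FC)"),
        (axes[1], sweep.sf_clustering, "SC-FC clustering (node mean)"),
    ):
        im = ax.imshow(grid, origin="lower", aspect="auto", extent=extent)
        ax.set_xlabel("Q")
        ax.set_ylabel("P")
        ax.set_title(title)
        fig.colorbar(im, ax=ax)
        if overlay:
            for label, marker in (("hopf", "."), ("saddle-node", "x")):
                pts = sweep.bifurcation_overlay.points(label)
                if len(pts):
                    ax.plot(pts[:, 1], pts[:, 0], marker, color="white",
                            markersize=2, linestyle="none")
            ax.set_xlim(extent[0], extent[1])
            ax.set_ylim(extent[2], extent[3])
    fig.savefig(path, dpi=150)
    plt.close(fig)
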