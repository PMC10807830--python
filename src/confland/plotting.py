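"""Optional figure output: all plots mirror the CSV/JSON data and nothing
downstream depends on them."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

from .clustering import ClusterAssignment  # noqa: E402
from .essential_dynamics import ProjectionSeries, projection_distribution  # noqa: E402
from .membrane_profile import DensityProfile  # noqa: E402
from .reaction_coordinates import DistanceSeries, PAIR_LABELS  # noqa: E402
from .superposition import RMSDMatrix  # noqa: E402

__all__ = ["plot_rmsd_matrix", "plot_cluster_timeline",
           "plot_distance_scatter", "plot_projection_distributions",
           "plot_density_profile"]


def plot_rmsd_matrix(matrix: RMSDMatrix, path: str | Path) -> None:
    """Grayscale time-vs-time RMSD matrix (dark = similar conformations)."""
    fig, ax = plt.subplots(figsize=(5, 4))
    t = matrix.times / 1000.0
    im = ax.imshow(matrix.values, cmap="gray", origin="lower",
                   extent=[t[0], t[-1], t[0], t[-1]])
    fig.colorbar(im, ax=ax, label="RMSD (Å)")
    ax.set_xlabel("time (ns)")
    ax.set_ylabel("time (ns)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_cluster_timeline(assignment: ClusterAssignment, times: np.ndarray,
                          path: str | Path) -> None:
    """Step plot of cluster id vs time; horizontal runs are dwell segments."""
    fig, ax = plt.subplots(figsize=(5, 3))
    ax.step(np.asarray(times) / 1000.0, assignment.labels, where="post")
    ax.set_xlabel("time (ns)")
    ax.set_ylabel("cluster id (earliest member frame)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_distance_scatter(series: DistanceSeries, path: str | Path) -> None:
    """The three pairwise domain-distance scatter panels."""
    pairs = ((PAIR_LABELS[0], PAIR_LABELS[1]), (PAIR_LABELS[0], PAIR_LABELS[2]),
             (PAIR_LABELS[1], PAIR_LABELS[2]))
    fig, axes = plt.subplots(1, 3, figsize=(11, 3.3))
    for ax, (a, b) in zip(axes, pairs):
        ax.scatter(series.pair(a), series.pair(b), s=4, alpha=0.4)
        ax.set_xlabel(f"{a} (Å)")
        ax.set_ylabel(f"{b} (Å)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_projection_distributions(series: ProjectionSeries, path: str | Path,
                                  bin_width: float = 1.0) -> None:
    fig, axes = plt.subplots(1, len(series.components),
                             figsize=(3.2 * len(series.components), 3))
    axes = np.atleast_1d(axes)
    for ax, (i, comp) in zip(axes, enumerate(series.components)):
        centers, density, maxima = projection_distribution(
            series.values[:, i], bin_width)
        ax.plot(centers, density)
        for m in maxima:
            ax.axvline(m, color="0.6", ls="--", lw=0.8)
        ax.set_xlabel(f"PC{comp} (Å)")
        ax.set_ylabel("density")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_density_profile(profile: DensityProfile, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 3.2))
    for group, dens in profile.densities.items():
        ax.plot(profile.bin_centers, dens, label=group)
    ax.set_xlabel(f"{profile.axis} (Å)")
    unit = "atoms/Å³" if profile.mode == "number" else "amu/Å³"
    ax.set_ylabel(f"density ({unit})")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
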