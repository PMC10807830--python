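"""Essential dynamics: coordinate PCA of Calpha fluctuations.

The covariance matrix of the analysis-selection Calpha coordinates is built
after rigid-body fitting every frame on a designated fit group (the TM
bundle in the receptor studies this package reproduces) and eigendecomposed.
Leading eigenvectors are the low-frequency collective motions; projections
of frames onto them, their histograms, cross-replicate projections,
cluster-conditioned projections and porcupine displacement vectors are all
derived here.

Conventions: internal units are Angstrom and Angstrom^2; an optional
nanometre scale is offered on export. Eigenvalues are sorted descending and
each eigenvector's largest-magnitude entry is made positive (eigenvector
signs are otherwise arbitrary).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .clustering import ClusterAssignment
from .structure_io import TrajectoryEnsemble
from .superposition import kabsch_fit

__all__ = [
    "EigenDecomposition",
    "ProjectionSeries",
    "covariance_analysis",
    "project",
    "projection_distribution",
    "fluctuation_fraction",
    "porcupine_vectors",
    "cluster_projection",
]

#: Leading trajectory time excluded from the covariance, ps (20 ns).
DEFAULT_EXCLUDE_LEADING_PS = 20000.0


@dataclasses.dataclass
class EigenDecomposition:
    """Mean conformation plus eigenpairs of the Calpha covariance (3N x 3N).

    ``mean_coords`` is the fitted mean of the analysis selection (atoms x 3,
    Angstrom); ``fit_mean`` the fitted mean of the fit selection, used as the
    superposition target when projecting further frames. ``eigenvalues``
    (Angstrom^2) are descending; ``eigenvectors`` holds orthonormal columns.
    """

    mean_coords: np.ndarray
    fit_mean: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    fit_indices: np.ndarray
    analysis_indices: np.ndarray
    fit_selection: str = "fit"
    analysis_selection: str = "analysis"
    excluded_leading_time: float = 0.0

    def __post_init__(self) -> None:
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        self.eigenvectors = np.asarray(self.eigenvectors, dtype=float)
        n3 = self.eigenvalues.size
        if self.eigenvectors.shape != (n3, n3):
            raise ValueError("eigenvector matrix must be 3N x 3N")
        if np.any(np.diff(self.eigenvalues) > 1e-12):
            raise ValueError("eigenvalues must be sorted descending")
        if np.any(self.eigenvalues < -1e-9):
            raise ValueError("covariance eigenvalues must be >= -1e-9")

    @property
    def n_atoms(self) -> int:
        return self.eigenvalues.size // 3

    @property
    def total_fluctuation(self) -> float:
        """Trace of the covariance = sum of eigenvalues, Angstrom^2."""
        return float(self.eigenvalues.sum())

    def to_frame(self, k: int = 10) -> pd.DataFrame:
        k = min(k, self.eigenvalues.size)
        lam = self.eigenvalues[:k]
        return pd.DataFrame({
            "component": np.arange(1, k + 1),
            "eigenvalue_A2": lam,
            "fraction": lam / self.total_fluctuation if self.total_fluctuation else 0.0,
            "cumulative_fraction": (np.cumsum(lam) / self.total_fluctuation
                                    if self.total_fluctuation else 0.0),
        })


@dataclasses.dataclass
class ProjectionSeries:
    """Per-frame projections (Angstrom) onto chosen principal components."""

    values: np.ndarray              # (frames, len(components))
    components: tuple[int, ...]     # 1-based component indices
    times: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.times = np.asarray(self.times, dtype=float)
        self.components = tuple(int(c) for c in self.components)
        if self.values.shape != (self.times.size, len(self.components)):
            raise ValueError("values must be (frames, n_components)")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    def component(self, k: int) -> np.ndarray:
        return self.values[:, self.components.index(k)]

    def subset(self, frame_positions: np.ndarray) -> "ProjectionSeries":
        pos = np.asarray(frame_positions, dtype=int)
        return ProjectionSeries(values=self.values[pos], components=self.components,
                                times=self.times[pos], source=self.source)

    def to_frame(self, unit: str = "A") -> pd.DataFrame:
        scale = 0.1 if unit == "nm" else 1.0
        data = {"time_ps": self.times}
        for i, c in enumerate(self.components):
            data[f"pc{c}_{unit}"] = self.values[:, i] * scale
        return pd.DataFrame(data)

    def to_csv(self, path: str | Path, unit: str = "A") -> None:
        self.to_frame(unit).to_csv(path, index=False)


def covariance_analysis(traj: TrajectoryEnsemble, fit_indices: np.ndarray,
                        analysis_indices: np.ndarray,
                        exclude_leading_ps: float = DEFAULT_EXCLUDE_LEADING_PS,
                        fit_name: str = "fit", analysis_name: str = "analysis",
                        ) -> EigenDecomposition:
    """Eigendecompose the Calpha covariance of the analysis selection.

    Frames earlier than ``exclude_leading_ps`` after the first frame are
    dropped (equilibration burn-in; 20 ns by default). Fitting is two-pass:
    all frames are first fitted on the fit selection to the first retained
    frame, the mean is computed, then the original frames are refitted to
    that mean before the covariance is accumulated.
    """
    fit_idx = np.asarray(fit_indices, dtype=int)
    ana_idx = np.asarray(analysis_indices, dtype=int)
    t0 = traj.times[0]
    keep = np.nonzero(traj.times - t0 >= exclude_leading_ps)[0]
    if keep.size == 0:
        raise ValueError(
            f"excluded leading time {exclude_leading_ps} ps covers the whole "
            f"trajectory span ({traj.times[-1] - t0} ps)")
    if keep.size < 10:
        raise ValueError(f"only {keep.size} frames remain after exclusion; need >= 10")

    coords = traj.coordinates[keep]
    # pass 1: fit to the first retained frame, take the mean
    ref_fit = coords[0, fit_idx]
    fitted = np.empty_like(coords)
    for i, frame in enumerate(coords):
        transform, _ = kabsch_fit(frame[fit_idx], ref_fit)
        fitted[i] = transform.apply(frame)
    mean1 = fitted.mean(axis=0)
    # pass 2: refit the original frames to the pass-1 mean
    for i, frame in enumerate(coords):
        transform, _ = kabsch_fit(frame[fit_idx], mean1[fit_idx])
        fitted[i] = transform.apply(frame)
    mean2 = fitted.mean(axis=0)
    # the stored fit target is the pass-2 target itself, so later projections
    # reproduce the covariance fitting exactly
    X = (fitted[:, ana_idx] - mean2[ana_idx]).reshape(keep.size, -1)
    cov = (X.T @ X) / keep.size
    lam, vec = np.linalg.eigh(cov)
    order = np.argsort(lam)[::-1]
    lam = lam[order]
    vec = vec[:, order]
    # sign convention: largest-magnitude entry of each eigenvector positive
    flips = np.sign(vec[np.argmax(np.abs(vec), axis=0), np.arange(vec.shape[1])])
    flips[flips == 0] = 1.0
    vec = vec * flips
    return EigenDecomposition(
        mean_coords=mean2[ana_idx], fit_mean=mean1[fit_idx],
        eigenvalues=lam, eigenvectors=vec,
        fit_indices=fit_idx, analysis_indices=ana_idx,
        fit_selection=fit_name, analysis_selection=analysis_name,
        excluded_leading_time=float(exclude_leading_ps))


def project(traj: TrajectoryEnsemble, decomp: EigenDecomposition,
            components: Sequence[int] = (1, 2, 3, 4),
            source: str = "") -> ProjectionSeries:
    """Project every frame onto the chosen components (1-based indices).

    Each frame is fitted on the decomposition's fit selection to the fitted
    mean, mean-centred on the analysis selection, flattened to 3N and dotted
    with the eigenvectors. Projections are computed for all frames of
    ``traj`` regardless of any burn-in excluded from the covariance;
    cross-replicate projection is simply calling this with another
    trajectory of the same atom set.
    """
    comps = tuple(int(c) for c in components)
    n3 = decomp.eigenvalues.size
    for c in comps:
        if not 1 <= c <= n3:
            raise ValueError(f"component {c} outside 1..{n3}")
    if traj.n_atoms <= int(max(decomp.analysis_indices.max(),
                               decomp.fit_indices.max())):
        raise ValueError("trajectory atom set does not cover the decomposition "
                         "selections")
    cols = np.array([c - 1 for c in comps])
    V = decomp.eigenvectors[:, cols]
    out = np.empty((traj.n_frames, len(comps)))
    mean_flat = decomp.mean_coords.reshape(-1)
    for i in range(traj.n_frames):
        frame = traj.coordinates[i]
        transform, _ = kabsch_fit(frame[decomp.fit_indices], decomp.fit_mean)
        disp = transform.apply(frame[decomp.analysis_indices]).reshape(-1) - mean_flat
        out[i] = disp @ V
    return ProjectionSeries(values=out, components=comps, times=traj.times,
                            source=source)


def reconstruct(decomp: EigenDecomposition,
                projections: np.ndarray) -> np.ndarray:
    """Rebuild fitted analysis coordinates from a full 3N projection vector.

    With all 3N components this is the exact inverse of :func:`project`
    (orthonormal basis), so frames are recovered to rounding error.
    """
    proj = np.atleast_2d(np.asarray(projections, dtype=float))
    coords = proj @ decomp.eigenvectors.T + decomp.mean_coords.reshape(-1)
    return coords.reshape(proj.shape[0], -1, 3)


def projection_distribution(series_values: np.ndarray, bin_width: float,
                            ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Density histogram of a projection series plus its local maxima.

    Returns ``(bin_centers, density, maxima_positions)``. The histogram is
    density-normalised; maxima are bin centres whose 3-bin moving-averaged
    density exceeds both neighbours, ordered by position. Requires at least
    two distinct values (a constant series has no distribution).
    """
    x = np.asarray(series_values, dtype=float).ravel()
    if np.unique(x).size < 2:
        raise ValueError("projection series is constant; distribution undefined")
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    lo, hi = x.min(), x.max()
    n_bins = max(int(np.ceil((hi - lo) / bin_width)), 1)
    edges = lo + bin_width * np.arange(n_bins + 1)
    density, _ = np.histogram(x, bins=edges, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    padded = np.concatenate([[density[0]], density, [density[-1]]])
    smooth = np.convolve(padded, np.full(3, 1 / 3), mode="valid")
    # edge bins count as maxima when they exceed their single inner
    # neighbour (a state centred at the range limit still shows up)
    guarded = np.concatenate([[-np.inf], smooth, [-np.inf]])
    is_max = (guarded[1:-1] > guarded[:-2]) & (guarded[1:-1] > guarded[2:])
    if not is_max.any():
        is_max[np.argmax(smooth)] = True
    return centers, density, centers[is_max]


def fluctuation_fraction(decomp: EigenDecomposition, k: int) -> float:
    """Fraction of the total fluctuation carried by the first k components."""
    n3 = decomp.eigenvalues.size
    if not 1 <= k <= n3:
        raise ValueError(f"k must lie in 1..{n3}")
    total = decomp.total_fluctuation
    if total == 0.0:
        return 0.0
    return float(decomp.eigenvalues[:k].sum() / total)


def porcupine_vectors(decomp: EigenDecomposition, component: int,
                      scale: float = 1.0) -> np.ndarray:
    """Per-atom displacement arrows for one component, anchored at the mean.

    vector_i = scale * sqrt(lambda_k) * eigenvector_k[3i:3i+3]; amplitude is
    thus one standard deviation of the motion at scale 1.
    """
    n3 = decomp.eigenvalues.size
    if not 1 <= component <= n3:
        raise ValueError(f"component {component} outside 1..{n3}")
    lam = max(decomp.eigenvalues[component - 1], 0.0)
    v = decomp.eigenvectors[:, component - 1].reshape(-1, 3)
    return scale * np.sqrt(lam) * v


def porcupine_frame(decomp: EigenDecomposition, component: int,
                    scale: float = 1.0) -> pd.DataFrame:
    vec = porcupine_vectors(decomp, component, scale)
    return pd.DataFrame({
        "atom": np.arange(decomp.n_atoms),
        "x_A": decomp.mean_coords[:, 0], "y_A": decomp.mean_coords[:, 1],
        "z_A": decomp.mean_coords[:, 2],
        "dx_A": vec[:, 0], "dy_A": vec[:, 1], "dz_A": vec[:, 2],
    })


def cluster_projection(assignment: ClusterAssignment, series: ProjectionSeries,
                       bin_width: float = 1.0) -> dict[int, dict]:
    """Per-cluster projection subsets with a mode-vs-maximum summary.

    The assignment's frame indices must be a subset of the series frames
    (matched by original frame index position). For each cluster the result
    records the subset series and, per component, whether the cluster's own
    histogram mode lands within one bin of a local maximum of the full
    distribution. An unknown/empty cluster id simply yields no entry.
    """
    frame_pos = {int(f): p for p, f in enumerate(
        np.arange(series.n_frames))}
    out: dict[int, dict] = {}
    for cluster in assignment.clusters:
        positions = []
        for f in cluster.member_frames:
            if int(f) not in frame_pos:
                raise ValueError(f"cluster frame {f} outside the projection series")
            positions.append(frame_pos[int(f)])
        sub = series.subset(np.asarray(positions, dtype=int))
        modes = {}
        for i, comp in enumerate(series.components):
            full = series.values[:, i]
            centers, density, maxima = projection_distribution(full, bin_width)
            subset_vals = sub.values[:, i]
            counts, _ = np.histogram(subset_vals,
                                     bins=np.concatenate([centers - bin_width / 2,
                                                          [centers[-1] + bin_width / 2]]))
            mode = centers[int(np.argmax(counts))]
            at_max = bool(maxima.size and np.min(np.abs(maxima - mode)) <= bin_width)
            modes[comp] = {"mode": float(mode), "at_distribution_maximum": at_max}
        out[cluster.id] = {"series": sub, "modes": modes}
    return out
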