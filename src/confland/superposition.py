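"""Optimal rigid-body superposition and RMSD machinery.

The central objects are the Kabsch fit (SVD solution of the orthogonal
Procrustes problem with the reflection excluded) and the time-vs-time RMSD
matrix in which every frame pair is fitted independently on a designated
group (typically the TM helix Calphas) before the RMSD is measured --
possibly on a different selection. Pairwise fitting, rather than fitting
all frames to a single reference, is what makes the matrix reveal
self-similar conformational epochs.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .structure_io import StructureModel, TrajectoryEnsemble

__all__ = [
    "RigidTransform",
    "RMSDMatrix",
    "GeometryError",
    "kabsch_fit",
    "rmsd",
    "rmsd_series",
    "rmsd_matrix",
]


class GeometryError(ValueError):
    """Raised for degenerate point sets (fewer than 3 points, collinear)."""


@dataclasses.dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x -> R x + t (rotation then translation, Angstrom)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation a 3-vector")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-10):
            raise ValueError("rotation is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-10):
            raise ValueError("rotation determinant is not +1 (reflection?)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


def rmsd(a: np.ndarray, b: np.ndarray, weights: np.ndarray | None = None) -> float:
    """Plain (unfitted) root-mean-square deviation between two point sets."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    d2 = np.sum((a - b) ** 2, axis=1)
    if weights is None:
        return float(np.sqrt(d2.mean()))
    w = np.asarray(weights, dtype=float)
    return float(np.sqrt(np.sum(w * d2) / np.sum(w)))


def kabsch_fit(mobile: np.ndarray, reference: np.ndarray,
               weights: np.ndarray | None = None) -> tuple[RigidTransform, float]:
    """Least-squares rigid fit of ``mobile`` onto ``reference``.

    Returns the proper rotation + translation minimising the (optionally
    weighted) RMSD, and that minimal RMSD. Reflections are excluded by
    flipping the sign of the smallest singular vector when needed.

    Raises :class:`GeometryError` for fewer than 3 points or point sets of
    rank < 2 (collinear), where the rotation is not determined.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and reference must both have shape (n, 3)")
    n = mobile.shape[0]
    if n < 3:
        raise GeometryError(f"need at least 3 points for a rigid fit, got {n}")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
        w = w / w.sum()
    cm = w @ mobile
    cr = w @ reference
    M = mobile - cm
    Rf = reference - cr
    H = M.T @ (w[:, None] * Rf)
    U, S, Vt = np.linalg.svd(H)
    scale = max(np.linalg.norm(M), 1.0)
    if S[1] <= 1e-12 * scale:
        raise GeometryError("degenerate (collinear) point set: rotation undetermined")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cr - R @ cm
    transform = RigidTransform(R, t)
    return transform, rmsd(transform.apply(mobile), reference,
                           None if weights is None else w)


def _resolve_reference(reference, traj: TrajectoryEnsemble) -> np.ndarray:
    if isinstance(reference, StructureModel):
        return reference.xyz
    if isinstance(reference, (int, np.integer)):
        return traj.coordinates[int(reference)]
    ref = np.asarray(reference, dtype=float)
    if ref.shape != (traj.n_atoms, 3):
        raise ValueError("reference coordinates must match the trajectory atoms")
    return ref


def rmsd_series(traj: TrajectoryEnsemble, fit_indices: np.ndarray,
                measure_indices: np.ndarray | None = None,
                reference=0,
                weights: np.ndarray | None = None) -> np.ndarray:
    """Per-frame RMSD after fitting each frame on ``fit_indices`` to a reference.

    ``reference`` may be a frame index, a :class:`StructureModel`, or a raw
    (n_atoms, 3) coordinate array. RMSD is measured on ``measure_indices``
    (default: the fit selection).
    """
    fit_idx = np.asarray(fit_indices, dtype=int)
    measure_idx = fit_idx if measure_indices is None else np.asarray(measure_indices, dtype=int)
    ref = _resolve_reference(reference, traj)
    out = np.empty(traj.n_frames)
    for i in range(traj.n_frames):
        transform, _ = kabsch_fit(traj.coordinates[i, fit_idx], ref[fit_idx],
                                  weights=weights)
        out[i] = rmsd(transform.apply(traj.coordinates[i, measure_idx]),
                      ref[measure_idx])
    return out


@dataclasses.dataclass
class RMSDMatrix:
    """Symmetric all-pairs frame RMSD table after per-pair fitting."""

    values: np.ndarray
    frame_indices: np.ndarray
    times: np.ndarray
    fit_selection: str = "fit"
    measure_selection: str = "measure"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("RMSD matrix must be square")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValueError("RMSD matrix must be symmetric within 1e-9")
        if np.any(np.abs(np.diag(self.values)) > 1e-12) or np.any(self.values < 0):
            raise ValueError("RMSD matrix needs a zero diagonal and entries >= 0")
        self.frame_indices = np.asarray(self.frame_indices, dtype=int)
        self.times = np.asarray(self.times, dtype=float)

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    def to_long_frame(self) -> pd.DataFrame:
        i, j = np.triu_indices(self.n_frames, k=1)
        return pd.DataFrame({"frame_i": self.frame_indices[i],
                             "frame_j": self.frame_indices[j],
                             "rmsd_A": self.values[i, j]})

    def to_csv(self, path: str | Path) -> None:
        self.to_long_frame().to_csv(path, index=False)

    def save_square(self, path: str | Path) -> None:
        np.savetxt(path, self.values, fmt="%.6f")


def rmsd_matrix(traj: TrajectoryEnsemble, fit_indices: np.ndarray,
                measure_indices: np.ndarray | None = None, stride: int = 1,
                fit_name: str = "fit", measure_name: str | None = None,
                ) -> RMSDMatrix:
    """All-pairs RMSD matrix with each frame pair fitted independently.

    Entry (i, j) fits frame j onto frame i using ``fit_indices`` and
    measures the RMSD on ``measure_indices`` (default: the fit group).
    The matrix is symmetrised by averaging with its transpose; with an
    exact pairwise fit the asymmetry is zero to rounding.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    frame_idx = np.arange(0, traj.n_frames, stride)
    if frame_idx.size < 2:
        raise ValueError("need at least 2 frames after striding")
    fit_idx = np.asarray(fit_indices, dtype=int)
    measure_idx = fit_idx if measure_indices is None else np.asarray(measure_indices, dtype=int)

    Xf = traj.coordinates[np.ix_(frame_idx, fit_idx)]
    Xm = traj.coordinates[np.ix_(frame_idx, measure_idx)]
    cf = Xf.mean(axis=1)                      # fit-group centroids, (F, 3)
    Xfc = Xf - cf[:, None, :]
    F = frame_idx.size
    values = np.zeros((F, F))
    for i in range(F - 1):
        mob = Xfc[i + 1:]                      # frames j > i, centered
        H = np.einsum("fnk,nl->fkl", mob, Xfc[i])
        U, S, Vt = np.linalg.svd(H)
        V = Vt.transpose(0, 2, 1)
        d = np.sign(np.linalg.det(V @ U.transpose(0, 2, 1)))
        V[:, :, 2] *= d[:, None]
        R = V @ U.transpose(0, 2, 1)          # rotates frame j onto frame i
        moved = np.einsum("fkl,fnl->fnk", R, Xm[i + 1:] - cf[i + 1:, None, :]) + cf[i]
        diff = moved - Xm[i]
        values[i, i + 1:] = np.sqrt(np.mean(np.sum(diff * diff, axis=2), axis=1))
    values = values + values.T                 # mirror the upper triangle
    return RMSDMatrix(values=values, frame_indices=frame_idx,
                      times=traj.times[frame_idx], fit_selection=fit_name,
                      measure_selection=measure_name or fit_name)
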