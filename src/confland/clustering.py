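"""Threshold-membership conformational clustering over an RMSD matrix.

A frame joins a cluster when its RMSD to any member is below the cutoff.
Stated incrementally that rule is order-dependent, so this module computes
its order-independent closure: the connected components of the graph with
an edge wherever RMSD < cutoff (strict inequality). Every incremental
clustering is contained in this partition and the result is deterministic.

Cluster ids are the earliest member frame index (zero-padded in string
form); the representative (medoid) of a cluster is the member minimising
the summed RMSD to its co-members, ties broken by earliest frame.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .superposition import RMSDMatrix

__all__ = ["Cluster", "ClusterAssignment", "threshold_cluster",
           "cluster_report", "cutoff_scan"]


@dataclasses.dataclass(frozen=True)
class Cluster:
    id: int
    member_frames: np.ndarray
    medoid_frame: int
    first_frame: int
    size: int

    @property
    def name(self) -> str:
        return f"{self.id:04d}"


@dataclasses.dataclass
class ClusterAssignment:
    """Partition of the matrix frames into threshold-membership clusters."""

    labels: np.ndarray
    clusters: tuple[Cluster, ...]
    cutoff: float
    frame_indices: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.frame_indices = np.asarray(self.frame_indices, dtype=int)
        if sum(c.size for c in self.clusters) != self.labels.size:
            raise ValueError("cluster sizes must sum to the frame count")

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def members(self, cluster_id: int) -> np.ndarray:
        """Original frame indices belonging to ``cluster_id`` (empty if unknown)."""
        for c in self.clusters:
            if c.id == cluster_id:
                return c.member_frames
        return np.empty(0, dtype=int)

    def to_frame(self, times: np.ndarray | None = None) -> pd.DataFrame:
        data = {"frame": self.frame_indices, "cluster_id": self.labels}
        if times is not None:
            data = {"frame": self.frame_indices,
                    "time_ps": np.asarray(times, dtype=float),
                    "cluster_id": self.labels}
        return pd.DataFrame(data)

    def to_csv(self, path: str | Path, times: np.ndarray | None = None) -> None:
        self.to_frame(times).to_csv(path, index=False)


def threshold_cluster(matrix: RMSDMatrix, cutoff: float) -> ClusterAssignment:
    """Cluster the matrix frames with the threshold-membership rule.

    ``cutoff`` is in Angstrom and must be positive; edges use strict
    inequality (RMSD < cutoff). Returns labels keyed by the matrix's
    original frame indices.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    values = matrix.values
    n = matrix.n_frames
    adj = csr_matrix(values < cutoff)
    _, comp = connected_components(adj, directed=False)
    frames = matrix.frame_indices
    labels = np.empty(n, dtype=int)
    clusters = []
    for c in np.unique(comp):
        pos = np.nonzero(comp == c)[0]
        cid = int(frames[pos].min())
        labels[pos] = cid
        sub = values[np.ix_(pos, pos)]
        sums = sub.sum(axis=0)
        medoid = int(frames[pos[int(np.argmin(sums))]])  # argmin: earliest on ties
        clusters.append(Cluster(id=cid, member_frames=frames[pos],
                                medoid_frame=medoid,
                                first_frame=int(frames[pos].min()),
                                size=int(pos.size)))
    clusters.sort(key=lambda c: c.id)
    return ClusterAssignment(labels=labels, clusters=tuple(clusters),
                             cutoff=float(cutoff), frame_indices=frames)


def cluster_report(assignment: ClusterAssignment,
                   times: np.ndarray) -> pd.DataFrame:
    """Contiguous time segments per cluster, in time order.

    One row per maximal run of consecutive frames sharing a cluster:
    (cluster_id, n_members, start_time_ps, end_time_ps, segment_frames).
    """
    times = np.asarray(times, dtype=float)
    labels = assignment.labels
    if times.shape != labels.shape:
        raise ValueError("times must align with the assignment frames")
    sizes = {c.id: c.size for c in assignment.clusters}
    rows = []
    start = 0
    for k in range(1, labels.size + 1):
        if k == labels.size or labels[k] != labels[start]:
            rows.append({"cluster_id": int(labels[start]),
                         "n_members": sizes[int(labels[start])],
                         "start_time_ps": times[start],
                         "end_time_ps": times[k - 1],
                         "segment_frames": k - start})
            start = k
    return pd.DataFrame(rows)


def cutoff_scan(matrix: RMSDMatrix,
                cutoffs: Sequence[float]) -> pd.DataFrame:
    """Number of clusters at each cutoff (a monotone, non-increasing curve)."""
    rows = [{"cutoff_A": float(c),
             "n_clusters": threshold_cluster(matrix, c).n_clusters}
            for c in cutoffs]
    return pd.DataFrame(rows)
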