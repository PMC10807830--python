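"""Domain-anchor reaction coordinates and the TM6 kink angle.

Three inter-domain distances (LRR-HR, LRR-TM, TM-HR) are measured between
single anchor Calphas, one per domain, on raw coordinates -- internal
coordinates need no superposition. Their pairwise Pearson correlations
expose concerted domain motions; cluster-conditioned distance maps tie the
membrane-side clustering to the aqueous-side domain geometry; and the kink
angle of TM helix 6 (upper-half vs lower-half axis vectors from two Calpha
pairs) tracks the activation-related helix bend against a crystal reference.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .clustering import ClusterAssignment
from .structure_io import (DomainAnchors, KinkSpec, StructureModel,
                           TrajectoryEnsemble, resolve_anchor, static_ensemble)
from .superposition import GeometryError

__all__ = [
    "DistanceSeries",
    "KinkSeries",
    "PAIR_LABELS",
    "domain_distances",
    "pairwise_correlation",
    "kink_angle",
    "cluster_distance_map",
    "range_summary",
]

PAIR_LABELS = ("lrr_hr", "lrr_tm", "tm_hr")


def _as_ensemble(traj_or_structure) -> TrajectoryEnsemble:
    if isinstance(traj_or_structure, StructureModel):
        return static_ensemble(traj_or_structure)
    return traj_or_structure


@dataclasses.dataclass
class DistanceSeries:
    """Per-frame Angstrom distances for the three labelled domain pairs."""

    lrr_hr: np.ndarray
    lrr_tm: np.ndarray
    tm_hr: np.ndarray
    times: np.ndarray
    anchors: DomainAnchors | None = None

    def __post_init__(self) -> None:
        for label in PAIR_LABELS:
            setattr(self, label, np.asarray(getattr(self, label), dtype=float))
        self.times = np.asarray(self.times, dtype=float)
        n = self.times.size
        if any(getattr(self, label).shape != (n,) for label in PAIR_LABELS):
            raise ValueError("distance series must match the frame count")

    @property
    def n_frames(self) -> int:
        return self.times.size

    def pair(self, label: str) -> np.ndarray:
        if label not in PAIR_LABELS:
            raise KeyError(f"unknown pair {label!r}; expected one of {PAIR_LABELS}")
        return getattr(self, label)

    def subset(self, positions: np.ndarray) -> "DistanceSeries":
        pos = np.asarray(positions, dtype=int)
        return DistanceSeries(lrr_hr=self.lrr_hr[pos], lrr_tm=self.lrr_tm[pos],
                              tm_hr=self.tm_hr[pos], times=self.times[pos],
                              anchors=self.anchors)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_ps": self.times,
                             "lrr_hr_A": self.lrr_hr,
                             "lrr_tm_A": self.lrr_tm,
                             "tm_hr_A": self.tm_hr})

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclasses.dataclass
class KinkSeries:
    """Per-frame helix kink angle (degrees) and its offset from a reference."""

    angles: np.ndarray
    spec: KinkSpec
    times: np.ndarray

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if np.any((self.angles < 0) | (self.angles > 180)):
            raise ValueError("kink angles must lie in [0, 180] degrees")

    @property
    def relative(self) -> np.ndarray:
        """Angle minus the reference (crystal-structure) angle, degrees."""
        return self.angles - self.spec.reference_angle

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_ps": self.times, "kink_deg": self.angles,
                             "kink_relative_deg": self.relative})

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def domain_distances(traj_or_structure, anchors: DomainAnchors) -> DistanceSeries:
    """Euclidean anchor-anchor distances per frame (length 1 for a structure).

    Distances are measured on raw, unfitted coordinates. When the anchors
    carry a distinct TM anchor for the TM-HR pair, that one is used for
    TM-HR and the primary TM anchor for LRR-TM, exactly as configured.
    """
    traj = _as_ensemble(traj_or_structure)
    model = traj.atom_table
    i_lrr = resolve_anchor(model, anchors.lrr_anchor)
    i_hr = resolve_anchor(model, anchors.hr_anchor)
    i_tm = resolve_anchor(model, anchors.tm_anchor)
    i_tm_hr = (i_tm if anchors.tm_hr_anchor is None
               else resolve_anchor(model, anchors.tm_hr_anchor))
    X = traj.coordinates

    def dist(a: int, b: int) -> np.ndarray:
        return np.linalg.norm(X[:, a] - X[:, b], axis=1)

    return DistanceSeries(lrr_hr=dist(i_lrr, i_hr), lrr_tm=dist(i_lrr, i_tm),
                          tm_hr=dist(i_tm_hr, i_hr), times=traj.times,
                          anchors=anchors)


def pairwise_correlation(series: DistanceSeries) -> dict[tuple[str, str], float]:
    """Pearson correlation for each of the three distance-pair combinations.

    Requires at least 3 frames and non-constant series (the correlation of a
    constant series is undefined).
    """
    if series.n_frames < 3:
        raise ValueError("need at least 3 frames for a correlation")
    out = {}
    pairs = (("lrr_hr", "lrr_tm"), ("lrr_hr", "tm_hr"), ("lrr_tm", "tm_hr"))
    for a, b in pairs:
        xa, xb = series.pair(a), series.pair(b)
        if np.ptp(xa) == 0 or np.ptp(xb) == 0:
            raise ValueError(f"distance series {a if np.ptp(xa) == 0 else b} is "
                             "constant; correlation undefined")
        out[(a, b)] = float(stats.pearsonr(xa, xb).statistic)
    return out


def kink_angle(traj_or_structure, spec: KinkSpec) -> KinkSeries:
    """Angle between the upper- and lower-half axis vectors of a helix.

    Both vectors point up the helix (second pair member -> first), so a
    straight helix reads ~0 deg. The absolute angle lies in [0, 180];
    :attr:`KinkSeries.relative` reports it against the crystal reference.
    """
    traj = _as_ensemble(traj_or_structure)
    model = traj.atom_table

    def ca(entry: tuple[str | None, int]) -> int:
        return resolve_anchor(model, (entry[0], entry[1], "CA"))

    iu0, iu1 = ca(spec.upper_pair[0]), ca(spec.upper_pair[1])
    il0, il1 = ca(spec.lower_pair[0]), ca(spec.lower_pair[1])
    X = traj.coordinates
    upper = X[:, iu0] - X[:, iu1]
    lower = X[:, il0] - X[:, il1]
    nu = np.linalg.norm(upper, axis=1)
    nl = np.linalg.norm(lower, axis=1)
    if np.any(nu == 0) or np.any(nl == 0):
        raise GeometryError("zero-length helix axis vector in kink calculation")
    cosang = np.clip(np.sum(upper * lower, axis=1) / (nu * nl), -1.0, 1.0)
    return KinkSeries(angles=np.degrees(np.arccos(cosang)), spec=spec,
                      times=traj.times)


def cluster_distance_map(assignment: ClusterAssignment, series: DistanceSeries,
                         cluster_ids=None) -> dict:
    """Per-cluster distance subsets, summary stats and pairwise overlaps.

    ``assignment`` frames must index into ``series`` frames (the series must
    cover the trajectory the matrix was built from). Returns a dict with
    ``subsets`` (cluster id -> DistanceSeries), ``table`` (min/max/mean per
    pair per cluster) and ``overlap`` (cluster-pair -> shared bounding-box
    volume fraction in (lrr_hr, lrr_tm, tm_hr) space, intersection over
    union of the two boxes).
    """
    if assignment.frame_indices.max() >= series.n_frames:
        raise ValueError("cluster assignment frames exceed the distance series")
    ids = ([c.id for c in assignment.clusters] if cluster_ids is None
           else list(cluster_ids))
    subsets: dict[int, DistanceSeries] = {}
    rows = []
    boxes = {}
    for cid in ids:
        members = assignment.members(cid)
        sub = series.subset(members)
        subsets[cid] = sub
        if sub.n_frames == 0:
            continue
        lo = np.array([sub.pair(p).min() for p in PAIR_LABELS])
        hi = np.array([sub.pair(p).max() for p in PAIR_LABELS])
        boxes[cid] = (lo, hi)
        for p in PAIR_LABELS:
            vals = sub.pair(p)
            rows.append({"cluster_id": cid, "pair": p,
                         "min_A": vals.min(), "max_A": vals.max(),
                         "mean_A": vals.mean(), "n_frames": sub.n_frames})
    overlap = {}
    keys = sorted(boxes)
    for i, a in enumerate(keys):
        for b in keys[i + 1:]:
            lo = np.maximum(boxes[a][0], boxes[b][0])
            hi = np.minimum(boxes[a][1], boxes[b][1])
            inter = float(np.prod(np.clip(hi - lo, 0.0, None)))
            va = float(np.prod(boxes[a][1] - boxes[a][0]))
            vb = float(np.prod(boxes[b][1] - boxes[b][0]))
            union = va + vb - inter
            overlap[(a, b)] = inter / union if union > 0 else float(inter > 0)
    return {"subsets": subsets, "table": pd.DataFrame(rows), "overlap": overlap}


def range_summary(series: DistanceSeries) -> dict[str, tuple[float, float]]:
    """Exact (min, max) over all frames for each labelled distance pair."""
    if series.n_frames == 0:
        raise ValueError("empty distance series")
    return {p: (float(series.pair(p).min()), float(series.pair(p).max()))
            for p in PAIR_LABELS}
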