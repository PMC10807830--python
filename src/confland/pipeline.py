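"""End-to-end orchestration of the conformational-landscape analysis.

:func:`run_pipeline` executes, from a single :class:`AnalysisConfig`:
domain distances -> correlations -> TM-fitted RMSD series and matrix ->
threshold clustering -> essential dynamics -> projections, distributions
and cluster-conditioned maps -> TM6 kink series -> (optional) membrane
density and box profiles, writing unit-labelled CSVs, optional plots and a
machine-readable JSON summary. Reruns with the same config and inputs are
deterministic.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clustering as cl
from . import essential_dynamics as ed
from . import membrane_profile as mp
from . import reaction_coordinates as rc
from . import structure_io as sio
from . import superposition as sup

log = logging.getLogger("confland")

__all__ = ["AnalysisConfig", "run_pipeline"]


@dataclasses.dataclass
class AnalysisConfig:
    """Flat, YAML-compatible configuration of a full analysis run."""

    structure_path: str = ""
    trajectory_path: str = ""
    out_dir: str = "confland_out"
    receptor: str = "fshr"              # geometry preset name
    geometry_config: str | None = None  # optional YAML overriding the preset
    structure_format: str | None = None
    trajectory_format: str | None = None
    chain: str | None = None            # override the preset chain
    frame_interval_ps: float = 10.0
    stride: int = 1                     # stride applied at trajectory read
    matrix_stride: int = 1              # extra stride for the RMSD matrix
    cluster_cutoff: float = 0.5         # Angstrom
    pca_exclude_ns: float = 20.0
    pca_components: int = 4
    projection_bin_width: float = 1.0   # Angstrom, for PC distributions
    density: bool = False
    density_bin_width: float = 1.0
    box_burn_in_ns: float = 50.0
    make_plots: bool = True
    seed: int = 0                       # for any stochastic utility
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self),
                                             sort_keys=False))

    def validate(self, check_paths: bool = True) -> None:
        if self.cluster_cutoff <= 0:
            raise ValueError("cluster_cutoff must be > 0")
        if self.stride < 1 or self.matrix_stride < 1:
            raise ValueError("strides must be >= 1")
        if self.pca_components < 1:
            raise ValueError("pca_components must be >= 1")
        if check_paths:
            for p in (self.structure_path, self.trajectory_path):
                if not p or not Path(p).exists():
                    raise FileNotFoundError(f"input path not found: {p!r}")


def _stage(name: str):
    log.info("=== stage: %s ===", name)


def run_pipeline(config: AnalysisConfig) -> dict:
    """Run every analysis stage and write the report bundle.

    Returns the summary dict (also written to ``summary.json``). Any stage
    failure raises with the stage named in the log; outputs written by
    earlier stages are preserved.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO),
                        format="%(asctime)s %(name)s %(levelname)s %(message)s")
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    _stage("load inputs")
    geometry = sio.load_receptor_geometry(config.receptor, config.geometry_config)
    if config.chain is not None:
        geometry = dataclasses.replace(
            geometry, chain=config.chain,
            tm_selection=dataclasses.replace(geometry.tm_selection,
                                             chain_id=config.chain))
    structure = sio.read_structure(config.structure_path, config.structure_format)
    traj = sio.read_trajectory(structure, config.trajectory_path,
                               fmt=config.trajectory_format,
                               stride=config.stride,
                               frame_interval_ps=config.frame_interval_ps)
    log.info("trajectory: %d frames, %d atoms", traj.n_frames, traj.n_atoms)
    tm_idx = sio.resolve_selection(structure, geometry.tm_selection)
    ca_idx = sio.resolve_selection(structure, sio.SelectionSpec(
        name="all_ca", residue_ranges=((int(structure.residue_number.min()),
                                        int(structure.residue_number.max())),),
        chain_id=geometry.chain))
    summary: dict = {"receptor": geometry.name, "n_frames": traj.n_frames,
                     "n_atoms": traj.n_atoms, "n_tm_atoms": int(tm_idx.size)}

    _stage("domain distances and correlations")
    distances = rc.domain_distances(traj, geometry.anchors)
    distances.to_csv(out / "distances.csv")
    correlations = rc.pairwise_correlation(distances)
    summary["distance_correlations"] = {f"{a}__{b}": round(v, 4)
                                        for (a, b), v in correlations.items()}
    summary["distance_ranges_A"] = {p: [round(v, 2) for v in r]
                                    for p, r in rc.range_summary(distances).items()}

    _stage("RMSD series and matrix")
    series = sup.rmsd_series(traj, tm_idx, reference=0)
    pd.DataFrame({"time_ps": traj.times, "rmsd_A": series}).to_csv(
        out / "rmsd_series.csv", index=False)
    matrix = sup.rmsd_matrix(traj, tm_idx, stride=config.matrix_stride,
                             fit_name=geometry.tm_selection.name)
    matrix.to_csv(out / "rmsd_matrix.csv")
    summary["rmsd_max_A"] = round(float(matrix.values.max()), 3)
    log.info("matrix: %d frames, max %.2f A", matrix.n_frames, matrix.values.max())

    _stage("threshold clustering")
    assignment = cl.threshold_cluster(matrix, config.cluster_cutoff)
    assignment.to_csv(out / "clusters.csv", times=matrix.times)
    report = cl.cluster_report(assignment, matrix.times)
    report.to_csv(out / "cluster_segments.csv", index=False)
    summary["n_clusters"] = assignment.n_clusters
    summary["largest_cluster"] = {
        "id": int(max(assignment.clusters, key=lambda c: c.size).id),
        "size": int(max(assignment.clusters, key=lambda c: c.size).size)}

    _stage("essential dynamics")
    decomp = ed.covariance_analysis(
        traj, tm_idx, ca_idx, exclude_leading_ps=config.pca_exclude_ns * 1000.0,
        fit_name=geometry.tm_selection.name, analysis_name="all_ca")
    decomp.to_frame(k=15).to_csv(out / "eigen.csv", index=False)
    k = min(config.pca_components, decomp.eigenvalues.size)
    summary["fluctuation_fractions"] = {
        f"pc1_to_pc{i}": round(ed.fluctuation_fraction(decomp, i), 4)
        for i in range(1, k + 1)}
    projections = ed.project(traj, decomp, components=range(1, k + 1),
                             source=geometry.name)
    projections.to_csv(out / "projections.csv")
    ed.porcupine_frame(decomp, 1).to_csv(out / "porcupine_pc1.csv", index=False)

    _stage("cluster-conditioned maps")
    cluster_proj = ed.cluster_projection(assignment, projections,
                                         bin_width=config.projection_bin_width)
    summary["cluster_modes_at_maxima"] = {
        str(cid): {f"pc{c}": info["modes"][c]["at_distribution_maximum"]
                   for c in projections.components}
        for cid, info in cluster_proj.items()}
    dist_map = rc.cluster_distance_map(assignment, distances)
    dist_map["table"].to_csv(out / "cluster_distances.csv", index=False)

    _stage("TM6 kink angle")
    kink = rc.kink_angle(traj, geometry.kink)
    kink.to_csv(out / "kink.csv")
    summary["kink_mean_deg"] = round(float(kink.angles.mean()), 2)
    summary["kink_relative_mean_deg"] = round(float(kink.relative.mean()), 2)

    if config.density:
        _stage("membrane density and box profile")
        profile = mp.density_profile(traj, bin_width=config.density_bin_width)
        profile.to_csv(out / "density.csv")
        boxes = mp.box_series(traj, burn_in_ps=config.box_burn_in_ns * 1000.0)
        boxes.to_csv(out / "box.csv", index=False)

    if config.make_plots:
        _stage("plots")
        from . import plotting
        plotting.plot_rmsd_matrix(matrix, out / "rmsd_matrix.png")
        plotting.plot_cluster_timeline(assignment, matrix.times,
                                       out / "clusters.png")
        plotting.plot_distance_scatter(distances, out / "distances.png")
        plotting.plot_projection_distributions(
            projections, out / "projections.png",
            bin_width=config.projection_bin_width)

    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    log.info("pipeline complete; summary written to %s", out / "summary.json")
    return summary
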