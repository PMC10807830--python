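"""The whole analysis from files on disk, the way a receptor study runs it.

Writes a synthetic fixture set (receptor PDB, DCD trajectory, ground-truth
labels), then runs the full pipeline from an AnalysisConfig -- distances,
correlations, RMSD matrix, clustering, essential dynamics, cluster maps
and the kink series -- and prints the machine-readable summary. The same
run is available from the shell as
``confland run --config <yaml>`` after ``confland simulate``.
"""

import json
import tempfile
from pathlib import Path

import confland as c
from confland import synthetic_data as syn
from confland.pipeline import AnalysisConfig

workdir = Path(tempfile.mkdtemp(prefix="confland_example_"))
receptor = c.generate_toy_receptor()
spec = c.SyntheticSpec(n_frames=300, seed=5)
traj, labels = c.generate_trajectory(receptor, spec)
paths = syn.write_fixture_set(workdir / "fixture", receptor, traj, labels)

config = AnalysisConfig(
    structure_path=str(paths["structure"]),
    trajectory_path=str(paths["trajectory"]),
    out_dir=str(workdir / "analysis"),
    receptor="fshr",
    cluster_cutoff=1.0,      # Å; 0.5 Å is the production choice for real TM bundles
    matrix_stride=2,
    pca_exclude_ns=0.2,      # 20 frames of burn-in at 10 ps
    make_plots=False,
)
summary = c.run_pipeline(config)

print(json.dumps(summary, indent=2))
print(f"\nCSV outputs in {config.out_dir}:")
for path in sorted(Path(config.out_dir).iterdir()):
    print(f"  {path.name}")
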