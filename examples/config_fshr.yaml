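# Production analysis preset for the follitropin receptor (AlphaFold
# AF-P23945 conventions, 695 residues, single chain). Point the two paths
# at your structure and backbone trajectory, then:
#   confland run --config config_fshr.yaml
structure_path: fshr_model.pdb        # AF-P23945 model (or any PDB/mmCIF)
trajectory_path: fshr_r1_backbone.dcd # backbone trajectory, 10 ps frames
out_dir: fshr_r1_analysis
receptor: fshr
frame_interval_ps: 10.0
matrix_stride: 1          # raise so the matrix stays <= ~2000 frames
cluster_cutoff: 0.5       # Angstrom; 1.0 merges everything into one cluster
pca_exclude_ns: 20.0      # equilibration excluded from the covariance
pca_components: 4
projection_bin_width: 1.0 # Angstrom
density: false            # enable for full-system trajectories with a box
box_burn_in_ns: 50.0
make_plots: true
seed: 0
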