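# Production analysis preset for the lutropin/choriogonadotropin receptor
# (cryo-EM structure PDB 7FII, chain R conventions).
structure_path: 7fii.pdb
trajectory_path: lhcgr_r1_backbone.dcd
out_dir: lhcgr_r1_analysis
receptor: lhcgr           # chain R, TM helices 360-625, kink reference 37 deg
frame_interval_ps: 10.0
matrix_stride: 1
cluster_cutoff: 0.5
pca_exclude_ns: 20.0
pca_components: 4
projection_bin_width: 1.0
density: false
box_burn_in_ns: 50.0
make_plots: true
seed: 0
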