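# confland

Conformational-landscape analysis for G-protein-coupled receptor molecular
dynamics trajectories, built around the glycoprotein hormone receptors
(FSHR, LHCGR): domain-anchor reaction coordinates, pairwise-fitted RMSD
matrices, threshold-membership clustering, Cα essential dynamics, TM6 kink
angles and membrane density profiles — plus a ground-truth-labelled
synthetic multi-state trajectory generator so every stage is testable
without downloading a single trajectory.

## Who this is for

Researchers analysing MD trajectories of the gonadotropin receptors (or any
multi-domain membrane receptor) who want the full chain from raw
coordinates to "which conformational states exist, how are they populated,
and along which coordinates do they interconvert" as a reproducible,
scriptable pipeline rather than a pile of one-off VMD/GROMACS invocations.

## What it computes

These receptors have three structural modules: a leucine-rich-repeat
ectodomain (LRR), a flexible hinge region (HR) and a seven-helix
transmembrane bundle (TM). The package tracks their relative motion through:

- **Domain-anchor distances** `d(LRR,HR)`, `d(LRR,TM)`, `d(TM,HR)` between
  single anchor Cα atoms (FSHR: L31 / Y303 / L460; LHCGR: S55 / C304 /
  I431·L452), measured on raw internal coordinates, with pairwise Pearson
  correlations to expose concerted motions.
- **Pairwise-fitted RMSD matrices**: for every frame pair *(t, t+Δt)* the
  TM-helix Cαs are superposed by a Kabsch fit (SVD solution of the
  orthogonal Procrustes problem, reflections excluded) before the RMSD is
  measured; dark blocks reveal self-similar conformational epochs.
- **Threshold-membership clustering**: a frame joins a cluster when its
  RMSD to *any* member is below the cutoff (0.5 Å in production use).
  The implementation computes the order-independent closure — connected
  components of the sub-cutoff graph — so results are deterministic.
- **Essential dynamics**: eigendecomposition of the Cα covariance
  `C = ⟨(x−⟨x⟩)(x−⟨x⟩)ᵀ⟩` after fitting on the TM group, with projections
  `p_k(t) = v_k·(x(t)−⟨x⟩)`, their histograms and local maxima,
  cross-replicate and cluster-conditioned projections, and porcupine
  displacement vectors `scale·√λ_k·v_k` per atom.
- **TM6 kink angle**: the angle between upper- and lower-half axis vectors
  of helix 6 defined by two Cα pairs, reported relative to the crystal
  reference (44° FSHR, 37° LHCGR).
- **Membrane profiles**: group number/mass densities along the bilayer
  normal (water, lipid tails, phosphate, protein) and box-dimension
  monitoring with a post-burn-in running mean.

The synthetic generator builds a 695-residue Cα pseudo-receptor with FSHR
numbering, simulates Markov switching between discrete conformational
states (rigid domain displacements + a TM distortion of controlled fitted
RMSD + thermal noise + global rigid jitter) and emits labelled
PDB/DCD/CSV fixtures.

## Worked example

```bash
python examples/01_domain_distances.py
```

```
anchor distances, frame 0 (Å):
  lrr_hr: 74.7
  lrr_tm: 115.8
  tm_hr: 65.8

observed ranges over the trajectory (Å):
  lrr_hr: 67.6 .. 75.3
  lrr_tm: 107.1 .. 116.4
  tm_hr: 59.4 .. 67.0

pairwise Pearson correlations:
  corr(lrr_hr, lrr_tm) = +0.995
  corr(lrr_hr, tm_hr) = +0.987
  corr(lrr_tm, tm_hr) = +0.995
```

The two imposed conformational states of the synthetic trajectory shift all
three inter-domain distances together, so the correlations are strongly
positive — the same signature a concerted LRR/HR motion relative to the
membrane leaves in a real trajectory. Clustering the TM-fitted RMSD matrix
of the same system (`examples/02_rmsd_matrix_clustering.py`) finds exactly
the two hidden states:

```
RMSD matrix: 400 frames, max 2.12 Å (TM helices, pairwise fitted)
cutoff 1.00 Å -> 2 cluster(s)
cutoff 0.25 Å -> 400 cluster(s)
agreement with hidden state labels at 1.0 Å: 100.0%
```

The other examples cover essential dynamics (`03`), kink angles (`04`),
membrane profiles (`05`) and the full file-based pipeline (`06`). From the
shell, the same pipeline runs as

```bash
confland simulate --seed 7 --frames 500 --out fixture
confland run --config examples/config_fshr.yaml
```

writing `distances.csv`, `rmsd_matrix.csv`, `clusters.csv`, `eigen.csv`,
`projections.csv`, `kink.csv` and `summary.json` into the output directory.

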