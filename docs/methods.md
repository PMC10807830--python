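# Methods

This note records the models, conventions and numerical choices behind
`confland`, and what the synthetic test battery does and does not show
about real trajectories.

## Coordinate model and units

Everything internal is Ångström, picoseconds and degrees; variances are
Å². Projections can be exported in nm (receptor studies often plot PC axes
in nm). Residue numbers are author numbers from the input file, never
renumbered, so field labels such as Y303 or L460 apply directly. Anchor
and kink atoms default to Cα, consistent with every analysis in the
package being Cα-based. Trajectory frames without time stamps (DCD,
multi-model PDB) are assigned `index × 10 ps`, the storage interval of the
receptor trajectories this pipeline targets; XTC times are taken from the
file. Altloc duplicates keep the highest-occupancy record.

## Rigid-body fitting

`kabsch_fit` solves the weighted orthogonal Procrustes problem by SVD of
the cross-covariance, flipping the smallest singular vector when the
unconstrained optimum is a reflection, so the returned matrix is always a
proper rotation. Point sets with fewer than three points or rank < 2
(collinear) raise a geometry error: the rotation is not determined there.
Fitting is mass-unweighted by default (per-atom weights are accepted); the
receptor analyses this package reproduces never state mass weighting.

## Pairwise-fitted RMSD matrices

Entry *(i, j)* superposes frame *j* onto frame *i* on the fit selection
(the TM-helix Cαs) and measures the RMSD on the measure selection (default:
the fit group). Each pair is fitted independently — not to a common
reference — which is what makes blocks of mutual similarity visible.
Because the optimal superposition of *j* onto *i* is the inverse of that of
*i* onto *j*, the measured RMSD is symmetric exactly; the implementation
computes the upper triangle and mirrors it, which coincides with
symmetrisation by averaging. Memory is O(n²) floats per matrix; the
`matrix_stride` config key is the intended way to keep n at or below ~2000
frames.

## Threshold-membership clustering

The production rule — "a structure joins a cluster when its RMSD to any
member is below the cutoff" — is order-dependent as stated. The package
implements its transitive closure: connected components of the graph with
an edge where RMSD < cutoff (strict inequality; boundary equality
excluded). The closure is deterministic, order-independent, and contains
every incremental result; this disambiguation is deliberate. Cluster ids
are the earliest member frame index (zero-padded in display); published
cluster labels of the original analyses use an undocumented numbering that
is not guessed here. The medoid minimises summed RMSD to co-members, ties
broken by earliest frame. Cluster count is non-increasing in the cutoff,
which the suite asserts across random matrices.

## Essential dynamics

The covariance of the analysis-selection Cα coordinates (all Cαs by
default) is built after a two-pass fit on the fit selection (the TM
bundle): fit all frames to the first retained frame, form the mean, refit
the original frames to that mean, then accumulate
`C = (1/F) Σ (x−μ)(x−μ)ᵀ` over the flattened 3N coordinates. The stored
superposition target is the pass-2 target itself, so later projections
reproduce the covariance fitting exactly and the source trajectory's
projections are mean-free to rounding. Frames earlier than 20 ns
(configurable) are excluded from the covariance only; projections are
computed for all frames, including cross-replicate projections onto another
replicate's eigenvectors. A dense symmetric eigensolver is used — for
receptors of ~700 residues, 3N ≈ 2100 is desk-scale. Eigenvector signs are
fixed by making each vector's largest-magnitude entry positive (signs are
otherwise arbitrary). Degenerate inputs: a rigid trajectory yields an
all-zero spectrum, and a constant projection series has no distribution
(hard error rather than a fabricated histogram).

Distribution maxima are bins whose 3-bin moving-averaged density exceeds
both neighbours; edge bins qualify when they exceed their single inner
neighbour, so a state sitting at the range limit is still reported.

## Reaction coordinates

Domain distances are raw Euclidean distances between single anchor Cαs —
internal coordinates need no superposition, and the suite asserts rigid
invariance. Correlations are Pearson (the originating analyses show linear
trend plots), computed over the full series with no leading exclusion. The
LHCGR geometry carries two TM anchors exactly as published (I431 for
LRR-TM, L452 for TM-HR) and warns that they differ. The FSHR kink
quadruplet uses M585 for the upper pair: the published supplementary lists
an atom (M858) that does not exist in a 695-residue receptor, and the
body text places the kink between M585 and D581, which is the only
consistent reading.

The kink angle is the angle between two axis vectors, each through a Cα
pair, both pointing up the helix. On an *ideal* straight helix a pair
spanning a non-integral number of turns carries a radial phase component,
so the toy receptor's FSHR quadruplet reads ~20° rather than 0°; this
offset is constant and cancels in relative angles, and pairs spanning
whole turns (18 residues = 5 turns at 100°/residue) read 0° exactly, which
the suite checks. Analytic bend constructions are recovered to < 1e-9°.

## Membrane profiles

Densities are per-frame histograms along the chosen axis divided by the
per-frame bin volume (box_x × box_y × bin_width) and averaged; number
density (atoms/Å³) is the default with a mass-density toggle. Bin width
defaults to 1 Å. Midplane centering uses the per-frame mean coordinate of
the lipid-tail group. The default group dictionary (water / tails /
phosphate / protein atom-name patterns) is this package's own,
CHARMM-flavoured, and fully configurable — published profiles rarely
enumerate their exact groupings. Number conservation (profile integral =
group atom count) holds exactly as long as all atoms fall inside the grid,
which the grid construction guarantees. Box monitoring reports xy area and
z height with a running mean after a 50 ns burn-in (configurable), the
horizon after which lipid areas are typically stable.

## The synthetic generator

The generator emulates the statistical structure the analyses assume — and
only that:

- a Cα-only three-domain pseudo-receptor with FSHR numbering (LRR solenoid,
  hinge loop with an ideal 11-residue helix around the Y303 anchor, seven
  ideal TM helices of 1.5 Å rise and 100°/residue on a 10 Å circle), so the
  shipped FSHR selection config resolves against it unchanged;
- discrete conformational states: rigid per-domain displacements plus an
  internal TM distortion whose Kabsch-fitted RMSD on the helix selection is
  calibrated to a target (rigid-body components of the random field are
  projected out by iterative rescaling, converged to 1e-9 Å);
- discrete-time Markov switching between states (chosen over rate-based
  kinetics; the 10 ps frame interval makes dwell frames ≈ dwell time);
- isotropic Gaussian thermal noise per atom, and a global random rigid
  motion per frame (default on) so superposition is genuinely exercised;
- a slab membrane box: lipid tails |z| < 15 Å, phosphate shells at
  |z| ≈ 19 Å, water beyond 21 Å.

Default conditions are two states with ~6–10 Å concerted shifts in all
three anchor distances, a 2.0 Å inter-state TM RMSD, σ = 0.2 Å noise,
100-frame mean dwells and 2000 frames at 10 ps — separations and
amplitudes in the range equilibrium receptor trajectories show (TM RMSD
below ~3 Å, domain distances fluctuating over tens of Å). Everything is
deterministic under the spec seed (per-purpose child streams of a seed
sequence), and the suite asserts bit-identical regeneration.

What passing on synthetic data does **not** show: the generator has no
force field, no solvent or membrane dynamics, no gradual drift within a
state, no helix unwinding — states are exactly Gaussian and exactly
Markovian. Recovery results therefore validate the *machinery*
(superposition, clustering closure, spectral conservation, bookkeeping),
not the scientific interpretation of any particular real trajectory.

## Problem sizes and verification battery

The test suite runs the unit and property checks at 100–500 frames; the
end-to-end recovery conditions (2000 frames, 2.0 Å TM separation,
σ = 0.2 Å) are exercised in the acceptance tests and in
`scripts/acceptance.py`, which recomputes from scratch: the Kabsch oracle
(100 random rigid motions; worst fitted RMSD and rotation error at machine
precision), the clustering-vs-closure oracle (50 random matrices, exact
agreement, monotone cutoff scans), spectral conservation (trace, Parseval,
3N-component reconstruction), two-state recovery (clustering ARI, PC1
midpoint separation, imposed-vs-measured distance correlations, exact 30°
kink) and density conservation. The RMSD matrix in the script is computed
at full 2000-frame resolution (~4M fitted pairs, vectorised batched SVD).

## Known limitations

- No sequence alignment: residue correspondence is by author number only.
- No tICA/Markov-state modelling, free-energy surfaces beyond histograms,
  area-per-lipid or acyl order parameters, or leaflet assignment.
- mmCIF is read but not written.
- PDB round trips are exact to the format's fixed width (1e-3 Å); DCD to
  single precision (~1e-5 Å relative to typical coordinates).
- Two-letter element symbols without an explicit element column fall back
  to a first-letter guess (fine for protein/lipid atoms, wrong for bare
  metal ions named like CA).
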