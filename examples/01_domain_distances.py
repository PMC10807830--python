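"""Domain-anchor reaction coordinates on a synthetic two-state trajectory.

Builds the toy receptor, simulates a short labelled trajectory, measures
the three inter-domain anchor distances (LRR-HR, LRR-TM, TM-HR) and their
pairwise Pearson correlations. Positive correlation between LRR-TM and
TM-HR means the extracellular domains move concertedly relative to the
membrane-embedded bundle.
"""

import confland as c
from confland import reaction_coordinates as rc

receptor = c.generate_toy_receptor()
geometry = c.load_receptor_geometry("fshr")
spec = c.SyntheticSpec(n_frames=500, seed=1)
traj, labels = c.generate_trajectory(receptor, spec)

series = c.domain_distances(traj, geometry.anchors)
print("anchor distances, frame 0 (Å):")
for pair in rc.PAIR_LABELS:
    print(f"  {pair}: {series.pair(pair)[0]:.1f}")

print("\nobserved ranges over the trajectory (Å):")
for pair, (lo, hi) in c.range_summary(series).items():
    print(f"  {pair}: {lo:.1f} .. {hi:.1f}")

print("\npairwise Pearson correlations:")
for (a, b), r in c.pairwise_correlation(series).items():
    print(f"  corr({a}, {b}) = {r:+.3f}")
print("\nThe two imposed conformational states shift all three distances "
      "together, hence the strong positive correlations.")
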