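"""Density profile along the bilayer normal of a slab-structured box.

The synthetic membrane places lipid-tail pseudo-atoms in |z| < 15 Å,
phosphate shells near |z| ~ 19 Å and water beyond 21 Å. The profile
recovers that layering: water vanishes in the hydrophobic core, phosphate
peaks flank it, and each group's integral returns its constructed atom
count (number conservation).
"""

import numpy as np

import confland as c

model, traj = c.generate_membrane_box(n_lipid_sites=3000, n_water=3000,
                                      box=(60.0, 60.0, 84.0), seed=4)
profile = c.density_profile(traj, bin_width=1.0)

area = traj.box[0, 0] * traj.box[0, 1]
print("group        atoms   integral(atoms)   peak density (atoms/Å³)")
for group, count in profile.group_counts.items():
    if count == 0:
        continue
    integral = profile.integral(group, area)
    print(f"{group:<12} {count:>5}   {integral:>12.3f}   "
          f"{profile.densities[group].max():.4f}")

z = profile.bin_centers
water = profile.densities["water"]
phos = profile.densities["phosphate"]
print(f"\nwater density for |z| < 10 Å: {water[np.abs(z) < 10].max():.4f}")
print(f"phosphate peaks at z = {z[z > 0][np.argmax(phos[z > 0])]:+.1f} "
      f"and {z[z < 0][np.argmax(phos[z < 0])]:+.1f} Å")

boxes = c.box_series(traj, burn_in_ps=0.0)
print(f"box area {boxes['area_xy_A2'].iloc[0]:.0f} Å², "
      f"height {boxes['height_z_A'].iloc[0]:.0f} Å")
print("\nThe zero water density in the core and the two phosphate shells "
      "reproduce the layering a well-equilibrated bilayer shows.")
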