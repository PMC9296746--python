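"""Build a small dataset of heterogeneous activity phantoms.

Generates a 10-entry manifest with the reference category proportions,
voxelizes each activity mask on the desk lattice and prints what was
made.  Values 0-100 are relative activity; each mask also carries the
maximum activity concentration (MBq/mL) it will be scaled to.
"""

import numpy as np

from spectsynth import (build_activity_mask, build_manifest,
                        cylinder_support, get_preset, scale_composition)

grid = get_preset("desk")
support = cylinder_support(grid)
manifest = build_manifest(scale_composition(10), seed=42,
                          split_fractions=(0.8, 0.1, 0.1))

print(f"lattice {grid.n}^3 @ {grid.voxel_size_mm} mm, cylinder "
      f"{grid.cylinder_diameter_mm:.0f} x {grid.cylinder_length_mm:.0f} mm")
print(f"{'id':8s} {'category':12s} {'max MBq/mL':>10s} {'active':>7s} "
      f"{'shapes':>6s}")
for row in manifest.itertuples():
    mask = build_activity_mask(row, grid, support)
    active = int((mask.grid > 0).sum())
    print(f"{row.id:8s} {row.category:12s} {row.max_conc_mbq_ml:10.2f} "
          f"{active:7d} {len(mask.shape_voxel_counts):6d}")

# 'active' counts voxels carrying activity (all inside the cylinder);
# 'shapes' is the number of placed random shapes (0 for patterns).
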