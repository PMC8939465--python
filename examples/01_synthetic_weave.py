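"""Generate a synthetic plain-weave fabric patch and inspect its geometry.

Builds a periodic 2x2-unit-cell weave of interlaced yarns with a few stray
fibers bridging the inter-yarn pores, then prints the summary statistics
used to match generated fabric to imaged fabric.
"""

import numpy as np

import weavefilter as wf

spec = wf.FabricSpec(rng_seed=0)   # defaults: 297 x 252 um lattice, 1.8 um voxels
print(f"threads per inch of this lattice: "
      f"{wf.threads_per_inch(spec.lattice_constant_x, spec.lattice_constant_y)}")

# A coarser voxel pitch keeps this demo fast; the geometry is the same weave.
from dataclasses import replace
spec = replace(spec, lattice_constant_x=160.0, lattice_constant_y=160.0,
               yarn_width=110.0, yarn_thickness=36.0, fabric_thickness=72.0,
               voxel_pitch=4.0, target_solid_fraction=0.6)
grid = wf.generate_plain_weave(spec)
alpha, mean_alpha = wf.porosity_profile(grid)

print(f"grid shape (voxels): {grid.shape}, voxel pitch {grid.voxel_pitch} um")
print(f"fabric slices: {grid.fabric_z_range}, "
      f"thickness {grid.fabric_thickness_um:.1f} um")
print(f"solid fraction inside fabric: {grid.solid_fraction():.3f} "
      f"(target {spec.target_solid_fraction})")
print(f"peak slice solid fraction alpha(z): {alpha.max():.3f}")
# The solid fraction profile alpha(z) rises from 0 in the air padding to a
# plateau inside the fabric; its plateau mean is what an imaged fabric's
# porosity profile is matched against.
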