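"""Segment lymphoid follicles, recover their volumes and spacing statistics.

Renders four spherical follicles with analytic volumes spanning 1-5 million
um^3 (the physiological ILF range) at 5 um voxels, segments them by
smoothing + thresholding + 26-connected labelling, and compares measured
volumes and centroid spacing against the ground truth.
"""

import math

import numpy as np

from gutopt import (
    FollicleSpec, PhantomSpec, follicle_stats, make_gut_phantom, segment_follicles,
)

analytic = [1e6, 2e6, 3e6, 5e6]
radii = [(3 * v / (4 * math.pi)) ** (1 / 3) for v in analytic]
follicles = [FollicleSpec((400.0 + 500.0 * k, 240.0, 240.0), (r, r, r))
             for k, r in enumerate(radii)]
spec = PhantomSpec(
    grid_shape=(560, 96, 96), voxel_size_um=5.0,
    lumen_radius_um=60.0, mucosa_outer_radius_um=150.0,
    submucosa_outer_radius_um=190.0, muscularis_outer_radius_um=220.0,
    follicle_specs=follicles, rng_seed=0,
)
_, marker, truth = make_gut_phantom(spec)

table = segment_follicles(marker, intensity_threshold=0.5,
                          smoothing_sigma_um=2.0, min_voxels=10)
measured = table.table.sort_values("centroid_z_um")["volume_um3"].to_numpy()
for m, a in zip(measured, analytic):
    print(f"analytic {a / 1e6:.1f} Mum^3 -> measured {m / 1e6:.3f} Mum^3 "
          f"({100 * (m - a) / a:+.2f}%)")

stats = follicle_stats(table)
print(f"mean nearest-neighbour spacing: {stats.mean_nearest_neighbour_um:.1f} um "
      f"(follicles were placed 500 um apart)")
print(f"per-follicle min/mean/max distances:\n{stats.table.round(1)}")
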