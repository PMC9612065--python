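"""Generate a small synthetic forest stand and inspect its ground truth.

The generator emulates the products of a drone photogrammetry survey:
smooth terrain, paraboloid tree crowns rendered into a DSM, an RGB
orthomosaic with greener-than-ground crowns, and a GNSS-located field
survey of tree heights and DBH.
"""

import numpy as np

from dronecanopy import (generate_terrain, place_trees, render_dsm,
                         render_orthomosaic, simulate_field_survey)

extent = (0.0, 0.0, 40.0, 40.0)
terrain = generate_terrain(extent, pixel_size=0.1, relief_amplitude=2.0,
                           correlation_length=15.0, base_elevation=100.0, seed=1)
truth = place_trees(extent, n_trees=20, height_range=(10.0, 30.0),
                    crown_ratio=0.15, min_spacing=5.0, seed=2)
dsm = render_dsm(terrain, truth)
ortho = render_orthomosaic(terrain, truth, noise_sd=8.0, shadow_fraction=0.3, seed=3)
survey = simulate_field_survey(truth, gnss_sd=0.10, height_error_sd=0.5,
                               n_points=15, seed=4)

heights = [t.height_m for t in truth.trees]
print(f"scene: {dsm.shape[0]} x {dsm.shape[1]} px at {dsm.gsd:.2f} m GSD")
print(f"terrain relief: {terrain.values.max() - terrain.values.min():.2f} m")
print(f"{len(truth.trees)} trees, heights {min(heights):.1f}-{max(heights):.1f} m")
print(f"DSM above terrain by up to {np.max(dsm.values - terrain.values):.2f} m "
      "(tallest crown apex)")
print(f"field survey: {len(survey)} stems, all DBH >= 10 cm, "
      f"GNSS-perturbed positions (sd 0.10 m)")
# The DSM-terrain maximum approximates the tallest tree: crown apices encode
# true heights, which the CHM pipeline later recovers without seeing truth.
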