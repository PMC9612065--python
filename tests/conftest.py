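import numpy as np
import pytest

from dronecanopy import (Grid, GridTransform, generate_terrain, place_trees,
                         render_dsm, render_orthomosaic)


def make_grid(values, gsd=1.0, origin=(0.0, 0.0), crs="EPSG:32756", nodata=-9999.0):
    """Grid with top-left corner at ``origin`` and square pixels of ``gsd``."""
    values = np.asarray(values, dtype=np.float64)
    return Grid(values=values, transform=GridTransform(origin[0], origin[1], gsd, -gsd),
                crs=crs, nodata=nodata)


def truth_footprint(grid, truth):
    """Boolean union of true crown footprints (d <= crown radius)."""
    X, Y = grid.pixel_centres()
    out = np.zeros(grid.shape, dtype=bool)
    for t in truth.trees:
        out |= (X - t.x) ** 2 + (Y - t.y) ** 2 <= t.crown_radius_m ** 2
    return out


@pytest.fixture(scope="session")
def tiny_scene():
    """Noise-free 20 x 20 m stand of 5 trees at gsd 0.2 m."""
    extent = (0.0, 0.0, 20.0, 20.0)
    terrain = generate_terrain(extent, 0.2, relief_amplitude=1.0,
                               correlation_length=8.0, base_elevation=100.0, seed=11)
    truth = place_trees(extent, 5, (8.0, 15.0), 0.15, 4.0, seed=12)
    dsm = render_dsm(terrain, truth)
    ortho = render_orthomosaic(terrain, truth, noise_sd=0.0, shadow_fraction=0.0, seed=13)
    return {"extent": extent, "terrain": terrain, "truth": truth, "dsm": dsm, "ortho": ortho}
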