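"""Small helpers shared by the example scripts."""

import numpy as np

from dronecanopy import Grid, GridTransform, RGBOrthomosaic


def ortho_from_single_pixel(R: float, G: float, B: float) -> RGBOrthomosaic:
    t = GridTransform(0.0, 0.0, 1.0, -1.0)
    bands = [Grid(values=np.array([[v]]), transform=t, crs="EPSG:32756", nodata=None)
             for v in (R, G, B)]
    return RGBOrthomosaic(red=bands[0], green=bands[1], blue=bands[2])
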