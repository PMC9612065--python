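"""Band normalisation and the twelve RGB colour indices.

Raw digital numbers R, G, B are first normalised to band fractions

    r = R / (R + G + B),  g = G / (R + G + B),  b = B / (R + G + B)

so r + g + b = 1 at every valid pixel and all downstream indices become
invariant to uniform brightness scaling.  The twelve indices (VARI, ExG,
ExR, ExB, ExGR, NGRDI, NGBDI, MGRVI, WI, IKAW, GLA, RGBVI) are evaluated
pixelwise on the normalised fractions.  NGBDI, the green-blue normalised
difference (g - b)/(g + b), is the index used downstream to separate tree
crowns from ground.

Pixels where a formula's denominator vanishes (|den| < 1e-12) become
nodata rather than +/-inf, so thresholding never sees infinities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .raster import Grid, RGBOrthomosaic, grid_from_nan, require_aligned

DEN_EPS = 1e-12

#: Canonical index order (fixed).
INDEX_NAMES = ("VARI", "ExG", "ExR", "ExB", "ExGR", "NGRDI",
               "NGBDI", "MGRVI", "WI", "IKAW", "GLA", "RGBVI")


@dataclass
class NormalizedBands:
    """Aligned normalised band-fraction grids r, g, b."""

    r: Grid
    g: Grid
    b: Grid

    def __post_init__(self) -> None:
        require_aligned(self.r, self.g, self.b)

    @property
    def valid(self) -> np.ndarray:
        return self.r.valid & self.g.valid & self.b.valid


@dataclass
class IndexRaster:
    """One named colour-index raster."""

    name: str
    grid: Grid

    def __post_init__(self) -> None:
        if self.name not in INDEX_NAMES:
            raise ValueError(f"unknown index {self.name!r}; expected one of {INDEX_NAMES}")


def normalize_bands(image: RGBOrthomosaic) -> NormalizedBands:
    """Normalise R, G, B digital numbers to band fractions.

    Zero-sum pixels (R + G + B = 0) and pixels that are nodata in any input
    band are nodata in all three outputs.
    """
    valid = image.red.valid & image.green.valid & image.blue.valid
    R = image.red.values.astype(np.float64)
    G = image.green.values.astype(np.float64)
    B = image.blue.values.astype(np.float64)
    total = R + G + B
    ok = valid & (total > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(ok, R / total, np.nan)
        g = np.where(ok, G / total, np.nan)
        b = np.where(ok, B / total, np.nan)
    template = image.red
    return NormalizedBands(
        r=grid_from_nan(r, template), g=grid_from_nan(g, template), b=grid_from_nan(b, template)
    )


def _ratio(num, den):
    out = np.where(np.abs(den) < DEN_EPS, np.nan, num / np.where(np.abs(den) < DEN_EPS, 1.0, den))
    return out


_FORMULAS = {
    "VARI":  lambda r, g, b: _ratio(g - r, g + r - b),
    "ExG":   lambda r, g, b: 2 * g - r - b,
    "ExR":   lambda r, g, b: 1.4 * r - g,
    "ExB":   lambda r, g, b: 1.4 * b - g,
    "ExGR":  lambda r, g, b: (2 * g - r - b) - (1.4 * r - g),
    "NGRDI": lambda r, g, b: _ratio(g - r, g + r),
    "NGBDI": lambda r, g, b: _ratio(g - b, g + b),
    "MGRVI": lambda r, g, b: _ratio(g ** 2 - r ** 2, g ** 2 + r ** 2),
    "WI":    lambda r, g, b: _ratio(g - b, r - g),
    "IKAW":  lambda r, g, b: _ratio(r - b, r + b),
    "GLA":   lambda r, g, b: _ratio(2 * g - r - b, 2 * g + r + b),
    "RGBVI": lambda r, g, b: _ratio(g ** 2 - b * r, g ** 2 + b * r),
}


def compute_index(bands: NormalizedBands, name: str) -> IndexRaster:
    """Evaluate one colour index pixelwise on normalised bands."""
    if name not in _FORMULAS:
        raise ValueError(f"unknown index {name!r}; expected one of {INDEX_NAMES}")
    valid = bands.valid
    r = np.where(valid, bands.r.values, np.nan)
    g = np.where(valid, bands.g.values, np.nan)
    b = np.where(valid, bands.b.values, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = _FORMULAS[name](r, g, b)
    return IndexRaster(name=name, grid=grid_from_nan(vals, bands.r))


def compute_all_indices(bands: NormalizedBands) -> list[IndexRaster]:
    """All twelve indices, in canonical order."""
    return [compute_index(bands, name) for name in INDEX_NAMES]
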