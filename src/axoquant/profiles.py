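"""Shaft-band excision, density binning, and mean profiles.

The central band of the straightened image (default 5 µm, the axonal shaft
itself) is flagged excluded so only collateral signal enters the profiles.
The mask (or intensity image) is then binned transversely into cells of
``bin_px`` columns × 1 row and converted to a density per µm²; cells are
tiled outward from the band edges so bin boundaries are registered to the
shaft across images, and leftover partial windows at the image edges are
dropped.  Transverse and longitudinal profiles are pooled cell means over
all rows (resp. bins) of all images of a group.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .collateral_mask import CollateralMask
from .straighten import StraightenedImage

__all__ = ["DensityGrid", "Profile", "StackSummary", "remove_shaft_band",
           "density_grid", "transverse_profile", "longitudinal_profile",
           "stack_and_project"]


@dataclass(frozen=True)
class DensityGrid:
    """Binned densities: rows = along-axon positions, columns = transverse bins."""

    values: np.ndarray        # density per µm² (collaterals or intensity)
    excluded: np.ndarray      # bool; excluded cells carry no value
    counts: np.ndarray        # raw per-cell sums (foreground px or intensity)
    bin_centers_um: np.ndarray  # signed offset of each bin center from shaft
    bin_width_x_um: float
    pixel_size_y: float
    cell_area_um2: float
    coverage: np.ndarray      # pixel-level bool: contributes to a kept cell

    @property
    def row_positions_um(self) -> np.ndarray:
        return np.arange(self.values.shape[0]) * self.pixel_size_y


@dataclass(frozen=True)
class Profile:
    """A 1D mean profile with the per-image profiles retained for statistics."""

    axis: str                 # 'transverse' | 'longitudinal'
    positions: np.ndarray     # µm
    values: np.ndarray        # pooled mean density per position
    source: str               # 'intensity' | 'mask'
    n_images: int
    per_image: np.ndarray     # (n_images, n_positions), NaN where no valid cell
    cell_counts: np.ndarray   # valid cells pooled per position

    def __post_init__(self):
        if len(self.positions) != len(self.values):
            raise ValueError("positions and values must align")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")


@dataclass(frozen=True)
class StackSummary:
    """Top-aligned group stack (sSTR/sMASK) with AVG and MAX projections."""

    stack: np.ndarray         # (n, rows, cols), padded with zeros
    valid: np.ndarray         # bool, False on padding/excluded pixels
    avg_projection: np.ndarray
    max_projection: np.ndarray


def remove_shaft_band(image, band_um: float = 5.0):
    """Flag the central ±``band_um``/2 columns (the axonal shaft) as excluded.

    Works on a :class:`StraightenedImage` or :class:`CollateralMask`;
    returns the same type with the band's pixels marked invalid and the
    excised column range recorded.  Pixels outside the band are untouched.
    """
    if not isinstance(image, (StraightenedImage, CollateralMask)):
        raise TypeError("expected a StraightenedImage or CollateralMask")
    if band_um >= image.width_um:
        raise ValueError("band_um must be smaller than the image width")
    offsets = image.transverse_offsets_um
    band = np.abs(offsets) <= band_um / 2 + 1e-9
    lo = int(np.argmax(band))
    hi = int(len(band) - 1 - np.argmax(band[::-1]))
    valid = image.valid.copy()
    valid[:, lo:hi + 1] = False
    return replace(image, valid=valid, band_cols=(lo, hi))


def density_grid(mask, bin_px: int = 4) -> DensityGrid:
    """Bin a band-excised mask (or STR) into densities per µm².

    Each cell covers ``bin_px`` columns × 1 row; its value is the cell's
    foreground count (or intensity sum) divided by the cell area
    ``bin_px · pixel_size_x · pixel_size_y``.  Bins tile outward from the
    excised shaft band on each side; windows that would straddle the band
    or run off the image are dropped, and cells containing any invalid
    pixel are excluded.
    """
    if bin_px < 1:
        raise ValueError("bin_px must be >= 1")
    if mask.band_cols is None:
        raise ValueError("remove_shaft_band must be applied before binning")
    lo, hi = mask.band_cols
    pix = np.asarray(mask.pixels, dtype=float)
    n_rows, n_cols = pix.shape
    psx, psy = mask.pixel_size_x, mask.pixel_size_y
    center = mask.center_column

    starts = []
    s = lo - bin_px
    while s >= 0:            # left of the band, tiled from the band edge out
        starts.append(s)
        s -= bin_px
    starts.reverse()
    s = hi + 1
    while s + bin_px <= n_cols:   # right of the band
        starts.append(s)
        s += bin_px
    starts = np.asarray(starts, dtype=int)
    if starts.size == 0:
        raise ValueError("no complete bins fit outside the shaft band")

    counts = np.empty((n_rows, starts.size))
    excluded = np.empty((n_rows, starts.size), dtype=bool)
    coverage = np.zeros_like(pix, dtype=bool)
    for j, s0 in enumerate(starts):
        win = slice(s0, s0 + bin_px)
        counts[:, j] = pix[:, win].sum(axis=1)
        excluded[:, j] = ~mask.valid[:, win].all(axis=1)
        coverage[:, win] = ~excluded[:, j, None]
    area = bin_px * psx * psy
    values = counts / area
    values[excluded] = 0.0
    counts[excluded] = 0.0
    centers = (starts + (bin_px - 1) / 2 - center) * psx
    return DensityGrid(values, excluded, counts, centers, bin_px * psx, psy,
                       area, coverage)


def _check_shared_bins(grids):
    if not grids:
        raise ValueError("empty grid list")
    ref = grids[0].bin_centers_um
    for g in grids[1:]:
        if not np.allclose(g.bin_centers_um, ref):
            raise ValueError("grids do not share bin geometry")


def transverse_profile(grids, source: str = "mask") -> Profile:
    """Mean density per transverse bin, pooled over all rows of all images."""
    _check_shared_bins(grids)
    n_bins = grids[0].values.shape[1]
    tot = np.zeros(n_bins)
    n = np.zeros(n_bins)
    per_image = np.full((len(grids), n_bins), np.nan)
    for i, g in enumerate(grids):
        ok = ~g.excluded
        tot += np.where(ok, g.values, 0.0).sum(axis=0)
        n += ok.sum(axis=0)
        ni = ok.sum(axis=0)
        with np.errstate(invalid="ignore"):
            per_image[i] = np.where(
                ni > 0, np.where(ok, g.values, 0.0).sum(axis=0) / ni, np.nan)
    with np.errstate(invalid="ignore"):
        mean = np.where(n > 0, tot / n, np.nan)
    return Profile("transverse", grids[0].bin_centers_um.copy(), mean,
                   source, len(grids), per_image, n)


def longitudinal_profile(grids, source: str = "mask") -> Profile:
    """Mean density per along-axon position, pooled over all bins and images.

    Images shorter than a position simply do not contribute there; the
    pooled valid-cell count per position is tracked.
    """
    if not grids:
        raise ValueError("empty grid list")
    for g in grids[1:]:
        if g.pixel_size_y != grids[0].pixel_size_y:
            raise ValueError("grids do not share the along-axon step")
    n_rows = max(g.values.shape[0] for g in grids)
    tot = np.zeros(n_rows)
    n = np.zeros(n_rows)
    per_image = np.full((len(grids), n_rows), np.nan)
    for i, g in enumerate(grids):
        r = g.values.shape[0]
        ok = ~g.excluded
        tot[:r] += np.where(ok, g.values, 0.0).sum(axis=1)
        n[:r] += ok.sum(axis=1)
        ni = ok.sum(axis=1)
        with np.errstate(invalid="ignore"):
            per_image[i, :r] = np.where(
                ni > 0, np.where(ok, g.values, 0.0).sum(axis=1) / ni, np.nan)
    with np.errstate(invalid="ignore"):
        mean = np.where(n > 0, tot / n, np.nan)
    positions = np.arange(n_rows) * grids[0].pixel_size_y
    return Profile("longitudinal", positions, mean, source, len(grids),
                   per_image, n)


def stack_and_project(images) -> StackSummary:
    """Top-align STR or MASK images into a group stack with AVG/MAX projections.

    All images must share the column count and type; shorter images are
    padded at the bottom with invalid pixels, which contribute to neither
    projection.
    """
    if not images:
        raise ValueError("empty image list")
    types = {type(im) for im in images}
    if len(types) > 1:
        raise ValueError("cannot mix STR and MASK images in one stack")
    n_cols = images[0].pixels.shape[1]
    if any(im.pixels.shape[1] != n_cols for im in images):
        raise ValueError("images must share the column count")
    n_rows = max(im.pixels.shape[0] for im in images)
    stack = np.zeros((len(images), n_rows, n_cols))
    valid = np.zeros((len(images), n_rows, n_cols), dtype=bool)
    for i, im in enumerate(images):
        r = im.pixels.shape[0]
        stack[i, :r] = im.pixels
        valid[i, :r] = im.valid
    n = valid.sum(axis=0)
    with np.errstate(invalid="ignore"):
        avg = np.where(n > 0, np.where(valid, stack, 0.0).sum(axis=0)
                       / np.maximum(n, 1), 0.0)
    mx = np.where(n > 0, np.where(valid, stack, -np.inf).max(axis=0), 0.0)
    return StackSummary(stack, valid, avg, mx)
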