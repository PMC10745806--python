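"""Scalar branching summaries per axon.

Total branching is the collateral skeleton length (µm of valid mask
foreground) divided by the axon length, a dimensionless ratio.  The axon is
additionally split at a dorsal extent (default 70 µm from the proximal end)
and each region's collateral length is normalized by that region's own
length, so dorsal values are comparable across axons of different lengths.

Foreground length is measured per pixel — each foreground skeleton pixel
contributes one step of √(pixel_size_x · pixel_size_y) µm — rather than by
summing skeleton graph edges.  A per-pixel measure splits exactly at a row
boundary, which makes the dorsal/ventral decomposition additive; on the
isotropic pixels this pipeline produces the step equals the pixel size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .collateral_mask import CollateralMask, _STRUCT8

__all__ = ["BranchingSummary", "branching_summary", "foreground_length_um"]


@dataclass(frozen=True)
class BranchingSummary:
    axon_length_um: float
    total_branching: float           # collateral length / axon length
    dorsal_branching: float          # first dorsal_extent_um, self-normalized
    ventral_branching: float | None  # remainder; None if axon ends dorsally
    dorsal_extent_um: float
    total_collateral_um: float
    n_components: int


def foreground_length_um(mask: CollateralMask,
                         rows: slice = slice(None)) -> float:
    """Valid foreground length (µm) over a row range, per-pixel metric."""
    step = float(np.sqrt(mask.pixel_size_x * mask.pixel_size_y))
    fg = mask.pixels[rows] & mask.valid[rows]
    return float(fg.sum()) * step


def branching_summary(mask: CollateralMask,
                      dorsal_extent_um: float = 70.0) -> BranchingSummary:
    """Branching ratios for one axon from its band-excised mask.

    ``ventral_branching`` is ``None`` (reported absent, not zero) when the
    axon is not longer than the dorsal extent.
    """
    if mask.band_cols is None:
        raise ValueError("remove_shaft_band must be applied before summarizing")
    length = mask.axon_length_um
    psy = mask.pixel_size_y
    n_dorsal_rows = min(int(np.floor(dorsal_extent_um / psy)) + 1,
                        mask.pixels.shape[0])

    total_um = foreground_length_um(mask)
    dorsal_um = foreground_length_um(mask, slice(0, n_dorsal_rows))
    ventral_um = total_um - dorsal_um

    total = total_um / length
    dorsal = dorsal_um / min(dorsal_extent_um, length)
    if length > dorsal_extent_um:
        ventral = ventral_um / (length - dorsal_extent_um)
    else:
        ventral = None

    fg = mask.pixels & mask.valid
    _, n_comp = ndimage.label(fg, structure=_STRUCT8)
    return BranchingSummary(length, total, dorsal, ventral,
                            float(dorsal_extent_um), total_um, int(n_comp))
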