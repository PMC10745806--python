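"""High-level orchestration: one axon through the whole pipeline."""

from __future__ import annotations

from dataclasses import dataclass

from .branching_metrics import BranchingSummary, branching_summary
from .collateral_mask import CollateralMask, make_mask
from .config import PipelineConfig
from .image_io import AxonTrace, ImageStack, PlanarImage, max_project
from .profiles import DensityGrid, density_grid, remove_shaft_band
from .straighten import StraightenedImage, straighten_image, project_to_2d

__all__ = ["AxonResult", "process_axon"]


@dataclass(frozen=True)
class AxonResult:
    str_image: StraightenedImage       # band excised
    mask: CollateralMask               # band excised
    grid: DensityGrid                  # collateral densities (mask source)
    intensity_grid: DensityGrid        # intensity densities (STR source)
    summary: BranchingSummary


def process_axon(image, trace: AxonTrace,
                 config: PipelineConfig = PipelineConfig()) -> AxonResult:
    """MIP (if needed) → straighten → mask → band excision → densities → metrics."""
    if isinstance(image, ImageStack):
        image = max_project(image)
    elif not isinstance(image, PlanarImage):
        raise TypeError("image must be an ImageStack or PlanarImage")
    if trace.ndim == 3:
        trace = project_to_2d(trace)
    str_image = straighten_image(image, trace, width_um=config.width_um)
    mask = make_mask(str_image, method=config.threshold_method,
                     fixed_value=config.threshold_value,
                     min_collateral_um=config.min_collateral_um)
    str_cut = remove_shaft_band(str_image, band_um=config.band_um)
    mask_cut = remove_shaft_band(mask, band_um=config.band_um)
    grid = density_grid(mask_cut, bin_px=config.bin_px)
    igrid = density_grid(str_cut, bin_px=config.bin_px)
    summary = branching_summary(mask_cut,
                                dorsal_extent_um=config.dorsal_extent_um)
    return AxonResult(str_cut, mask_cut, grid, igrid, summary)
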