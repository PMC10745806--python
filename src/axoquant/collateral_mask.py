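"""Binary collateral masks: threshold, skeletonize, and length-filter.

An STR image is thresholded (Otsu by default), skeletonized to 1-px-wide
curves, and every 8-connected skeleton component whose geodesic length does
not exceed the minimum collateral length (default 0.5 µm, strict) is
removed.  Component length is the longest shortest path over the skeleton
pixel graph with physically weighted edges (``pixel_size_x`` horizontal,
``pixel_size_y`` vertical, Euclidean diagonal), so diagonal runs are not
underestimated.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.csgraph import dijkstra
from skimage.filters import threshold_otsu
from skimage.morphology import skeletonize

from .straighten import StraightenedImage

__all__ = ["CollateralMask", "threshold_image", "skeletonize_mask",
           "component_lengths", "filter_short_components", "make_mask"]

_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class CollateralMask:
    """Binary skeleton mask in STR geometry after the length filter."""

    pixels: np.ndarray  # bool (rows = along axon, cols = transverse)
    valid: np.ndarray   # False where excluded (out-of-bounds or shaft band)
    pixel_size_x: float
    pixel_size_y: float
    width_um: float
    axon_length_um: float
    min_collateral_um: float = 0.5
    band_cols: tuple[int, int] | None = None  # inclusive excised-column range

    def __post_init__(self):
        p = np.asarray(self.pixels, dtype=bool)
        if p.shape != self.valid.shape:
            raise ValueError("pixels and valid mask must share a shape")
        object.__setattr__(self, "pixels", p)

    @property
    def center_column(self) -> int:
        return self.pixels.shape[1] // 2

    @property
    def transverse_offsets_um(self) -> np.ndarray:
        c = self.center_column
        return (np.arange(self.pixels.shape[1]) - c) * self.pixel_size_x


def threshold_image(str_image: StraightenedImage, method: str = "otsu",
                    fixed_value: float | None = None) -> np.ndarray:
    """Threshold an STR image to a boolean foreground grid.

    ``otsu`` maximizes between-class variance over the valid-pixel
    histogram; a constant valid region yields an empty foreground.  Invalid
    (out-of-bounds) pixels are always background.
    """
    vals = np.asarray(str_image.pixels, dtype=float)
    valid = str_image.valid
    if method == "fixed":
        if fixed_value is None:
            raise ValueError("fixed threshold requires fixed_value")
        thr = float(fixed_value)
    elif method == "otsu":
        sample = vals[valid]
        if sample.size == 0 or np.ptp(sample) == 0:
            return np.zeros_like(vals, dtype=bool)
        thr = float(threshold_otsu(sample, nbins=256))
        # threshold_otsu returns the upper edge of the lower class; use >=
        # on the next representable level so both classes separate cleanly.
        return (vals >= np.nextafter(thr, np.inf)) & valid
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    return (vals >= thr) & valid


def skeletonize_mask(binary: np.ndarray) -> np.ndarray:
    """Reduce a binary grid to a 1-px-wide skeleton (topology preserving)."""
    return skeletonize(np.asarray(binary, dtype=bool))


def _component_graph(coords: np.ndarray, psx: float, psy: float):
    """Sparse weighted 8-neighbor graph over skeleton pixel coordinates."""
    n = coords.shape[0]
    index = {tuple(c): i for i, c in enumerate(coords)}
    rows, cols, w = [], [], []
    diag = float(np.hypot(psx, psy))
    steps = [(-1, -1, diag), (-1, 0, psy), (-1, 1, diag), (0, -1, psx)]
    for i, (r, c) in enumerate(coords):
        for dr, dc, dist in steps:
            j = index.get((r + dr, c + dc))
            if j is not None:
                rows.append(i)
                cols.append(j)
                w.append(dist)
    g = sparse.csr_matrix((w, (rows, cols)), shape=(n, n))
    return g + g.T


def component_lengths(skeleton: np.ndarray, pixel_size_x: float,
                      pixel_size_y: float):
    """Geodesic length (µm) of every 8-connected skeleton component.

    Returns ``(labels, lengths)`` where ``labels`` is the component label
    image and ``lengths[k]`` the longest shortest-path length within
    component ``k + 1``.  A single-pixel component has length 0.
    """
    labels, n = ndimage.label(skeleton, structure=_STRUCT8)
    lengths = np.zeros(n)
    for k in range(1, n + 1):
        coords = np.argwhere(labels == k)
        if coords.shape[0] < 2:
            continue
        g = _component_graph(coords, pixel_size_x, pixel_size_y)
        d = dijkstra(g, directed=False)
        lengths[k - 1] = float(d[np.isfinite(d)].max())
    return labels, lengths


def filter_short_components(skeleton: np.ndarray, pixel_size_x: float,
                            pixel_size_y: float,
                            min_collateral_um: float = 0.5) -> np.ndarray:
    """Remove skeleton components not strictly longer than the minimum.

    A component of exactly ``min_collateral_um`` is removed ("longer than"
    is strict).
    """
    labels, lengths = component_lengths(skeleton, pixel_size_x, pixel_size_y)
    keep = np.flatnonzero(lengths > min_collateral_um) + 1
    return np.isin(labels, keep)


def make_mask(str_image: StraightenedImage, *, method: str = "otsu",
              fixed_value: float | None = None,
              min_collateral_um: float = 0.5) -> CollateralMask:
    """Full STR → MASK pipeline: threshold, skeletonize, length-filter."""
    binary = threshold_image(str_image, method=method, fixed_value=fixed_value)
    skel = skeletonize_mask(binary)
    filtered = filter_short_components(skel, str_image.pixel_size_x,
                                       str_image.pixel_size_y,
                                       min_collateral_um)
    return CollateralMask(filtered, str_image.valid.copy(),
                          str_image.pixel_size_x, str_image.pixel_size_y,
                          str_image.width_um, str_image.axon_length_um,
                          min_collateral_um)
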