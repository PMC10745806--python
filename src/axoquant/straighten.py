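"""Trace length measurement and straightening of the axon into a band image.

The manually traced axon path (a polyline in µm) is resampled at uniform
arc-length steps and the source image is sampled along the local normal at
signed transverse offsets, producing a straightened band (STR) in which
rows run along the axon (row 0 = proximal end) and columns run transversely
with the shaft on the exact center column.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image_io import AxonTrace, PlanarImage

__all__ = ["StraightenedImage", "trace_length", "project_to_2d",
           "straighten_image"]


@dataclass(frozen=True)
class StraightenedImage:
    """Straightened band image (STR).

    ``pixels[s, t]``: row ``s`` is arc length ``s * pixel_size_y`` from the
    proximal end; column ``t`` is transverse offset
    ``(t - n_cols // 2) * pixel_size_x`` from the shaft center.  ``valid``
    flags samples that fell inside the source image; out-of-bounds samples
    are zero-filled and flagged False.
    """

    pixels: np.ndarray
    valid: np.ndarray
    pixel_size_x: float
    pixel_size_y: float
    width_um: float
    axon_length_um: float
    band_cols: tuple[int, int] | None = None  # inclusive excised-column range

    def __post_init__(self):
        if self.pixels.shape != self.valid.shape:
            raise ValueError("pixels and valid mask must share a shape")
        if self.pixels.shape[1] % 2 != 1:
            raise ValueError("column count must be odd (center column = shaft)")
        if not self.width_um > 0:
            raise ValueError("width_um must be positive")

    @property
    def center_column(self) -> int:
        return self.pixels.shape[1] // 2

    @property
    def transverse_offsets_um(self) -> np.ndarray:
        """Signed µm offset of each column center from the shaft center."""
        c = self.center_column
        return (np.arange(self.pixels.shape[1]) - c) * self.pixel_size_x


def trace_length(trace: AxonTrace) -> float:
    """Polyline length in µm: sum of Euclidean segment lengths (2D or 3D)."""
    seg = np.diff(trace.vertices, axis=0)
    return float(np.sum(np.linalg.norm(seg, axis=1)))


def project_to_2d(trace: AxonTrace) -> AxonTrace:
    """Drop the z coordinate of a 3D trace, merging consecutive duplicates."""
    if trace.ndim != 3:
        raise ValueError("trace is already 2D")
    pts = trace.vertices[:, :2]
    keep = np.ones(len(pts), dtype=bool)
    keep[1:] = np.any(np.diff(pts, axis=0) != 0, axis=1)
    return AxonTrace(pts[keep])


def _resample_polyline(vertices: np.ndarray, step: float) -> np.ndarray:
    """Resample a polyline at uniform arc-length steps (endpoint included)."""
    seg = np.diff(vertices, axis=0)
    seglen = np.linalg.norm(seg, axis=1)
    s = np.concatenate([[0.0], np.cumsum(seglen)])
    total = s[-1]
    n = int(np.floor(total / step)) + 1
    targets = np.arange(n) * step
    out = np.empty((n, vertices.shape[1]))
    for d in range(vertices.shape[1]):
        out[:, d] = np.interp(targets, s, vertices[:, d])
    return out


def straighten_image(image: PlanarImage, trace: AxonTrace,
                     width_um: float = 25.0) -> StraightenedImage:
    """Resample ``image`` along ``trace`` into a fixed-width straightened band.

    The path is resampled at arc-length steps equal to the source
    ``pixel_size_y``; tangents come from central differences of the
    resampled path and normals are the tangents rotated so that, for a
    downward-running trace, positive transverse offsets point toward +x.
    Sampling is bilinear; samples outside the source are zero with
    ``valid=False``.
    """
    if trace.ndim != 2:
        raise ValueError("straightening needs a 2D trace; project_to_2d first")
    if not width_um > 0:
        raise ValueError("width_um must be positive")
    length_um = trace_length(trace)
    if length_um <= 0:
        raise ValueError("degenerate zero-length trace")

    step = image.pixel_size_y
    path = _resample_polyline(trace.vertices, step)  # (n, 2) in µm

    tang = np.gradient(path, axis=0)
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    # Rotate tangent by -90° (x, y) -> (y, -x): for a trace running down the
    # image (ty > 0), the positive offset side is +x.
    normal = np.column_stack([tang[:, 1], -tang[:, 0]])

    n_cols = int(round(width_um / image.pixel_size_x))
    if n_cols % 2 == 0:
        n_cols += 1
    offsets = (np.arange(n_cols) - n_cols // 2) * image.pixel_size_x

    # Sample positions in µm, then to fractional pixel indices per axis.
    sample = path[:, None, :] + offsets[None, :, None] * normal[:, None, :]
    px = sample[..., 0] / image.pixel_size_x
    py = sample[..., 1] / image.pixel_size_y

    h, w = image.pixels.shape
    inside = (px >= 0) & (px <= w - 1) & (py >= 0) & (py <= h - 1)
    coords = np.stack([py.ravel(), px.ravel()])
    out = ndimage.map_coordinates(np.asarray(image.pixels, dtype=float),
                                  coords, order=1, mode="constant", cval=0.0)
    out = out.reshape(px.shape)
    out[~inside] = 0.0
    return StraightenedImage(out, inside, image.pixel_size_x,
                             image.pixel_size_y, float(width_um),
                             float(length_um))
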