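"""Reading and writing of on-disk artifacts.

Handles single-channel TIFF stacks and images, axon traces (ImageJ ``.roi``
polylines or CSV point lists), and tab-separated profile arrays.

Coordinate conventions
----------------------
Pixel coordinates are 0-based with pixel centers at integer positions;
``x`` is the column index and ``y`` the row index.  Conversion to physical
micrometres multiplies by the per-axis pixel size.  Trace vertices are
always stored in micrometres.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "ImageStack",
    "PlanarImage",
    "AxonTrace",
    "read_stack",
    "write_stack",
    "read_image",
    "write_image",
    "max_project",
    "read_trace",
    "write_trace_csv",
    "read_roi",
    "write_roi",
    "write_profiles_tsv",
    "read_profiles_tsv",
]


@dataclass(frozen=True)
class ImageStack:
    """A 3D voxel grid (z, y, x) with physical voxel sizes in µm."""

    voxels: np.ndarray
    pixel_size_x: float
    pixel_size_y: float
    z_step: float

    def __post_init__(self):
        v = np.asarray(self.voxels)
        if v.ndim != 3 or min(v.shape) < 1:
            raise ValueError("voxels must be a non-empty 3D (z, y, x) array")
        if not (self.pixel_size_x > 0 and self.pixel_size_y > 0 and self.z_step > 0):
            raise ValueError("physical voxel sizes must be positive")
        if not np.all(np.isfinite(v)) or np.any(v < 0):
            raise ValueError("intensities must be finite and non-negative")
        object.__setattr__(self, "voxels", v)


@dataclass(frozen=True)
class PlanarImage:
    """A 2D intensity image (y, x) with pixel sizes in µm."""

    pixels: np.ndarray
    pixel_size_x: float
    pixel_size_y: float

    def __post_init__(self):
        p = np.asarray(self.pixels)
        if p.ndim != 2 or min(p.shape) < 1:
            raise ValueError("pixels must be a non-empty 2D (y, x) array")
        if not (self.pixel_size_x > 0 and self.pixel_size_y > 0):
            raise ValueError("pixel sizes must be positive")
        object.__setattr__(self, "pixels", p)


@dataclass(frozen=True)
class AxonTrace:
    """An ordered polyline in physical µm coordinates, 2D (x, y) or 3D (x, y, z).

    The first vertex is the proximal (dorsal) end of the axon.
    """

    vertices: np.ndarray

    def __post_init__(self):
        v = np.atleast_2d(np.asarray(self.vertices, dtype=float))
        if v.ndim != 2 or v.shape[0] < 2 or v.shape[1] not in (2, 3):
            raise ValueError("trace needs >= 2 vertices of uniform 2D/3D dimensionality")
        if np.any(np.all(np.diff(v, axis=0) == 0, axis=1)):
            raise ValueError("consecutive vertices must be distinct")
        object.__setattr__(self, "vertices", v)

    @property
    def ndim(self) -> int:
        return self.vertices.shape[1]

    def __len__(self) -> int:
        return self.vertices.shape[0]


# ---------------------------------------------------------------------------
# TIFF stacks and images

def _pixel_sizes_from_tiff(tif: tifffile.TiffFile):
    """Extract (psx, psy, z_step) in µm from TIFF/ImageJ metadata, or Nones."""
    psx = psy = dz = None
    page = tif.pages[0]
    # TIFF resolution tags are pixels per unit; unit 3 = centimetre.
    xres = page.tags.get("XResolution")
    yres = page.tags.get("YResolution")
    unit = page.tags.get("ResolutionUnit")
    scale = None
    if unit is not None:
        u = getattr(unit.value, "value", unit.value)
        if u == 3:
            scale = 1e4  # µm per cm
        elif u == 2:
            scale = 25.4e3  # µm per inch
    ij = tif.imagej_metadata or {}
    if ij.get("unit") in ("micron", "um", "µm"):
        scale = 1.0 if scale is None else scale
        if xres is None:
            scale = 1.0
    if xres is not None and scale is not None:
        num, den = xres.value
        if num:
            psx = scale * den / num
    if yres is not None and scale is not None:
        num, den = yres.value
        if num:
            psy = scale * den / num
    if "spacing" in ij:
        dz = float(ij["spacing"])
    return psx, psy, dz


def read_stack(path, *, pixel_size_x=None, pixel_size_y=None, z_step=None,
               channel=None) -> ImageStack:
    """Read a single-channel TIFF stack.

    Pixel sizes come from TIFF/ImageJ metadata; keyword overrides always win.
    Missing sizes with no override raise ``ValueError`` rather than guessing.
    """
    with tifffile.TiffFile(str(path)) as tif:
        arr = tif.asarray()
        mx, my, mz = _pixel_sizes_from_tiff(tif)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim == 4:
        if channel is None:
            raise ValueError(
                f"{path}: multi-channel stack; pass channel= to select one")
        arr = arr[:, channel] if arr.shape[1] <= 8 else arr[..., channel]
    if arr.ndim != 3:
        raise ValueError(f"{path}: cannot interpret shape {arr.shape} as (z, y, x)")
    psx = pixel_size_x if pixel_size_x is not None else mx
    psy = pixel_size_y if pixel_size_y is not None else my
    dz = z_step if z_step is not None else mz
    if dz is None and arr.shape[0] == 1:
        dz = 1.0  # single slice: z step is irrelevant
    if psx is None or psy is None or dz is None:
        raise ValueError(
            f"{path}: pixel sizes absent from metadata and no override given")
    return ImageStack(arr, float(psx), float(psy), float(dz))


def write_stack(stack: ImageStack, path) -> None:
    """Write a stack as an ImageJ-compatible TIFF with µm calibration."""
    res = (1.0 / stack.pixel_size_x, 1.0 / stack.pixel_size_y)
    tifffile.imwrite(
        str(path), stack.voxels, imagej=True,
        resolution=res,
        metadata={"unit": "um", "spacing": stack.z_step, "axes": "ZYX"},
    )


def read_image(path, *, pixel_size_x=None, pixel_size_y=None) -> PlanarImage:
    """Read a 2D single-channel TIFF image."""
    with tifffile.TiffFile(str(path)) as tif:
        arr = tif.asarray()
        mx, my, _ = _pixel_sizes_from_tiff(tif)
    if arr.ndim == 3 and arr.shape[0] == 1:
        arr = arr[0]
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a 2D image, got shape {arr.shape}")
    psx = pixel_size_x if pixel_size_x is not None else mx
    psy = pixel_size_y if pixel_size_y is not None else my
    if psx is None or psy is None:
        raise ValueError(
            f"{path}: pixel sizes absent from metadata and no override given")
    return PlanarImage(arr, float(psx), float(psy))


def write_image(image: PlanarImage, path) -> None:
    res = (1.0 / image.pixel_size_x, 1.0 / image.pixel_size_y)
    tifffile.imwrite(str(path), image.pixels, imagej=True, resolution=res,
                     metadata={"unit": "um"})


def max_project(stack: ImageStack) -> PlanarImage:
    """Maximum intensity projection over z."""
    return PlanarImage(stack.voxels.max(axis=0),
                       stack.pixel_size_x, stack.pixel_size_y)


# ---------------------------------------------------------------------------
# Axon traces

def read_trace(path, pixel_size_x: float, pixel_size_y: float, *,
               units: str = "px") -> AxonTrace:
    """Read an axon trace from an ImageJ ``.roi`` polyline or a CSV point list.

    CSV columns are x,y[,z] with an optional header; ``units`` declares
    whether CSV/ROI coordinates are pixels (``px``, default, converted with
    the supplied pixel sizes) or already micrometres (``um``).  The z column
    of a 3D CSV is taken in the same units as x.
    """
    path = Path(path)
    if path.suffix.lower() == ".roi":
        pts = read_roi(path)
    else:
        pts = _read_trace_csv(path)
    pts = np.asarray(pts, dtype=float)
    if units == "px":
        scale = np.array([pixel_size_x, pixel_size_y, pixel_size_x][: pts.shape[1]])
        pts = pts * scale
    elif units != "um":
        raise ValueError(f"unknown trace units {units!r}")
    return AxonTrace(pts)


def _read_trace_csv(path) -> np.ndarray:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            parts = [p for p in line.replace("\t", ",").split(",") if p != ""]
            try:
                rows.append([float(p) for p in parts])
            except ValueError:
                if rows:
                    raise ValueError(f"{path}: malformed line {line!r}")
                continue  # header
    if not rows:
        raise ValueError(f"{path}: no coordinate rows")
    widths = {len(r) for r in rows}
    if len(widths) != 1 or widths.pop() not in (2, 3):
        raise ValueError(f"{path}: mixed or unsupported column counts")
    return np.array(rows)


def write_trace_csv(trace: AxonTrace, path, *, pixel_size_x=None,
                    pixel_size_y=None, units: str = "um") -> None:
    """Write a trace as CSV, in µm (default) or converted back to pixels."""
    pts = trace.vertices
    if units == "px":
        scale = np.array([pixel_size_x, pixel_size_y, pixel_size_x][: pts.shape[1]],
                         dtype=float)
        pts = pts / scale
    header = "x,y" if pts.shape[1] == 2 else "x,y,z"
    np.savetxt(path, pts, delimiter=",", header=header, comments="",
               fmt="%.9g")


# --- ImageJ .roi binary format (polyline subset) ---------------------------
# Layout follows the public ImageJ RoiDecoder byte offsets: 64-byte header
# starting with "Iout", big-endian; integer vertex coordinates are stored as
# shorts relative to the bounding box, subpixel coordinates as float32 when
# options bit 7 is set.

_ROI_POLYLINE = 5
_OPT_SUBPIXEL = 128


def read_roi(path) -> np.ndarray:
    """Read a polyline/segmented-line ``.roi`` file; returns (n, 2) pixel coords."""
    data = Path(path).read_bytes()
    if data[:4] != b"Iout":
        raise ValueError(f"{path}: not an ImageJ ROI file")
    roi_type = data[6]
    if roi_type != _ROI_POLYLINE:
        raise ValueError(
            f"{path}: ROI type {roi_type} is not a polyline/segmented line")
    top, left, bottom, right, n = struct.unpack(">5h", data[8:18])
    options = struct.unpack(">h", data[50:52])[0]
    if n < 2:
        raise ValueError(f"{path}: polyline needs >= 2 vertices, has {n}")
    if options & _OPT_SUBPIXEL:
        off = 64 + 4 * n  # float block follows the integer block
        xs = np.frombuffer(data, ">f4", n, off)
        ys = np.frombuffer(data, ">f4", n, off + 4 * n)
        pts = np.column_stack([xs, ys]).astype(float)
    else:
        xs = np.frombuffer(data, ">i2", n, 64).astype(float) + left
        ys = np.frombuffer(data, ">i2", n, 64 + 2 * n).astype(float) + top
        pts = np.column_stack([xs, ys])
    if np.any(np.all(np.diff(pts, axis=0) == 0, axis=1)):
        raise ValueError(f"{path}: consecutive duplicate vertices")
    return pts


def write_roi(points, path) -> None:
    """Write pixel coordinates as an ImageJ segmented-line ``.roi``.

    Always writes the subpixel (float32) coordinate block so round trips
    preserve fractional positions.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ValueError("need an (n >= 2, 2) array of x, y pixel coordinates")
    n = pts.shape[0]
    left, top = int(np.floor(pts[:, 0].min())), int(np.floor(pts[:, 1].min()))
    right, bottom = int(np.ceil(pts[:, 0].max())), int(np.ceil(pts[:, 1].max()))
    header = bytearray(64)
    header[0:4] = b"Iout"
    struct.pack_into(">h", header, 4, 228)  # version
    header[6] = _ROI_POLYLINE
    struct.pack_into(">5h", header, 8, top, left, bottom, right, n)
    struct.pack_into(">h", header, 50, _OPT_SUBPIXEL)
    ints = np.concatenate([
        np.round(pts[:, 0]).astype(">i2") - left,
        np.round(pts[:, 1]).astype(">i2") - top,
    ]).tobytes()
    floats = np.concatenate([pts[:, 0], pts[:, 1]]).astype(">f4").tobytes()
    Path(path).write_bytes(bytes(header) + ints + floats)


# ---------------------------------------------------------------------------
# Tab-separated profile arrays

def write_profiles_tsv(profiles, path) -> None:
    """Write per-image profiles as a TSV: one header row of positions (µm),
    then one row of mean values per image.

    ``profiles`` is a sequence of 1D value arrays sharing one position axis,
    or a single object with ``positions`` and ``per_image`` attributes.
    """
    if hasattr(profiles, "per_image"):
        positions = np.asarray(profiles.positions, dtype=float)
        rows = np.atleast_2d(np.asarray(profiles.per_image, dtype=float))
    else:
        seq = list(profiles)
        if not seq:
            raise ValueError("no profiles to write")
        if hasattr(seq[0], "positions"):
            positions = np.asarray(seq[0].positions, dtype=float)
            rows = np.vstack([np.asarray(p.values, dtype=float) for p in seq])
            for p in seq:
                if not np.array_equal(np.asarray(p.positions), positions):
                    raise ValueError("profiles in one file must share positions")
        else:
            rows = np.vstack([np.asarray(p, dtype=float) for p in seq])
            positions = np.arange(rows.shape[1], dtype=float)
    if rows.shape[1] != positions.size:
        raise ValueError("profile length does not match position axis")
    with open(path, "w") as fh:
        fh.write("\t".join(f"{p:.6g}" for p in positions) + "\n")
        for row in rows:
            fh.write("\t".join(f"{v:.6g}" for v in row) + "\n")


def read_profiles_tsv(path):
    """Read a profiles TSV; returns (positions, values) arrays.

    ``values`` has one row per image; missing entries (``nan``) are allowed.
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if len(lines) < 2:
        raise ValueError(f"{path}: need a header row and >= 1 profile row")
    positions = np.array([float(v) for v in lines[0].split("\t")])
    values = np.array([[float(v) if v not in ("", "nan") else np.nan
                        for v in ln.split("\t")] for ln in lines[1:]])
    if values.shape[1] != positions.size:
        raise ValueError(f"{path}: ragged rows")
    return positions, values
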