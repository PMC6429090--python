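"""Raster and ROI input/output.

The analysis operates on the green channel of 8-bit RGB photographs of the
CAM viewing window: blood absorbs strongly at 500-600 nm, so vessels are
dark in green while the membrane background is bright.  Only 8-bit input is
accepted; silently rescaling other bit depths would change the semantics of
the intensity inequality at the core of the segmentation.

Pixel coordinates are 0-based ``(row, col)`` with row 0 at the top.  ROIs
are stored as plain-text polygon files (one ``row,col`` vertex per line,
``#`` comments allowed) or as 8-bit single-channel mask images in which any
nonzero pixel is inside the region.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import shapely
import tifffile
from PIL import Image


class FormatError(ValueError):
    """Input raster violates the 8-bit 3-channel contract."""


class ROIError(ValueError):
    """ROI definition is malformed or inconsistent with the image."""


@dataclass
class AcquisitionMeta:
    """Optional acquisition record attached to an image."""

    egg_id: str | None = None
    group: str | None = None
    timepoint_min: float | None = None


@dataclass
class RGBImage:
    """8-bit RGB raster (height x width x 3, values in [0, 255])."""

    pixels: np.ndarray
    metadata: AcquisitionMeta = field(default_factory=AcquisitionMeta)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise FormatError(
                f"expected height x width x 3 array, got shape {px.shape}"
            )
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise FormatError("image must be at least 1x1")
        if px.dtype != np.uint8:
            if not np.issubdtype(px.dtype, np.integer):
                raise FormatError(f"expected integer pixels, got dtype {px.dtype}")
            if px.min() < 0 or px.max() > 255:
                raise FormatError("channel values outside [0, 255]")
            px = px.astype(np.uint8)
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


def load_rgb_image(path: str | Path, metadata: AcquisitionMeta | None = None) -> RGBImage:
    """Read an 8-bit RGB PNG or TIFF.

    Grayscale and 16-bit inputs are rejected rather than converted: the
    segmentation inequality is defined on the 8-bit green channel.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    if path.suffix.lower() in {".tif", ".tiff"}:
        arr = tifffile.imread(path)
    else:
        with Image.open(path) as im:
            if im.mode == "RGBA":
                raise FormatError(f"{path}: alpha channel not supported (mode RGBA)")
            if im.mode not in {"RGB"}:
                raise FormatError(
                    f"{path}: expected 8-bit RGB, got PIL mode {im.mode!r}"
                )
            arr = np.asarray(im)
    arr = np.asarray(arr)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise FormatError(
            f"{path}: expected 3 channels, got array of shape {arr.shape}"
        )
    if arr.dtype != np.uint8:
        raise FormatError(f"{path}: expected 8-bit samples, got dtype {arr.dtype}")
    return RGBImage(arr, metadata or AcquisitionMeta())


def save_rgb_image(img: RGBImage | np.ndarray, path: str | Path) -> None:
    """Write an 8-bit RGB raster as PNG or TIFF (lossless)."""
    px = img.pixels if isinstance(img, RGBImage) else np.asarray(img, dtype=np.uint8)
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, px, photometric="rgb")
    else:
        Image.fromarray(px, mode="RGB").save(path)


def extract_green(img: RGBImage | np.ndarray) -> np.ndarray:
    """Return the green channel (index 1 of R,G,B) as a 2-D uint8 raster."""
    px = img.pixels if isinstance(img, RGBImage) else np.asarray(img)
    if px.ndim != 3 or px.shape[2] != 3:
        raise FormatError(f"expected RGB array, got shape {px.shape}")
    return px[:, :, 1].copy()


def save_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a binary mask as an 8-bit single-channel PNG (255 = vessel)."""
    arr = (np.asarray(mask, dtype=bool) * np.uint8(255))
    Image.fromarray(arr, mode="L").save(Path(path))


def load_mask(path: str | Path) -> np.ndarray:
    """Read an 8-bit single-channel mask image; nonzero means inside/vessel."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"mask file not found: {path}")
    with Image.open(path) as im:
        if im.mode != "L":
            raise FormatError(f"{path}: expected 8-bit single-channel mask, mode {im.mode!r}")
        arr = np.asarray(im)
    return arr > 0


@dataclass
class ROIPolygon:
    """Simple polygon ROI in 0-based (row, col) pixel coordinates.

    The polygon is implicitly closed from the last vertex back to the first.
    A pixel belongs to the ROI when its center lies inside or on the
    boundary of the polygon.
    """

    vertices: np.ndarray  # (n, 2) float array of (row, col)

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise ROIError(f"ROI needs >= 3 (row, col) vertices, got shape {v.shape}")
        poly = shapely.Polygon(v)
        if not poly.is_valid:
            raise ROIError("ROI polygon is self-intersecting or degenerate")
        if poly.area <= 0:
            raise ROIError("ROI polygon has zero area")
        self.vertices = v

    def validate_bounds(self, image_shape: tuple[int, int]) -> None:
        h, w = image_shape
        r, c = self.vertices[:, 0], self.vertices[:, 1]
        if r.min() < 0 or c.min() < 0 or r.max() > h - 1 or c.max() > w - 1:
            raise ROIError(
                f"ROI vertex outside image bounds {image_shape}: "
                f"rows [{r.min()}, {r.max()}], cols [{c.min()}, {c.max()}]"
            )

    def to_mask(self, image_shape: tuple[int, int]) -> np.ndarray:
        """Rasterize: Boolean array, True where the pixel center is covered."""
        h, w = image_shape
        poly = shapely.Polygon(self.vertices)
        rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
        inside = shapely.intersects_xy(poly, rr.ravel(), cc.ravel())
        return inside.reshape(h, w)


def load_roi(path: str | Path, image_shape: tuple[int, int] | None = None) -> ROIPolygon:
    """Read a polygon ROI from the text format (one "row,col" per line).

    Lines starting with ``#`` and blank lines are ignored.  If
    ``image_shape`` is given, all vertices must lie inside the image.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"ROI file not found: {path}")
    verts: list[tuple[float, float]] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(",")
        if len(parts) != 2:
            raise ROIError(f"{path}:{lineno}: expected 'row,col', got {line!r}")
        try:
            verts.append((float(parts[0]), float(parts[1])))
        except ValueError as exc:
            raise ROIError(f"{path}:{lineno}: non-numeric vertex {line!r}") from exc
    roi = ROIPolygon(np.asarray(verts, dtype=float).reshape(-1, 2) if verts else np.empty((0, 2)))
    if image_shape is not None:
        roi.validate_bounds(image_shape)
    return roi


def save_roi(roi: ROIPolygon, path: str | Path) -> None:
    """Write a polygon ROI in the text format."""
    lines = ["# ROI polygon, one 'row,col' vertex per line (0-based, row 0 at top)"]
    for r, c in roi.vertices:
        lines.append(f"{r:g},{c:g}")
    Path(path).write_text("\n".join(lines) + "\n")
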