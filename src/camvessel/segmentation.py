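"""Vessel detection by local-mean comparison.

Vessels are dark in the green channel relative to the surrounding membrane.
Each pixel is compared against the mean intensity over a disk-shaped
neighborhood: where the disk mean strictly exceeds ``alpha`` times the
original pixel value the pixel is locally dark and is marked vessel,

    mask = disk_mean(G) > alpha * G

with ``alpha = 1.05`` and a disk of radius 30 px as defaults.  Speckle is
then suppressed by dropping 4-connected components smaller than 1000 px.

Near the image border the disk mean is taken over the in-bounds subset of
the disk (normalized convolution).  Zero-padding instead would depress the
mean near the border and spuriously mark border pixels as vessel.

All arithmetic is floating point; 8-bit input is never re-quantized
mid-pipeline.  For integer-valued images the disk sums are exact integers,
so the direct and FFT convolution paths below produce bit-identical masks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.signal import fftconvolve

from .image_io import ROIPolygon

# above this many pixel*footprint products, integer-valued images take the
# FFT path (sums rounded back to exact integers)
_FFT_THRESHOLD = 2e8

_STRUCT_4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
_STRUCT_8 = np.ones((3, 3), dtype=bool)


@dataclass
class SegmentationParams:
    """Tuning constants of the vessel detector.

    disk_radius : disk neighborhood radius in pixels (default 30)
    alpha : threshold multiplier on the original intensity (default 1.05)
    min_component_size : components smaller than this are removed (default 1000)
    connectivity : 4 or 8 neighbor adjacency for components (default 4)
    """

    disk_radius: int = 30
    alpha: float = 1.05
    min_component_size: int = 1000
    connectivity: int = 4

    def __post_init__(self) -> None:
        if self.disk_radius < 1:
            raise ValueError(f"disk_radius must be >= 1, got {self.disk_radius}")
        if not self.alpha > 0:
            raise ValueError(f"alpha must be > 0, got {self.alpha}")
        if self.min_component_size < 0:
            raise ValueError("min_component_size must be >= 0")
        if self.connectivity not in (4, 8):
            raise ValueError(f"connectivity must be 4 or 8, got {self.connectivity}")


def disk_footprint(radius: int) -> np.ndarray:
    """Boolean disk: offset (dr, dc) is inside iff dr^2 + dc^2 <= radius^2."""
    if radius < 1:
        raise ValueError(f"radius must be >= 1, got {radius}")
    r = int(radius)
    dr, dc = np.meshgrid(np.arange(-r, r + 1), np.arange(-r, r + 1), indexing="ij")
    return (dr * dr + dc * dc) <= radius * radius


def disk_mean_convolve(gray: np.ndarray, radius: int) -> np.ndarray:
    """Mean of pixels within Euclidean distance <= radius of each pixel.

    Border pixels average over the in-bounds part of the disk.  Returns a
    float64 raster of the input shape.
    """
    img = np.asarray(gray, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError(f"expected 2-D image, got shape {img.shape}")
    fp = disk_footprint(radius)
    integer_valued = np.array_equal(img, np.rint(img))
    if integer_valued and img.size * fp.sum() > _FFT_THRESHOLD:
        # sums of integer pixels are exact integers; FFT error ~1e-7 << 0.5,
        # so rounding recovers the exact sum and matches the direct path
        sums = np.rint(fftconvolve(img, fp.astype(np.float64), mode="same"))
        counts = np.rint(fftconvolve(np.ones_like(img), fp.astype(np.float64), mode="same"))
    else:
        sums = ndimage.convolve(img, fp.astype(np.float64), mode="constant", cval=0.0)
        counts = ndimage.convolve(np.ones_like(img), fp.astype(np.float64), mode="constant", cval=0.0)
    return sums / counts


def threshold_vessels(convolved: np.ndarray, original: np.ndarray, alpha: float) -> np.ndarray:
    """Boolean test ``convolved > alpha * original`` (strict, float arithmetic)."""
    conv = np.asarray(convolved, dtype=np.float64)
    orig = np.asarray(original, dtype=np.float64)
    if conv.shape != orig.shape:
        raise ValueError(f"shape mismatch: {conv.shape} vs {orig.shape}")
    if not alpha > 0:
        raise ValueError(f"alpha must be > 0, got {alpha}")
    return conv > alpha * orig


def filter_small_components(mask: np.ndarray, min_size: int, connectivity: int = 4) -> np.ndarray:
    """Keep only connected components of size >= min_size.

    ``connectivity`` is 4 (edge-adjacent) or 8 (edge- or corner-adjacent).
    """
    m = np.asarray(mask, dtype=bool)
    if min_size <= 1:
        return m.copy()
    structure = _STRUCT_4 if connectivity == 4 else _STRUCT_8
    labels, n = ndimage.label(m, structure=structure)
    if n == 0:
        return m.copy()
    sizes = np.bincount(labels.ravel())
    keep = sizes >= min_size
    keep[0] = False
    return keep[labels]


def segment_vessels(
    gray: np.ndarray,
    params: SegmentationParams | None = None,
    roi: ROIPolygon | np.ndarray | None = None,
) -> np.ndarray:
    """Full detector: disk mean, threshold, size filter, then ROI restriction.

    Size filtering runs on the whole-frame mask before the ROI cut, so a
    component straddling the ROI boundary is judged by its full size.
    ``roi`` may be a polygon or a precomputed Boolean mask.
    """
    params = params or SegmentationParams()
    img = np.asarray(gray)
    conv = disk_mean_convolve(img, params.disk_radius)
    mask = threshold_vessels(conv, img, params.alpha)
    mask = filter_small_components(mask, params.min_component_size, params.connectivity)
    if roi is not None:
        if isinstance(roi, ROIPolygon):
            roi_mask = roi.to_mask(img.shape)
        else:
            roi_mask = np.asarray(roi, dtype=bool)
            if roi_mask.shape != img.shape:
                raise ValueError(f"ROI mask shape {roi_mask.shape} != image {img.shape}")
        mask = mask & roi_mask
    return mask


def dice_coefficient(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); 1.0 when both masks are empty."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / denom
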