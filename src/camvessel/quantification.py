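"""Endpoints derived from binary vessel masks.

Three quantities summarize the treatment response:

* the vessel-area fraction inside a manually drawn ROI,
* that fraction tracked over time and expressed as a percentage of the
  pre-treatment (baseline) image, and
* local vessel diameters in microns, calibrated against a ring of known
  physical diameter (1.5 cm by default) placed on the membrane.

Diameters are read off the mask by skeletonizing each connected component
and sampling the Euclidean distance transform along the skeleton; the local
diameter at a skeleton pixel is taken as ``2 d - 1`` pixels, where ``d`` is
the distance to the nearest background pixel center (a bar exactly 7 px
thick then reads exactly 7 px).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize

from .image_io import ROIPolygon


class DegenerateSeriesError(ValueError):
    """Baseline vessel fraction is zero; normalization undefined."""


@dataclass
class ScaleCalibration:
    """Pixel-to-physical scale from the ring of known diameter.

    microns_per_pixel = 1e4 * ring_diameter_cm / ring_diameter_px
    """

    microns_per_pixel: float
    ring_diameter_cm: float = 1.5
    ring_diameter_px: float | None = None


def calibrate_scale(ring_diameter_px: float, ring_diameter_cm: float = 1.5) -> ScaleCalibration:
    """Derive microns/pixel from the ring's apparent pixel diameter."""
    if ring_diameter_px <= 0:
        raise ValueError(f"ring_diameter_px must be > 0, got {ring_diameter_px}")
    if ring_diameter_cm <= 0:
        raise ValueError(f"ring_diameter_cm must be > 0, got {ring_diameter_cm}")
    upp = 1e4 * ring_diameter_cm / ring_diameter_px
    return ScaleCalibration(upp, ring_diameter_cm, ring_diameter_px)


@dataclass
class SeriesEntry:
    timepoint_min: float
    area_fraction: float
    normalized_percent: float


@dataclass
class TimeSeriesRecord:
    """Per-egg occlusion time course, anchored at the pre-treatment image."""

    egg_id: str
    group: str
    entries: list[SeriesEntry] = field(default_factory=list)


def vessel_area_fraction(mask: np.ndarray, roi: ROIPolygon | np.ndarray) -> float:
    """(vessel pixels inside ROI) / (pixels inside ROI), in [0, 1]."""
    m = np.asarray(mask, dtype=bool)
    if isinstance(roi, ROIPolygon):
        roi_mask = roi.to_mask(m.shape)
    else:
        roi_mask = np.asarray(roi, dtype=bool)
        if roi_mask.shape != m.shape:
            raise ValueError(f"ROI mask shape {roi_mask.shape} != mask {m.shape}")
    n_roi = int(roi_mask.sum())
    if n_roi == 0:
        raise ValueError("ROI covers no pixels")
    return int((m & roi_mask).sum()) / n_roi


def normalize_series(
    fractions: list[tuple[float, float]], baseline_index: int = 0
) -> list[SeriesEntry]:
    """Express each fraction as a percent of the baseline fraction.

    ``fractions`` is a list of (timepoint_min, area_fraction); the entry at
    ``baseline_index`` (the pre-application image) maps to 100%.
    """
    if not fractions:
        raise ValueError("empty series")
    times = [t for t, _ in fractions]
    if any(b <= a for a, b in zip(times, times[1:])):
        raise ValueError(f"timepoints must be strictly increasing, got {times}")
    if not 0 <= baseline_index < len(fractions):
        raise ValueError(f"baseline_index {baseline_index} out of range")
    baseline = fractions[baseline_index][1]
    if baseline <= 0:
        raise DegenerateSeriesError(
            "baseline vessel-area fraction is zero; series cannot be normalized"
        )
    return [SeriesEntry(t, f, 100.0 * f / baseline) for t, f in fractions]


@dataclass
class ComponentDiameters:
    component_label: int
    n_skeleton_px: int
    median_um: float
    max_um: float


@dataclass
class DiameterSummary:
    """Per-component and pooled local-diameter statistics, in microns."""

    components: list[ComponentDiameters]
    pooled_um: np.ndarray  # all skeleton-pixel diameters

    @property
    def median_um(self) -> float:
        return float(np.median(self.pooled_um)) if self.pooled_um.size else float("nan")

    @property
    def max_um(self) -> float:
        return float(self.pooled_um.max()) if self.pooled_um.size else float("nan")

    @property
    def n_components(self) -> int:
        return len(self.components)


def estimate_vessel_diameters(mask: np.ndarray, cal: ScaleCalibration) -> DiameterSummary:
    """Local diameters along the medial skeleton of each vessel component.

    An empty mask yields an empty summary, not an error.
    """
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        return DiameterSummary([], np.empty(0))
    dist = ndimage.distance_transform_edt(m)
    skel = skeletonize(m)
    labels, n = ndimage.label(m, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], bool))
    components: list[ComponentDiameters] = []
    pooled: list[np.ndarray] = []
    for lab in range(1, n + 1):
        sel = skel & (labels == lab)
        if not sel.any():
            # component too small/round to leave a skeleton sample: use its
            # maximal inscribed disk at the distance-transform peak
            sel = (labels == lab) & (dist == dist[labels == lab].max())
        diam_um = (2.0 * dist[sel] - 1.0) * cal.microns_per_pixel
        diam_um = np.maximum(diam_um, cal.microns_per_pixel)  # at least one pixel wide
        components.append(
            ComponentDiameters(lab, int(sel.sum()), float(np.median(diam_um)), float(diam_um.max()))
        )
        pooled.append(diam_um)
    return DiameterSummary(components, np.concatenate(pooled))


def percent_reduction(before: float, after: float) -> float:
    """100 * (before - after) / before; negative values mean growth."""
    if before <= 0:
        raise ValueError(f"'before' must be > 0, got {before}")
    return 100.0 * (before - after) / before
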