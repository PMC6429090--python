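"""Synthetic CAM phantom generator.

Real CAM photographs behind the published analysis were never deposited, so
validation runs on phantoms with known ground truth.  A phantom emulates the
features the detector relies on:

* a bright membrane background with high green values and smooth
  low-frequency texture,
* a branching vessel tree, dark in green and reddish (blood-like), with
  calibers spanning roughly 70-400 um,
* a dark ring of known physical diameter (1.5 cm) for scale calibration,
* additive Gaussian noise.

Treatment response is modeled as multiplicative vessel-width shrinkage with
a collapse floor: all widths scale by a factor s per timepoint, and
segments thinner than the floor vanish (small vessels collapse first, the
qualitative behavior seen in vivo).  No hemodynamics is attempted.

The default scale is 10 um/px with the 1.5 cm ring spanning 1500 px, so
paper-scale calibers (70-400 um) map to 7-40 px.  Everything is
deterministic given ``rng_seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.transform import resize

from .dosimetry import RingGeometry
from .image_io import AcquisitionMeta, RGBImage, ROIPolygon, save_mask, save_rgb_image, save_roi


@dataclass
class Segment:
    """One straight vessel segment in physical coordinates (um)."""

    start: tuple[float, float]  # (row, col) um
    end: tuple[float, float]
    width_um: float


@dataclass
class VesselTree:
    segments: list[Segment]
    root_width_um: float

    def widths(self) -> np.ndarray:
        return np.array([s.width_um for s in self.segments])


@dataclass
class PhantomParams:
    """Generation parameters for one phantom egg.

    Scale defaults put the 1.5 cm ring at 1500 px (10 um/px); intensities
    are 8-bit gray levels with vessels ~90 gray levels darker than the
    membrane in green, comfortably above the detector's contrast needs.
    """

    image_size: tuple[int, int] = (1600, 1600)
    microns_per_pixel: float = 10.0
    background_green: float = 180.0
    background_red: float = 205.0
    background_blue: float = 160.0
    texture_amplitude: float = 8.0
    vessel_green: float = 90.0
    vessel_red: float = 150.0
    vessel_blue: float = 95.0
    ring: RingGeometry = field(default_factory=RingGeometry)
    ring_intensity: float = 60.0
    ring_thickness_px: float = 20.0
    noise_sd: float = 3.0
    n_trunks: int = 3
    depth: int = 5
    branch_angle_deg: float = 35.0
    width_decay: float = 0.7
    root_width_um: float = 400.0
    min_width_um: float = 30.0
    collapse_floor_um: float = 30.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.vessel_green >= self.background_green:
            raise ValueError("vessels must be darker than background in green")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.width_decay > 1.0:
            raise ValueError(
                f"width_decay must be <= 1 (children no wider than parents), got {self.width_decay}"
            )
        if self.width_decay >= 1.0 and self.min_width_um <= 0:
            raise ValueError("width_decay >= 1 with no minimum width never terminates")

    @property
    def ring_diameter_px(self) -> float:
        return self.ring.diameter_cm * 1e4 / self.microns_per_pixel

    @property
    def extent_um(self) -> tuple[float, float]:
        return (
            self.image_size[0] * self.microns_per_pixel,
            self.image_size[1] * self.microns_per_pixel,
        )


def generate_vessel_tree(params: PhantomParams) -> VesselTree:
    """Recursive bifurcating tree from ``n_trunks`` root trunks.

    Each segment spawns two children with width = parent width x decay and
    direction = parent direction +/- jitter, until ``depth`` levels or the
    minimum width is reached.  Endpoints are clipped to the field of view.
    Deterministic given ``rng_seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([params.rng_seed, 1]))
    h_um, w_um = params.extent_um
    center = np.array([h_um / 2.0, w_um / 2.0])
    field_r = 0.48 * min(h_um, w_um)
    segments: list[Segment] = []

    def clip(p: np.ndarray) -> np.ndarray:
        return np.clip(p, [0.0, 0.0], [h_um, w_um])

    def grow(start: np.ndarray, angle: float, width: float, length: float, level: int) -> None:
        end = clip(start + length * np.array([math.sin(angle), math.cos(angle)]))
        segments.append(Segment(tuple(start), tuple(end), width))
        if level + 1 >= params.depth:
            return
        child_w = width * params.width_decay
        if child_w < params.min_width_um:
            return
        spread = math.radians(params.branch_angle_deg)
        for sign in (-1.0, 1.0):
            jitter = rng.uniform(0.3, 1.0) * spread
            grow(end, angle + sign * jitter, child_w, length * 0.65, level + 1)

    for _ in range(params.n_trunks):
        theta = rng.uniform(0, 2 * math.pi)
        start = clip(center + field_r * np.array([math.sin(theta), math.cos(theta)]))
        toward_center = math.atan2(center[0] - start[0], center[1] - start[1])
        angle = toward_center + rng.uniform(-0.3, 0.3)
        grow(start, angle, params.root_width_um, 0.38 * min(h_um, w_um), 0)
    return VesselTree(segments, params.root_width_um)


def apply_shrinkage(tree: VesselTree, factor: float, width_floor_um: float = 0.0) -> VesselTree:
    """Multiply every width by ``factor``; drop segments below the floor.

    Composition law: shrinking by a then b (floor 0) equals shrinking by
    a*b.  Geometry is unchanged.
    """
    if not 0.0 < factor <= 1.0:
        raise ValueError(f"shrink factor must be in (0, 1], got {factor}")
    kept = [
        replace(s, width_um=s.width_um * factor)
        for s in tree.segments
        if s.width_um * factor >= width_floor_um
    ]
    return VesselTree(kept, tree.root_width_um * factor)


def rasterize_tree(tree: VesselTree, params: PhantomParams) -> np.ndarray:
    """Ground-truth mask: union of stadiums (capped thick lines), noise-free."""
    h, w = params.image_size
    upp = params.microns_per_pixel
    mask = np.zeros((h, w), dtype=bool)
    for seg in tree.segments:
        p0 = np.array(seg.start) / upp
        p1 = np.array(seg.end) / upp
        r = seg.width_um / 2.0 / upp
        lo = np.floor(np.minimum(p0, p1) - r - 1).astype(int)
        hi = np.ceil(np.maximum(p0, p1) + r + 1).astype(int)
        lo = np.maximum(lo, 0)
        hi = np.minimum(hi, [h - 1, w - 1])
        if np.any(hi < lo):
            continue
        rr = np.arange(lo[0], hi[0] + 1)
        cc = np.arange(lo[1], hi[1] + 1)
        gr, gc = np.meshgrid(rr, cc, indexing="ij")
        # distance from pixel centers to the segment p0-p1
        d = p1 - p0
        L2 = float(d @ d)
        vr = gr - p0[0]
        vc = gc - p0[1]
        if L2 == 0.0:
            dist2 = vr * vr + vc * vc
        else:
            t = np.clip((vr * d[0] + vc * d[1]) / L2, 0.0, 1.0)
            dr = vr - t * d[0]
            dc = vc - t * d[1]
            dist2 = dr * dr + dc * dc
        mask[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1] |= dist2 <= r * r
    return mask


def _background(params: PhantomParams, rng: np.random.Generator) -> np.ndarray:
    """Smooth low-frequency membrane texture, one field shared by channels."""
    coarse = rng.normal(0.0, 1.0, (12, 12))
    tex = resize(coarse, params.image_size, order=3, mode="reflect", anti_aliasing=False)
    return params.texture_amplitude * tex


def _ring_mask(params: PhantomParams) -> np.ndarray:
    h, w = params.image_size
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    d = np.hypot(rr - (h - 1) / 2.0, cc - (w - 1) / 2.0)
    r = params.ring_diameter_px / 2.0
    return np.abs(d - r) <= params.ring_thickness_px / 2.0


def render_phantom(
    tree: VesselTree, params: PhantomParams, frame_index: int = 0
) -> tuple[RGBImage, np.ndarray]:
    """Rasterize the tree onto the membrane; returns (image, truth mask).

    The truth mask is the noise-free union of vessel stadiums; the ring is
    drawn in the image but is not part of the truth.
    """
    if tree.segments and min(s.width_um for s in tree.segments) < params.microns_per_pixel:
        import warnings

        warnings.warn("some vessel widths are sub-pixel at this scale", stacklevel=2)
    h, w = params.image_size
    tex = _background(params, np.random.default_rng(np.random.SeedSequence([params.rng_seed, 2])))
    truth = rasterize_tree(tree, params)
    ring = _ring_mask(params)
    img = np.empty((h, w, 3), dtype=np.float64)
    for ch, (bg, vess) in enumerate(
        [
            (params.background_red, params.vessel_red),
            (params.background_green, params.vessel_green),
            (params.background_blue, params.vessel_blue),
        ]
    ):
        plane = bg + tex
        plane[truth] = vess
        plane[ring] = params.ring_intensity
        img[:, :, ch] = plane
    if params.noise_sd > 0:
        noise_rng = np.random.default_rng(
            np.random.SeedSequence([params.rng_seed, 3, frame_index])
        )
        img += noise_rng.normal(0.0, params.noise_sd, img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return RGBImage(img), truth


def default_roi(params: PhantomParams) -> ROIPolygon:
    """Octagonal ROI inscribed inside the ring, clear of the annulus."""
    h, w = params.image_size
    cr, cc = (h - 1) / 2.0, (w - 1) / 2.0
    r = 0.82 * params.ring_diameter_px / 2.0
    verts = [
        (cr + r * math.sin(a), cc + r * math.cos(a))
        for a in np.linspace(0, 2 * math.pi, 8, endpoint=False)
    ]
    return ROIPolygon(np.array(verts))


@dataclass
class Frame:
    timepoint_min: float
    shrink_factor: float
    image: RGBImage
    truth_mask: np.ndarray
    is_baseline: bool


# post-treatment imaging grid: every 30 min for 3 h, then 12 h and 24 h
DEFAULT_TIMEPOINTS_MIN = (0, 30, 60, 90, 120, 150, 180, 720, 1440)


def generate_time_series(
    params: PhantomParams, shrink_schedule: list[tuple[float, float]]
) -> list[Frame]:
    """Render one frame per (timepoint, shrink factor) schedule entry.

    The first entry is the pre-treatment baseline and must have factor 1.0.
    Shrinkage is applied to the baseline tree (factors are cumulative
    relative to baseline, not chained frame-to-frame).
    """
    if not shrink_schedule:
        raise ValueError("empty shrink schedule")
    if shrink_schedule[0][1] != 1.0:
        raise ValueError(
            f"first schedule entry is the baseline and must have factor 1.0, "
            f"got {shrink_schedule[0][1]}"
        )
    for _, f in shrink_schedule:
        if not 0.0 < f <= 1.0:
            raise ValueError(f"shrink factors must be in (0, 1], got {f}")
    tree = generate_vessel_tree(params)
    frames: list[Frame] = []
    for k, (t_min, factor) in enumerate(shrink_schedule):
        shrunk = apply_shrinkage(tree, factor, params.collapse_floor_um if factor < 1.0 else 0.0)
        img, truth = render_phantom(shrunk, params, frame_index=k)
        img.metadata = AcquisitionMeta(timepoint_min=t_min)
        frames.append(Frame(t_min, factor, img, truth, is_baseline=(k == 0)))
    return frames


def write_series(
    frames: list[Frame],
    params: PhantomParams,
    outdir: str | Path,
    egg_id: str = "egg01",
    group: str = "PDT6",
) -> Path:
    """Write frames, truth masks, the ROI file, and a manifest CSV.

    The manifest is the same format the series quantifier consumes; returns
    its path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    roi_path = outdir / f"{egg_id}_roi.txt"
    save_roi(default_roi(params), roi_path)
    rows = []
    for frame in frames:
        stem = f"{egg_id}_t{int(frame.timepoint_min):05d}"
        img_path = outdir / f"{stem}.png"
        truth_path = outdir / f"{stem}_truth.png"
        save_rgb_image(frame.image, img_path)
        save_mask(frame.truth_mask, truth_path)
        rows.append(
            {
                "image": img_path.name,
                "roi": roi_path.name,
                "egg_id": egg_id,
                "group": group,
                "timepoint_min": frame.timepoint_min,
                "baseline": int(frame.is_baseline),
                "ring_diameter_px": params.ring_diameter_px,
                "ring_diameter_cm": params.ring.diameter_cm,
                "truth_mask": truth_path.name,
            }
        )
    manifest = outdir / f"{egg_id}_manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
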