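# Methods

## Problem and model

The package quantifies vascular occlusion in the chick chorioallantoic
membrane (CAM) after photodynamic therapy (PDT) with curcumin as the
photosensitizer. The CAM is photographed through a shell window at a fixed
series of timepoints; blood absorbs strongly at 500–600 nm, so vessels are
dark in the green channel while the membrane is bright. The analysis turns
each photograph into a single number — the fraction of a region of interest
(ROI) covered by vessels — and tracks that number over time relative to the
pre-treatment image.

### Vessel detection

Detection is a local-mean comparison on the 8-bit green channel *G*:

1. **Disk-mean convolution.** Each pixel is replaced by the arithmetic mean
   of all pixels within Euclidean distance ≤ *r* (default *r* = 30 px). A
   pixel offset (Δr, Δc) belongs to the disk iff Δr² + Δc² ≤ r²; this
   membership rule is stated because rasterized-disk conventions differ.
   Near the border the mean is taken over the in-bounds subset of the disk
   (normalized convolution). Zero-padding was rejected because padded means
   drop below the threshold along the border and mark the frame edge as
   vessel.
2. **Threshold.** A pixel is vessel when `mean_disk(G) > α·G`, strictly,
   with α = 1.05. Inside a vessel the disk mean (dominated by bright
   surround) exceeds the dark pixel value; on open membrane it does not.
   The test is evaluated in float64; the 8-bit input is never re-quantized
   mid-pipeline. In exact arithmetic the mask is invariant to multiplying
   the image by any positive gain, since both sides scale together.
3. **Component filtering.** Speckle is removed by deleting 4-connected
   components smaller than 1000 px. The threshold is inclusive: a component
   of exactly 1000 px survives.
4. **ROI restriction.** Size filtering runs on the whole frame *before* the
   ROI cut, so a component straddling the ROI boundary is judged by its
   full size; the choice is recorded in the output metadata.

Defaults (r = 30, α = 1.05, min size 1000, 4-connectivity) are the
published operating point; the disk radius is exposed as a parameter
because it may need adjustment per image, but no automatic selection is
attempted — any tuning criterion would be an invention.

**Numerical design.** For integer-valued images every disk sum is an exact
integer, and integers of this magnitude are exact in float64 regardless of
summation order. Small or float-valued images use direct convolution
(`scipy.ndimage.convolve`); large integer-valued images use FFT convolution
with the sums rounded back to the nearest integer (FFT error ~1e-7 ≪ 0.5).
Both paths therefore produce the same exact sums divided by the same exact
in-bounds pixel counts — bit-identical masks — which is why the pipeline can
be tested pixel-for-pixel against a naive per-pixel double-loop reference,
including border pixels and threshold ties.

### Endpoints

* **Area fraction**: vessel pixels inside the ROI divided by ROI pixels. A
  pixel is inside the ROI when its center lies inside or on the polygon
  boundary (shapely point-in-polygon).
* **Normalized time series**: 100 × fraction(t) / fraction(baseline), the
  baseline being the image acquired before photosensitizer application.
  The baseline frame must be flagged explicitly in the manifest; it is
  never inferred from timestamps. A zero baseline raises a degenerate-input
  error rather than silently dropping the egg. Timepoints follow the
  acquisition grid (every 30 min to 3 h, then 12 h and 24 h) but any
  strictly increasing grid is accepted; no interpolation is performed.
* **Diameters**: the scale is calibrated from a ring of known physical
  diameter (1.5 cm default) placed on the membrane:
  µm/px = 10⁴ × ring_cm / ring_px. Each mask component is skeletonized and
  the local diameter at a skeleton pixel is taken as (2d − 1) px, where d is
  the Euclidean distance to the nearest background pixel center. The −1
  corrects for the half-pixel overshoot on each side: a bar exactly 7 px
  thick reads exactly 7 px, and a rasterized disk of radius 20 px reads
  41 px at its center, both within one pixel-width of truth. The original
  study measured diameters by hand in ImageJ; this automated medial-axis
  estimator is this package's own substitute so that diameter-scale
  endpoints (≈70 µm detection floor, ≈30% reduction of ≈400 µm vessels) are
  computable and testable. Components too small or round to leave a
  skeleton sample fall back to the distance-transform peak.

### Group statistics

Per-egg normalized curves are averaged within each experimental group
(arithmetic mean and sample SD per timepoint; eggs missing at a timepoint
reduce n and are never imputed — embryos are lost at high doses). Group
contrasts use classical one-way ANOVA (`scipy.stats.f_oneway`), a standard
stage with no quantity of its own to reproduce; it is validated against
textbook identities (identical groups give F = 0, p = 1; F is invariant to
location shifts and scaling).

### Dosimetry

Fluence (J/cm²) = irradiance (mW/cm²) × duration (s) / 1000. The built-in
group table holds the 20 conditions: L1–L5 (light only, 6–36 J/cm²), C1–C6
(curcumin only, 0.1–10 mM/cm² areal concentration), PDT1–PDT9 (50 mW/cm²
at 30 or 15 J/cm²). Durations not printed per condition are reconstructed
from fluence/irradiance consistency: 600 s everywhere except the 15 J/cm²
conditions at 300 s. The "mM/cm²" unit is kept as an opaque condition label
(solution molarity applied over the ring area) because converting it to
mol/cm² would require resolving an ambiguity the source data do not. The
ring area π(d/2)² is kept at full precision internally; the two-decimal
*truncation* display rule (1.7671… → "1.76") exists only for report output.

## Synthetic phantoms

No raw CAM photographs were released, so all quantitative validation runs
on synthetic phantoms with exact ground truth. A phantom contains:

* a membrane background (green ≈ 180) with smooth low-frequency texture
  (amplitude 8 gray levels, a 12×12 random grid upsampled with cubic
  interpolation) — smooth because the local-mean detector assumes the
  background varies slowly relative to the disk; the amplitude is a
  parameter so tests can probe failure modes;
* a branching vessel tree: bifurcation from root trunks (default 3), child
  width = parent width × 0.7 per generation from 400 µm roots down to a
  30 µm floor, covering the 70–400 µm caliber range of interest; vessels
  are dark in green (≈ 90) and reddish in RGB;
* a dark ring annulus of 1.5 cm physical diameter (1500 px at the default
  10 µm/px), the scale reference;
* additive Gaussian noise (default SD 3 gray levels) per channel, clipped
  to [0, 255]. Photon (Poisson) noise is out of scope.

Occlusion is modeled as multiplicative width shrinkage applied to the
baseline tree (factors are relative to baseline, not chained), with
segments falling below a collapse floor (30 µm) removed — mirroring the
qualitative in vivo pattern in which small vessels collapse first while
large vessels shrink by tens of percent. No hemodynamic or photochemical
model is attempted, and the shrink schedules shipped with the analysis
scripts are documented example dynamics, not calibrated claims: the
published group curves derive from unreleased photographs and are therefore
not reproduction targets.

Everything is deterministic given the seed: the tree, texture, and
per-frame noise draw from independent child streams of `rng_seed`, so a
regenerated series is bit-identical.

**What passing phantom tests shows — and does not.** Recovery of a known
shrink factor s to within a few percentage points (measured normalized area
within ±10 points of 100·s across seeds, baseline Dice ≥ 0.8, typically
≈ 0.98) demonstrates that the implemented operator chain is correct and
that the area-ratio endpoint tracks uniform caliber change under realistic
contrast and noise. It does not validate the detector against real CAM
images, which have specular highlights, embryo structures, uneven
illumination, motion between timepoints, and vessel-like texture that the
phantom deliberately omits.

## Problem sizes

Tests and the acceptance script use: full-scale phantoms (1600², 10 µm/px)
for the recovery experiment — 5 seeds × 5 frames; reduced phantoms (300–400
px with a proportionally smaller 0.5 cm ring and min component 250 px) for
pipeline and CLI behavior checks; and 108 random 64×64 images across the
radius × α grid for oracle equivalence. The small-phantom component
threshold scales with frame area for the same reason the published 1000 px
threshold suits full frames: it is an absolute area, not a fraction.

## Known limitations

* The detector is the faithful published operator, not a state-of-the-art
  vessel segmenter; no ridge filters or learned models are offered.
* Whether the original convolution re-quantized to 8 bits before
  thresholding is unknowable from the description; float is used here and
  the difference is confined to ties within one gray level.
* Residual speckle above 1000 px is tolerated, as in the original
  ("partially filtered"); no second denoising pass exists.
* No vessel tracking or registration between timepoints; the comparison is
  aggregate area only. No branching-topology metrics.
* ROI placement and ring localization are manual inputs; whether one ROI is
  reused across an egg's timepoints or drawn per image is the caller's
  choice and is recorded in the output metadata.
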