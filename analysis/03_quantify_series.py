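#!/usr/bin/env python
"""Segment every phantom frame and quantify occlusion over time.

Reads scratch/phantoms/manifest.csv (from 02), runs the default detector
(disk radius 30, alpha 1.05, min component 1000 px, 4-connectivity) inside
each egg's ROI, and writes per-frame results to results/occlusion_results.csv:
area fraction, normalized percent of baseline, component count, and
ring-calibrated diameter summaries.
"""

from pathlib import Path

from camvessel.pipeline import quantify_series
from camvessel.segmentation import SegmentationParams

ROOT = Path(__file__).resolve().parents[1]
manifest = ROOT / "scratch" / "phantoms" / "manifest.csv"
if not manifest.exists():
    raise SystemExit("run analysis/02_simulate_phantoms.py first")

results = quantify_series(manifest, SegmentationParams())
out = ROOT / "results" / "occlusion_results.csv"
out.parent.mkdir(exist_ok=True)
results.to_csv(out, index=False)
print(f"wrote {out} ({len(results)} frames)")
for egg, sub in results.groupby("egg_id"):
    curve = ", ".join(f"{t:g}min={v:.1f}%" for t, v in zip(sub["timepoint_min"], sub["normalized_percent"]))
    print(f"  {egg}: {curve}")
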