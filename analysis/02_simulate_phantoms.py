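#!/usr/bin/env python
"""Simulate a phantom cohort: PDT-like versus curcumin-only occlusion.

Generates two eggs per condition at the default phantom scale (1600 px,
10 um/px, 1.5 cm ring = 1500 px).  The shrink schedules are documented
example dynamics, not calibrated claims: the PDT-like arm shrinks fast and
deep (to 50% width by 3 h), the curcumin-only arm drifts mildly (to 85%).
Frames and truth masks land under scratch/phantoms (large binaries);
manifests are merged into scratch/phantoms/manifest.csv for step 03.
"""

from pathlib import Path

import pandas as pd

from camvessel.synthetic import PhantomParams, generate_time_series, write_series

ROOT = Path(__file__).resolve().parents[1]
SIMDIR = ROOT / "scratch" / "phantoms"

PDT_SCHEDULE = [(0, 1.0), (30, 0.85), (60, 0.75), (120, 0.6), (180, 0.5)]
CUR_SCHEDULE = [(0, 1.0), (30, 0.97), (60, 0.95), (120, 0.9), (180, 0.85)]

manifests = []
for i, (egg, group, sched) in enumerate(
    [
        ("pdt_egg1", "PDT6", PDT_SCHEDULE),
        ("pdt_egg2", "PDT6", PDT_SCHEDULE),
        ("cur_egg1", "C6", CUR_SCHEDULE),
        ("cur_egg2", "C6", CUR_SCHEDULE),
    ]
):
    params = PhantomParams(rng_seed=100 + i)
    frames = generate_time_series(params, sched)
    m = write_series(frames, params, SIMDIR / egg, egg_id=egg, group=group)
    manifests.append(m)
    print(f"{egg} ({group}): {len(frames)} frames -> {m.parent}")

joined = pd.concat(
    [
        pd.read_csv(m).assign(
            image=lambda d, m=m: [f"{m.parent.name}/{p}" for p in d["image"]],
            roi=lambda d, m=m: [f"{m.parent.name}/{p}" for p in d["roi"]],
        )
        for m in manifests
    ],
    ignore_index=True,
)
joined.to_csv(SIMDIR / "manifest.csv", index=False)
print(f"merged manifest: {SIMDIR / 'manifest.csv'} ({len(joined)} frames)")
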