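#!/usr/bin/env python
"""Tabulate the experimental conditions and verify the light-dose arithmetic.

Writes results/group_table.csv (the 20 conditions with reconstructed
exposure durations) and prints the fluence checks: every irradiated group's
stored fluence must reproduce from irradiance x duration / 1000.
"""

from pathlib import Path

import pandas as pd

from camvessel.dosimetry import fluence, load_group_table, ring_area, truncate_2dp

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

rows = []
for g in load_group_table():
    rows.append(
        {
            "group": g.name,
            "curcumin_mM_cm2": g.curcumin_mM_cm2,
            "irradiance_mW_cm2": g.exposure.irradiance_mw_cm2 if g.exposure else None,
            "duration_s": g.exposure.duration_s if g.exposure else None,
            "fluence_J_cm2": g.fluence_j_cm2,
        }
    )
table = pd.DataFrame(rows)
table.to_csv(OUT / "group_table.csv", index=False)

ok = all(
    abs(r["fluence_J_cm2"] - fluence(r["irradiance_mW_cm2"], r["duration_s"])) < 1e-12
    for r in rows
    if r["fluence_J_cm2"] is not None
)
print(f"wrote {OUT / 'group_table.csv'} ({len(table)} conditions)")
print(f"all stored fluences reproduce from irradiance x duration: {ok}")
print(f"PDT full dose: {fluence(50, 600)} J/cm^2 (10 min), reduced: {fluence(50, 300)} J/cm^2 (5 min)")
print(f"ring field: {ring_area(1.5):.4f} cm^2, displayed {truncate_2dp(ring_area(1.5))} cm^2")
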