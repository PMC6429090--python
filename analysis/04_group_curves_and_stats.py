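#!/usr/bin/env python
"""Average occlusion curves per group and contrast PDT vs curcumin-only.

Reads results/occlusion_results.csv, writes results/group_summary.csv
(group, timepoint, n, mean, sd), runs a one-way ANOVA between the two arms
at the last common timepoint, and saves a curve plot to scratch/.
"""

from pathlib import Path

import pandas as pd

from camvessel.pipeline import anova_at_timepoint, summarize_results

ROOT = Path(__file__).resolve().parents[1]
results = pd.read_csv(ROOT / "results" / "occlusion_results.csv")

summary = summarize_results(results)
out = ROOT / "results" / "group_summary.csv"
summary.to_csv(out, index=False)
print(f"wrote {out}")
print(summary.to_string(index=False))

t_last = results["timepoint_min"].max()
groups = sorted(results["group"].unique())
f, p = anova_at_timepoint(results, groups, t_last)
print(f"\none-way ANOVA across {groups} at t={t_last:g} min: F={f:.3f}, p={p:.3g}")

try:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for group, sub in summary.groupby("group"):
        ax.errorbar(sub["timepoint_min"], sub["mean"], yerr=sub["sd"], marker="o", label=group)
    ax.set_xlabel("time after treatment (min)")
    ax.set_ylabel("vessel area, % of baseline")
    ax.axhline(100, color="gray", lw=0.5)
    ax.legend()
    fig.tight_layout()
    figpath = ROOT / "scratch" / "group_curves.png"
    figpath.parent.mkdir(exist_ok=True)
    fig.savefig(figpath, dpi=150)
    print(f"plot: {figpath}")
except ImportError:
    print("matplotlib unavailable; skipped plot")
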