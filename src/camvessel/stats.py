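"""Group aggregation and the one-way ANOVA comparison.

Per-egg normalized occlusion curves are averaged within each experimental
group (mean and sample SD per timepoint, n reflecting availability — eggs
lost at high doses are reported with reduced n, never imputed).  Group
contrasts use classical one-way analysis of variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .quantification import TimeSeriesRecord


@dataclass
class GroupSummary:
    group: str
    table: pd.DataFrame  # columns: timepoint_min, n, mean, sd, sd_defined


def summarize_group(records: list[TimeSeriesRecord]) -> GroupSummary:
    """Mean and sample SD of normalized percent per timepoint across eggs.

    All records must share a group label.  Missing timepoints simply lower
    that timepoint's n.  With a single egg the SD is undefined and reported
    as 0 with ``sd_defined = False``.
    """
    if not records:
        raise ValueError("no records to summarize")
    groups = {r.group for r in records}
    if len(groups) != 1:
        raise ValueError(f"records span multiple groups: {sorted(groups)}")
    rows = [
        {"timepoint_min": e.timepoint_min, "value": e.normalized_percent}
        for r in records
        for e in r.entries
    ]
    df = pd.DataFrame(rows)
    agg = (
        df.groupby("timepoint_min")["value"]
        .agg(n="count", mean="mean", sd=lambda v: v.std(ddof=1))
        .reset_index()
    )
    agg["sd_defined"] = agg["n"] >= 2
    agg["sd"] = agg["sd"].fillna(0.0)
    return GroupSummary(groups.pop(), agg)


def one_way_anova(groups: list[list[float]]) -> tuple[float, float]:
    """Classical one-way ANOVA F statistic and p value.

    Identical groups give F = 0, p = 1.  Requires >= 2 groups of >= 2
    values each.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("every group needs at least two values")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if all(np.allclose(a, arrays[0].mean()) for a in arrays) and all(
        np.allclose(a.std(), 0) for a in arrays
    ):
        return 0.0, 1.0
    f, p = sps.f_oneway(*arrays)
    if np.isnan(f):  # zero between-group variance with zero within-group variance
        return 0.0, 1.0
    return float(f), float(p)
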