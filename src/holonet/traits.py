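"""Host trait encoding and replicate averaging at the sample-group level.

Traits: Day (kept ordinal for the Spearman rule downstream), WaterSW
(1 = salt water), a one-hot encoding of the four feed categories,
Female_ratio (fraction of sexed fish that are female), and the condition
factor CF = 10^N * W / L^3 with weight W in grams, length L in millimeters
and N = 4 chosen to bring CF near 1.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .data_io import FEED_LEVELS, OmicsMatrix, SampleTable, WATER_LEVELS

logger = logging.getLogger(__name__)

TRAIT_COLUMNS = ("Day", "WaterSW") + FEED_LEVELS + ("Female_ratio", "Condition_factor")


def condition_factor(weight_g: float, length_mm: float, n: int = 4) -> float:
    """Fulton-type condition factor ``10^n * W / L^3``."""
    if weight_g <= 0 or length_mm <= 0:
        raise ValueError("weight and length must be positive")
    return 10.0**n * weight_g / length_mm**3


def group_order(samples: SampleTable) -> list[str]:
    """Canonical group ordering: feed, then water, then day (the integrated
    heatmap's column order)."""
    df = samples.table
    keys = {}
    for r in df.itertuples():
        keys[r.group_id] = (FEED_LEVELS.index(r.feed), WATER_LEVELS.index(r.water), r.day, r.group_id)
    return [g for g, _ in sorted(keys.items(), key=lambda kv: kv[1])]


def encode_traits(samples: SampleTable) -> pd.DataFrame:
    """Group x trait matrix, rows in canonical group order.

    Female_ratio excludes unknown-sex fish from the denominator and is NaN
    (with a warning) for groups where every fish is of unknown sex.
    """
    df = samples.table
    rows = []
    for gid in group_order(samples):
        sub = df[df["group_id"] == gid]
        feed = sub["feed"].iloc[0]
        water = sub["water"].iloc[0]
        sexed = sub[sub["sex"].isin(("M", "F"))]
        if len(sexed) == 0:
            logger.warning("group %s has no sexed fish; Female_ratio is missing", gid)
            female_ratio = np.nan
        else:
            female_ratio = float((sexed["sex"] == "F").sum() / len(sexed))
        cf = float(np.mean([condition_factor(w, l) for w, l in zip(sub["weight_g"], sub["length_mm"])]))
        row = {"group_id": gid, "Day": float(sub["day"].iloc[0]), "WaterSW": 1.0 if water == "SW" else 0.0}
        for f in FEED_LEVELS:
            row[f] = 1.0 if f == feed else 0.0
        row["Female_ratio"] = female_ratio
        row["Condition_factor"] = cf
        rows.append(row)
    out = pd.DataFrame(rows).set_index("group_id")
    return out[list(TRAIT_COLUMNS)]


def average_replicates(matrix, samples: SampleTable) -> pd.DataFrame:
    """Mean profile per replicate group, columns in canonical group order.

    Accepts an :class:`OmicsMatrix`, an eigennode matrix, or any DataFrame
    whose columns are sample ids.
    """
    if isinstance(matrix, OmicsMatrix):
        values = matrix.values
    elif hasattr(matrix, "values") and isinstance(getattr(matrix, "values"), pd.DataFrame):
        values = matrix.values
    else:
        values = matrix
    missing = [s for s in values.columns if s not in samples.table.index]
    if missing:
        raise ValueError(f"matrix sample(s) absent from sample table: {missing[:5]}")
    gid = samples.table.loc[values.columns, "group_id"]
    grouped = values.T.groupby(gid.to_numpy()).mean().T
    order = [g for g in group_order(samples.subset(list(values.columns))) if g in grouped.columns]
    return grouped[order]
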