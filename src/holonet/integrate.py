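"""Integrated heatmap analysis of holobiont interactions (iHAHI).

Host module eigennodes are correlated, across replicate-averaged sample
groups, with encoded host traits (left block; Spearman for the ordinal Day
variable, Pearson otherwise) and with microbiota module eigennodes (right
block; Pearson).  The central panel shows group-mean eigennode profiles
with columns ordered by feed, then water, then day.  Significance stars
annotate raw two-sided p-values at 0.05 / 0.01 / 0.001.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import SampleTable
from .network import EigennodeMatrix
from .traits import average_replicates

logger = logging.getLogger(__name__)

_P_MIN = float(np.nextafter(0.0, 1.0))


@dataclass
class CorrResult:
    """Row x column correlation block with p-values and per-cell group counts."""

    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame
    method: dict = field(default_factory=dict)  # column -> "pearson" | "spearman"
    undefined: pd.DataFrame | None = None  # True where r is undefined (zero variance)


def _corr_p(r: float, n: int) -> float:
    """Two-sided p from t = r * sqrt((n-2)/(1-r^2)) on n-2 df."""
    if abs(r) >= 1.0:
        return _P_MIN
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def correlate(rows: pd.DataFrame, cols: pd.DataFrame, method_per_col: dict | None = None) -> CorrResult:
    """Correlate every row variable against every column variable.

    Both inputs are variable x group DataFrames sharing an identically
    ordered group axis.  Cells use pairwise-complete observations;
    zero-variance cells give r = NaN, p = 1 and are flagged.
    """
    if list(rows.columns) != list(cols.columns):
        raise ValueError("rows and cols must share identically ordered group columns")
    n_groups = rows.shape[1]
    if n_groups < 3:
        raise ValueError("correlate requires at least 3 groups")
    method_per_col = method_per_col or {}
    R = pd.DataFrame(index=rows.index, columns=cols.index, dtype=float)
    P = pd.DataFrame(1.0, index=rows.index, columns=cols.index, dtype=float)
    N = pd.DataFrame(0, index=rows.index, columns=cols.index, dtype=int)
    undef = pd.DataFrame(False, index=rows.index, columns=cols.index)
    methods = {c: method_per_col.get(c, "pearson") for c in cols.index}
    X = rows.to_numpy(dtype=float)
    Y = cols.to_numpy(dtype=float)
    for j, cvar in enumerate(cols.index):
        spearman = methods[cvar] == "spearman"
        for i in range(X.shape[0]):
            x, y = X[i], Y[j]
            mask = np.isfinite(x) & np.isfinite(y)
            n = int(mask.sum())
            N.iloc[i, j] = n
            if n < 3:
                R.iloc[i, j] = np.nan
                undef.iloc[i, j] = True
                continue
            xv, yv = x[mask], y[mask]
            if spearman:
                xv = stats.rankdata(xv, method="average")
                yv = stats.rankdata(yv, method="average")
            if np.std(xv) == 0 or np.std(yv) == 0:
                R.iloc[i, j] = np.nan
                undef.iloc[i, j] = True
                continue
            r = float(np.corrcoef(xv, yv)[0, 1])
            r = float(np.clip(r, -1.0, 1.0))
            R.iloc[i, j] = r
            P.iloc[i, j] = _corr_p(r, n)
    return CorrResult(r=R, p=P, n=N, method=methods, undefined=undef)


def significance_stars(p: float) -> str:
    """Star band for a raw p-value: *** <= 0.001 < ** <= 0.01 < * <= 0.05."""
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p-value out of [0,1]: {p}")
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


def stars_frame(p: pd.DataFrame) -> pd.DataFrame:
    return p.map(significance_stars)


def bh_adjust(p: pd.DataFrame) -> pd.DataFrame:
    """Optional Benjamini-Hochberg adjustment of a p-value block (a deviation
    from the raw-p star convention of the default display)."""
    flat = p.to_numpy().ravel()
    order = np.argsort(flat)
    m = flat.size
    adj = np.empty(m)
    prev = 1.0
    for rank_idx in range(m - 1, -1, -1):
        i = order[rank_idx]
        prev = min(prev, flat[i] * m / (rank_idx + 1))
        adj[i] = prev
    return pd.DataFrame(adj.reshape(p.shape), index=p.index, columns=p.columns)


@dataclass
class IhahiResult:
    center: pd.DataFrame  # kept hME rows x ordered groups (group-mean profiles)
    left: CorrResult  # hME x traits
    right: CorrResult  # hME x mME
    stars_left: pd.DataFrame
    stars_right: pd.DataFrame
    kept_rows: list
    row_rule: str


def build_ihahi(
    hme: EigennodeMatrix,
    mme: EigennodeMatrix,
    traits: pd.DataFrame,
    samples: SampleTable,
    row_rule: str = "significant_both",
) -> IhahiResult:
    """Assemble the three-panel integrated heatmap.

    ``traits`` is the group x trait matrix from :func:`holonet.traits.encode_traits`.
    ``row_rule`` ``"significant_both"`` keeps host modules with at least one
    trait association and at least one microbiota association at p <= 0.05;
    ``"all"`` keeps every host module.
    """
    hme_g = average_replicates(hme.values, samples)
    mme_g = average_replicates(mme.values, samples)
    common = [g for g in hme_g.columns if g in mme_g.columns and g in traits.index]
    if not common:
        raise ValueError("no common sample groups between eigennodes and traits")
    hme_g, mme_g = hme_g[common], mme_g[common]
    traits_g = traits.loc[common].T  # trait x group
    method = {t: ("spearman" if t == "Day" else "pearson") for t in traits_g.index}
    left = correlate(hme_g, traits_g, method)
    right = correlate(hme_g, mme_g)
    if row_rule == "significant_both":
        keep = [
            m for m in hme_g.index
            if (left.p.loc[m] <= 0.05).any() and len(right.p.columns) and (right.p.loc[m] <= 0.05).any()
        ]
        if not keep:
            logger.warning("no host module passes the significance row rule; result is empty")
    elif row_rule == "all":
        keep = list(hme_g.index)
    else:
        raise ValueError(f"unknown row_rule {row_rule!r}")
    return IhahiResult(
        center=hme_g.loc[keep],
        left=CorrResult(left.r.loc[keep], left.p.loc[keep], left.n.loc[keep], left.method,
                        left.undefined.loc[keep]),
        right=CorrResult(right.r.loc[keep], right.p.loc[keep], right.n.loc[keep], right.method,
                         right.undefined.loc[keep]),
        stars_left=stars_frame(left.p.loc[keep]),
        stars_right=stars_frame(right.p.loc[keep]),
        kept_rows=keep,
        row_rule=row_rule,
    )


def node_level_follow_up(gene_profile: pd.Series, otu_profile: pd.Series) -> CorrResult:
    """Pearson correlation between one gene and one OTU at the group level;
    used to drill into a predicted module-module interaction."""
    common = [g for g in gene_profile.index if g in otu_profile.index]
    rows = pd.DataFrame([gene_profile.loc[common]], index=["gene"])
    cols = pd.DataFrame([otu_profile.loc[common]], index=["otu"])
    return correlate(rows, cols)


def export_ihahi(result: IhahiResult, out_prefix) -> list[str]:
    """Write the numeric blocks as TSV; returns the written paths."""
    written = []
    for name, df in (
        ("center", result.center),
        ("left_r", result.left.r), ("left_p", result.left.p),
        ("right_r", result.right.r), ("right_p", result.right.p),
        ("stars_left", result.stars_left), ("stars_right", result.stars_right),
    ):
        path = f"{out_prefix}_{name}.tsv"
        df.to_csv(path, sep="\t", float_format="%.17g")
        written.append(path)
    return written


def plot_ihahi(result: IhahiResult, path, figsize=None) -> None:
    """Render the three-panel heatmap (left traits, center profiles, right
    cross-kingdom correlations) as a pure view of the exported numbers."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n_rows = max(len(result.kept_rows), 1)
    widths = [max(result.left.r.shape[1], 1), max(result.center.shape[1], 1),
              max(result.right.r.shape[1], 1)]
    figsize = figsize or (min(18, 2 + 0.35 * sum(widths)), min(20, 2 + 0.3 * n_rows))
    fig, axes = plt.subplots(1, 3, figsize=figsize, width_ratios=widths)
    panels = [
        (result.left.r, result.stars_left, "traits", "bwr", (-1, 1)),
        (result.center, None, "group means", "bwr", None),
        (result.right.r, result.stars_right, "mME", "bwr", (-1, 1)),
    ]
    for ax, (block, stars, title, cmap, lim) in zip(axes, panels):
        if block.size == 0:
            ax.set_visible(False)
            continue
        data = block.to_numpy(dtype=float)
        vlim = lim or (-np.nanmax(np.abs(data)) or -1, np.nanmax(np.abs(data)) or 1)
        ax.imshow(np.nan_to_num(data), cmap=cmap, vmin=vlim[0], vmax=vlim[1], aspect="auto")
        ax.set_xticks(range(block.shape[1]))
        ax.set_xticklabels(block.columns, rotation=90, fontsize=6)
        ax.set_yticks(range(block.shape[0]))
        ax.set_yticklabels(block.index, fontsize=6)
        ax.set_title(title, fontsize=9)
        if stars is not None:
            for i in range(block.shape[0]):
                for j in range(block.shape[1]):
                    s = stars.iloc[i, j]
                    if s:
                        ax.text(j, i, s, ha="center", va="center", fontsize=5)
    fig.tight_layout()
    fig.savefig(path, dpi=150, metadata={"Software": None} if str(path).endswith(".png") else None)
    plt.close(fig)
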