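"""Count normalization, feature filtering and outlier screening.

Host gene counts are normalized between samples with the trimmed mean of
M-values (TMM) and expressed as log2 counts-per-million; microbial OTU
counts are scaled by cumulative-sum scaling (CSS) and log2-transformed.
Gene filtering operates on the normalized log2 scale (maximum expression
and standard-deviation rules); OTU filtering operates on raw relative
abundance before normalization.  Outlier screening min-max scales each
sample and flags samples that join an average-linkage tree unusually high.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist

from .data_io import OmicsMatrix

logger = logging.getLogger(__name__)


@dataclass
class NormalizationResult:
    matrix: OmicsMatrix  # stage normalized_log2
    scale_factors: "np.ndarray"  # one per sample, positive
    method: str  # "TMM" | "CSS"
    params: dict = field(default_factory=dict)


@dataclass
class FilterReport:
    """Partition of input features into kept and removed, with the rule
    that removed each feature."""

    kept_ids: list
    removed_ids: list
    rule_fired: dict  # removed id -> rule name

    def __post_init__(self) -> None:
        if set(self.kept_ids) & set(self.removed_ids):
            raise ValueError("kept and removed sets overlap")
        if set(self.rule_fired) != set(self.removed_ids):
            raise ValueError("rule_fired must cover exactly the removed ids")


def tmm_normalize(
    counts: OmicsMatrix,
    trim_M: float = 0.30,
    trim_A: float = 0.05,
    pseudocount: float = 0.5,
) -> NormalizationResult:
    """TMM between-sample normalization, output as log2 CPM.

    The reference sample is the one whose upper-quartile/library-size ratio
    is closest to the mean of that ratio.  For every other sample the scale
    factor is ``2**(weighted mean of doubly trimmed M-values)`` where
    M = log2 ratio of library-size-scaled counts vs the reference, features
    zero in either sample are excluded, the central ``1 - 2*trim_M`` mass of
    M and ``1 - 2*trim_A`` mass of A are retained, and weights are the
    inverse asymptotic (binomial) variance of M.  Factors are rescaled to
    geometric mean 1.
    """
    if counts.stage != "raw_counts":
        raise ValueError("tmm_normalize expects raw counts")
    X = counts.values.to_numpy(dtype=float)
    n_feat, n_samp = X.shape
    if n_samp < 2:
        raise ValueError("TMM requires at least 2 samples")
    lib = X.sum(axis=0)
    if (lib <= 0).any():
        bad = [counts.sample_ids[j] for j in np.flatnonzero(lib <= 0)]
        raise ValueError(f"sample(s) with all-zero counts: {bad}")

    uq_ratio = np.array([np.quantile(X[:, j], 0.75) for j in range(n_samp)]) / lib
    ref = int(np.argmin(np.abs(uq_ratio - uq_ratio.mean())))
    r = X[:, ref]
    Nr = lib[ref]

    factors = np.ones(n_samp)
    for j in range(n_samp):
        if j == ref:
            continue
        x = X[:, j]
        Nx = lib[j]
        mask = (x > 0) & (r > 0)
        if mask.sum() == 0:
            logger.warning("no shared nonzero features with reference for sample %s; factor 1",
                           counts.sample_ids[j])
            continue
        px, pr = x[mask] / Nx, r[mask] / Nr
        M = np.log2(px / pr)
        A = 0.5 * np.log2(px * pr)
        keep = (
            (M >= np.quantile(M, trim_M))
            & (M <= np.quantile(M, 1.0 - trim_M))
            & (A >= np.quantile(A, trim_A))
            & (A <= np.quantile(A, 1.0 - trim_A))
        )
        if keep.sum() == 0:
            keep = np.ones_like(M, dtype=bool)
        w = 1.0 / ((Nx - x[mask]) / (Nx * x[mask]) + (Nr - r[mask]) / (Nr * r[mask]))
        factors[j] = 2.0 ** (np.sum(w[keep] * M[keep]) / np.sum(w[keep]))

    factors = factors / np.exp(np.mean(np.log(factors)))
    eff_lib = lib * factors
    out = np.log2((X + pseudocount) / eff_lib[None, :] * 1e6)
    mat = OmicsMatrix(
        pd.DataFrame(out, index=counts.values.index, columns=counts.values.columns),
        kingdom=counts.kingdom,
        stage="normalized_log2",
    )
    return NormalizationResult(
        matrix=mat,
        scale_factors=factors,
        method="TMM",
        params={"trim_M": trim_M, "trim_A": trim_A, "pseudocount": pseudocount,
                "reference_sample": counts.sample_ids[ref]},
    )


def css_normalize(counts: OmicsMatrix, quantile: float = 0.5) -> NormalizationResult:
    """Cumulative-sum scaling: divide each sample by the sum of its counts at
    or below its q-th quantile of nonzero counts, then ``log2(x/f*1000 + 1)``."""
    if counts.stage != "raw_counts":
        raise ValueError("css_normalize expects raw counts")
    if not (0.0 < quantile <= 1.0):
        raise ValueError("quantile must lie in (0, 1]")
    X = counts.values.to_numpy(dtype=float)
    n_samp = X.shape[1]
    factors = np.empty(n_samp)
    for j in range(n_samp):
        x = X[:, j]
        nz = x[x > 0]
        if nz.size == 0:
            raise ValueError(f"sample {counts.sample_ids[j]} has no nonzero counts")
        q = np.quantile(nz, quantile)
        factors[j] = x[x <= q].sum()
    out = np.log2(X / factors[None, :] * 1000.0 + 1.0)
    mat = OmicsMatrix(
        pd.DataFrame(out, index=counts.values.index, columns=counts.values.columns),
        kingdom=counts.kingdom,
        stage="normalized_log2",
    )
    return NormalizationResult(
        matrix=mat, scale_factors=factors, method="CSS", params={"quantile": quantile}
    )


def filter_genes(
    matrix: OmicsMatrix, min_expr: float = 1.0, min_sd: float = 0.15
) -> tuple[OmicsMatrix, FilterReport]:
    """Remove genes whose expression never reaches ``min_expr`` and/or whose
    standard deviation (n-1 denominator) is below ``min_sd``."""
    X = matrix.values.to_numpy(dtype=float)
    mx = X.max(axis=1)
    sd = X.std(axis=1, ddof=1) if X.shape[1] > 1 else np.zeros(X.shape[0])
    keep = (mx >= min_expr) & (sd >= min_sd)
    ids = matrix.feature_ids
    kept = [ids[i] for i in np.flatnonzero(keep)]
    removed, rules = [], {}
    for i in np.flatnonzero(~keep):
        removed.append(ids[i])
        rules[ids[i]] = "max_expression" if mx[i] < min_expr else "low_sd"
    if not kept:
        logger.warning("filter_genes removed every feature")
        report = FilterReport(kept, removed, rules)
        return matrix, report  # empty result would be invalid; caller decides
    out = matrix.subset_features(kept)
    return out, FilterReport(kept, removed, rules)


def filter_otus(
    counts: OmicsMatrix, min_total_fraction: float = 0.00005
) -> tuple[OmicsMatrix, FilterReport]:
    """Keep OTUs contributing at least ``min_total_fraction`` of the grand
    total abundance (boundary retained)."""
    X = counts.values.to_numpy(dtype=float)
    grand = X.sum()
    if grand <= 0:
        raise ValueError("grand total of counts is zero")
    frac = X.sum(axis=1) / grand
    keep = frac >= min_total_fraction
    ids = counts.feature_ids
    kept = [ids[i] for i in np.flatnonzero(keep)]
    removed = [ids[i] for i in np.flatnonzero(~keep)]
    rules = {i: "low_total_abundance" for i in removed}
    if not kept:
        logger.warning("filter_otus removed every OTU")
        return counts, FilterReport(kept, removed, rules)
    return counts.subset_features(kept), FilterReport(kept, removed, rules)


def detect_outlier_samples(matrix: OmicsMatrix, height_mad_k: float = 5.0) -> list[str]:
    """Flag samples by min-max scaling + average-linkage clustering.

    Each sample is scaled to [0, 1] over its features, samples are clustered
    on Euclidean distance with average linkage, and a sample is flagged iff
    the height at which its leaf first joins the tree exceeds
    ``median(merge heights) + height_mad_k * MAD(merge heights)`` (unscaled
    median absolute deviation).
    """
    n_samp = matrix.shape[1]
    if n_samp < 4:
        logger.warning("detect_outlier_samples needs >=4 samples; returning none")
        return []
    X = matrix.values.to_numpy(dtype=float).T.copy()  # samples x features
    rng_span = X.max(axis=1) - X.min(axis=1)
    safe = np.where(rng_span > 0, rng_span, 1.0)
    X = (X - X.min(axis=1, keepdims=True)) / safe[:, None]
    d = pdist(X, metric="euclidean")
    if np.all(d == 0):
        return []
    Z = linkage(d, method="average")
    heights = Z[:, 2]
    med = np.median(heights)
    mad = np.median(np.abs(heights - med))
    threshold = med + height_mad_k * mad
    # height at which each original leaf first participates in a merge
    leaf_height = np.full(n_samp, np.nan)
    for a, b, h, _ in Z:
        for idx in (int(a), int(b)):
            if idx < n_samp and np.isnan(leaf_height[idx]):
                leaf_height[idx] = h
    flagged = [matrix.sample_ids[i] for i in range(n_samp) if leaf_height[i] > threshold]
    if flagged:
        logger.warning("flagged %d outlier sample(s): %s", len(flagged), flagged)
    return flagged
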