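"""Signed weighted co-abundance network inference.

The method follows the weighted-correlation-network recipe: a robust
biweight midcorrelation between feature profiles, soft thresholding of the
signed similarity ``(1 + cor)/2`` by a power chosen for approximate
scale-free topology, a signed weighted topological overlap measure (TOM),
average-linkage clustering of ``1 - TOM`` with a deep-split-controlled
height cut to detect modules, module eigennodes (first principal component
of the standardized module members), kME-based trimming, eigennode-based
module merging, and intramodular connectivity statistics.

Everything is computed in a single dense block; the entry point is
:func:`infer_network`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .data_io import OmicsMatrix

logger = logging.getLogger(__name__)


@dataclass
class NetworkParams:
    """Tuning constants of the network inference.

    ``power`` of ``None`` means "pick by scale-free fit".  ``deep_split``
    maps linearly onto the branch-cut height (4 = most sensitive).
    ``merge_cut_height`` defaults differ by kingdom in the pipeline
    (0.5 host, 0.4 microbe).
    """

    power: float | None = None
    network_type: str = "signed"
    tom_type: str = "signed"
    max_p_outliers: float = 0.05
    deep_split: int = 4
    min_module_size: int = 2
    min_kme_to_stay: float = 0.5
    min_core_kme: float = 0.5
    min_core_kme_size: int = 2
    merge_cut_height: float = 0.5
    reassign_threshold: float = 0.0  # 0 = cross-module reassignment disabled
    r2_cut: float = 0.85
    candidate_powers: tuple = tuple(range(1, 31))
    merge_corr_method: str = "pearson"
    # branch signal floor: modules must have mean within-branch correlation
    # >= cor_floor_z / sqrt(n_samples); 0 disables the floor
    cor_floor_z: float = 3.0

    def __post_init__(self) -> None:
        if not 0 <= self.max_p_outliers <= 1:
            raise ValueError("max_p_outliers must lie in [0,1]")
        if self.deep_split not in range(5):
            raise ValueError("deep_split must be an integer in 0..4")
        if not 0 < self.merge_cut_height < 1:
            raise ValueError("merge_cut_height must lie in (0,1)")


@dataclass
class ModulePartition:
    """Node -> module labels; label 0 marks unassigned ("grey") nodes.

    Labels of surviving modules are consecutive positive integers ordered by
    descending module size (ties broken by smallest member position).
    ``prefix`` names eigennode rows, e.g. ``hME`` for host modules.
    """

    labels: pd.Series  # index = node ids, values = int labels
    prefix: str = "ME"

    def __post_init__(self) -> None:
        self.labels = self.labels.astype(int)
        if (self.labels < 0).any():
            raise ValueError("module labels must be >= 0")

    @property
    def module_labels(self) -> list[int]:
        return sorted(set(self.labels[self.labels > 0]))

    @property
    def n_modules(self) -> int:
        return len(self.module_labels)

    def members(self, label: int) -> list:
        return list(self.labels.index[self.labels == label])

    def module_column_name(self, label: int) -> str:
        return f"{self.prefix}{label}"

    def relabel_by_size(self) -> "ModulePartition":
        """Recompact labels to 1..m ordered by descending size."""
        sizes = []
        for lab in set(self.labels[self.labels > 0]):
            idx = np.flatnonzero(self.labels.to_numpy() == lab)
            sizes.append((-len(idx), idx[0], lab))
        mapping = {old: new + 1 for new, (_, _, old) in enumerate(sorted(sizes))}
        new_labels = self.labels.map(lambda v: mapping.get(v, 0))
        return ModulePartition(new_labels, prefix=self.prefix)


@dataclass
class EigennodeMatrix:
    """Module x sample representative profiles, plus variance explained.

    Each row has zero mean and unit variance over samples and is oriented
    so its correlation with the module's mean standardized profile is >= 0.
    """

    values: pd.DataFrame  # rows named <prefix><label>
    var_explained: pd.Series

    @property
    def module_ids(self) -> list[str]:
        return list(self.values.index)


@dataclass
class NetworkResult:
    partition: ModulePartition
    eigennodes: EigennodeMatrix
    kme: pd.DataFrame
    connectivity: pd.DataFrame
    fit_table: pd.DataFrame
    power: float


# ---------------------------------------------------------------------------
# robust correlation


def _biweight_prepare(x: np.ndarray, max_p_outliers: float) -> tuple[np.ndarray, bool]:
    """Return the weighted, centered, L2-normalized version of ``x`` used by
    the biweight midcorrelation, and whether the Pearson fallback fired.

    The side cap rescales u separately below and above the median so that at
    most ``max_p_outliers`` of the observations on each side receive zero
    weight.  A zero median absolute deviation triggers the Pearson fallback
    (uniform weights) for this feature.
    """
    x = np.asarray(x, dtype=float)
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    fallback = mad == 0
    if fallback:
        c = x - x.mean()
        nrm = np.sqrt(np.sum(c * c))
        if nrm == 0:
            return np.zeros_like(x), True
        return c / nrm, True
    u = (x - med) / (9.0 * mad)
    if 0 < max_p_outliers < 0.5:
        q_lo = np.quantile(x, max_p_outliers)
        q_hi = np.quantile(x, 1.0 - max_p_outliers)
        u_lo = (q_lo - med) / (9.0 * mad)
        u_hi = (q_hi - med) / (9.0 * mad)
        if u_lo < -1.0:
            u = np.where(u < 0, u / np.abs(u_lo), u)
        if u_hi > 1.0:
            u = np.where(u > 0, u / u_hi, u)
    w = (1.0 - u * u) ** 2 * (np.abs(u) < 1.0)
    a = w * (x - med)
    nrm = np.sqrt(np.sum(a * a))
    if nrm == 0:
        # all weight vanished (pathological); fall back to Pearson
        c = x - x.mean()
        nrm = np.sqrt(np.sum(c * c))
        if nrm == 0:
            return np.zeros_like(x), True
        return c / nrm, True
    return a / nrm, False


def bicor(x, y, max_p_outliers: float = 0.05) -> float:
    """Biweight midcorrelation of two equal-length vectors (>= 3 samples)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("bicor: length mismatch")
    if x.size < 3:
        raise ValueError("bicor requires at least 3 observations")
    ax, fx = _biweight_prepare(x, max_p_outliers)
    ay, fy = _biweight_prepare(y, max_p_outliers)
    if not np.any(ax) or not np.any(ay):
        logger.warning("bicor: degenerate constant input, correlation set to 0")
        return 0.0
    return float(np.clip(np.dot(ax, ay), -1.0, 1.0))


def correlation_matrix(matrix: OmicsMatrix, params: NetworkParams | None = None) -> pd.DataFrame:
    """All-pairs biweight midcorrelation of feature profiles.

    Rows that are constant even under the Pearson fallback are undefined;
    their off-diagonal entries are NaN (downstream, missing adjacencies are
    replaced by 0).
    """
    params = params or NetworkParams()
    X = matrix.values.to_numpy(dtype=float)
    if X.shape[1] < 3:
        raise ValueError("correlation_matrix requires >= 3 samples")
    n = X.shape[0]
    G = np.empty_like(X)
    degenerate = np.zeros(n, dtype=bool)
    n_fallback = 0
    for i in range(n):
        G[i], fb = _biweight_prepare(X[i], params.max_p_outliers)
        n_fallback += fb
        degenerate[i] = not np.any(G[i])
    if n_fallback:
        logger.info("bicor: Pearson fallback used for %d feature(s)", n_fallback)
    C = np.clip(G @ G.T, -1.0, 1.0)
    if degenerate.any():
        logger.warning("%d constant feature(s) have undefined correlations", degenerate.sum())
        C[degenerate, :] = np.nan
        C[:, degenerate] = np.nan
    np.fill_diagonal(C, 1.0)
    ids = matrix.values.index
    return pd.DataFrame(C, index=ids, columns=ids)


# ---------------------------------------------------------------------------
# soft threshold, adjacency, TOM


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Scale-free topology fit of a connectivity vector.

    Bins log10(k) into ``n_bins`` equal-width bins, regresses log10 of the
    bin frequency on log10 of the bin mean connectivity, and returns
    ``(R^2 * sign(-slope), slope)``.
    """
    k = np.asarray(k, dtype=float)
    k = k[k > 0]
    if k.size < 2 or np.allclose(k, k[0]):
        return 0.0, 0.0
    logk = np.log10(k)
    edges = np.linspace(logk.min(), logk.max(), n_bins + 1)
    idx = np.clip(np.digitize(logk, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = idx == b
        if mask.sum() == 0:
            continue
        xs.append(np.log10(np.mean(k[mask])))
        ys.append(np.log10(mask.sum() / k.size))
    if len(xs) < 3:
        return 0.0, 0.0
    xs, ys = np.asarray(xs), np.asarray(ys)
    slope, intercept = np.polyfit(xs, ys, 1)
    resid = ys - (slope * xs + intercept)
    ss_tot = np.sum((ys - ys.mean()) ** 2)
    r2 = 1.0 - np.sum(resid**2) / ss_tot if ss_tot > 0 else 0.0
    return float(r2 * np.sign(-slope)), float(slope)


def default_signed_power(n_samples: int) -> float:
    """Canonical soft-threshold power for signed networks by sample count,
    used when the data show no scale-free trend at any candidate power."""
    if n_samples < 20:
        return 18.0
    if n_samples < 30:
        return 16.0
    if n_samples < 40:
        return 14.0
    return 12.0


def pick_soft_threshold(
    corr: pd.DataFrame,
    candidate_powers=tuple(range(1, 31)),
    r2_cut: float = 0.85,
    n_samples: int | None = None,
) -> tuple[float, pd.DataFrame]:
    """Choose the smallest power whose signed network reaches the scale-free
    fit cut.

    If no candidate reaches the cut, the argmax-fit power is used provided
    the best fit still shows a scale-free trend (fit >= 0.5); when even that
    fails — typical for designed experiments whose connectivity distribution
    is not remotely power-law — the sample-size-based canonical signed power
    (nearest candidate) is used instead.  ``table.attrs`` carries the
    ``no_power_reached_cut`` and ``used_default_power`` flags.
    """
    if len(candidate_powers) == 0:
        raise ValueError("empty candidate power list")
    n = corr.shape[0]
    if n < 20:
        logger.warning("pick_soft_threshold: only %d features; fit is unreliable", n)
    C = np.nan_to_num(corr.to_numpy(dtype=float), nan=-1.0)  # NaN -> adjacency 0
    S = (1.0 + C) / 2.0
    rows = []
    for beta in candidate_powers:
        A = S**beta
        k = A.sum(axis=0) - np.diag(A)
        fit, slope = scale_free_fit(k)
        rows.append(
            {"power": beta, "fit": fit, "slope": slope,
             "mean_k": float(k.mean()), "median_k": float(np.median(k)), "max_k": float(k.max())}
        )
    table = pd.DataFrame(rows)
    table.attrs["no_power_reached_cut"] = False
    table.attrs["used_default_power"] = False
    ok = table[table["fit"] >= r2_cut]
    if len(ok):
        beta = float(ok.iloc[0]["power"])
    else:
        table.attrs["no_power_reached_cut"] = True
        best_fit = float(table["fit"].max())
        if best_fit >= 0.5 or n_samples is None:
            beta = float(table.loc[table["fit"].idxmax(), "power"])
            logger.warning("no candidate power reached fit cut %.2f; using argmax power %g",
                           r2_cut, beta)
        else:
            target = default_signed_power(n_samples)
            beta = float(min(candidate_powers, key=lambda b: (abs(b - target), b)))
            table.attrs["used_default_power"] = True
            logger.warning(
                "no scale-free trend (best fit %.2f); using canonical signed power %g",
                best_fit, beta,
            )
    return beta, table


def signed_adjacency(corr: pd.DataFrame, beta: float) -> pd.DataFrame:
    """Signed adjacency ``a_ij = ((1 + cor_ij)/2)**beta`` with unit diagonal.

    Undefined (NaN) correlations become adjacency 0 with a logged count."""
    if beta <= 0:
        raise ValueError("beta must be positive")
    C = corr.to_numpy(dtype=float)
    n_missing = int(np.isnan(C[np.triu_indices_from(C, 1)]).sum())
    if n_missing:
        logger.warning("replacing %d missing adjacencies with 0", n_missing)
    A = ((1.0 + np.nan_to_num(C, nan=-1.0)) / 2.0) ** beta
    np.fill_diagonal(A, 1.0)
    return pd.DataFrame(A, index=corr.index, columns=corr.columns)


def signed_tom(adj: pd.DataFrame) -> pd.DataFrame:
    """Signed weighted topological overlap:
    ``TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)``
    with ``k_i`` excluding the diagonal and unit TOM on the diagonal."""
    A = adj.to_numpy(dtype=float)
    if (A < 0).any() or (A > 1).any():
        raise ValueError("adjacency entries must lie in [0, 1]")
    k = A.sum(axis=0) - np.diag(A)
    AA = A @ A
    # shared-neighbor sum excluding u in {i, j}; diag(A) == 1
    num = AA - A * (np.diag(A)[:, None] + np.diag(A)[None, :]) + A
    den = np.minimum.outer(k, k) + 1.0 - A
    with np.errstate(invalid="ignore", divide="ignore"):
        T = np.where(den > 0, num / den, 0.0)
    np.fill_diagonal(T, 1.0)
    T = np.clip(T, 0.0, 1.0)
    T = (T + T.T) / 2.0
    return pd.DataFrame(T, index=adj.index, columns=adj.columns)


# ---------------------------------------------------------------------------
# module detection


def _cut_height(heights: np.ndarray, deep_split: int) -> float:
    # deeper split -> higher cut -> branches completing higher in the tree
    # still qualify, so more (and smaller) modules are caught
    base = heights.min()
    span = heights.max() - base
    return float(base + span * (0.95 - 0.05 * (4 - deep_split)))


MAX_CORE_SCATTER = 0.80
MIN_CORE_GAP = 0.15


def detect_modules(
    diss: pd.DataFrame,
    params: NetworkParams,
    prefix: str = "ME",
    corr: pd.DataFrame | None = None,
    n_samples: int | None = None,
) -> ModulePartition:
    """Recursive branch decomposition of the average-linkage TOM tree.

    A branch of the dendrogram qualifies as a module when
    (i) it completes below the ``deep_split``-controlled height cut
    (deeper split -> higher cut -> more branches eligible),
    (ii) it has at least ``min_module_size`` leaves,
    (iii) it is tight and distinct: its core (mean internal merge height)
    lies in the lower 80% of the merge-height span and the stem between
    the core and the height where the branch joins the rest of the tree
    spans at least 15% of the height range, and
    (iv) when ``corr`` and ``n_samples`` are supplied, its mean
    within-branch correlation clears a size-adaptive signal floor
    ``cor_floor_z * (0.5 + 2/m) / sqrt(n_samples)`` for an ``m``-leaf
    branch.  The floor tracks the chance level of the tightest clusters a
    random dendrogram offers (small clusters can be incidentally tight, so
    they need proportionally more signal) and is what separates real
    co-abundance from the self-similar structure of pure-noise trees.

    The tree is decomposed top-down and the largest qualifying branches
    win, so a genuine module is reported whole rather than as its tightest
    fragments.  Leaves outside every qualifying branch stay unassigned
    (label 0); there is no post-hoc reassignment stage.
    """
    D = diss.to_numpy(dtype=float)
    if D.shape[0] != D.shape[1]:
        raise ValueError("dissimilarity matrix must be square")
    n = D.shape[0]
    labels = pd.Series(np.zeros(n, dtype=int), index=diss.index)
    if n < 2:
        return ModulePartition(labels, prefix=prefix)
    D = (D + D.T) / 2.0
    np.fill_diagonal(D, 0.0)
    Z = linkage(squareform(D, checks=False), method="average")
    heights = Z[:, 2]
    h_star = _cut_height(heights, params.deep_split)
    base = heights.min()
    span = heights.max() - base
    C = None
    use_floor = corr is not None and n_samples is not None and params.cor_floor_z > 0
    if use_floor:
        C = np.nan_to_num(corr.to_numpy(dtype=float), nan=0.0)

    n_nodes = n + len(Z)
    size = np.ones(n_nodes, dtype=int)
    members: list = [[i] for i in range(n)] + [None] * len(Z)
    core_sum = np.zeros(n_nodes)  # sum of internal merge heights
    core_cnt = np.zeros(n_nodes, dtype=int)
    within_sum = np.zeros(n_nodes)  # sum of off-diagonal correlations
    parent = np.full(n_nodes, -1, dtype=int)
    parent_h = np.full(n_nodes, np.inf)
    for k, (a, b, h, _) in enumerate(Z):
        a, b = int(a), int(b)
        node = n + k
        size[node] = size[a] + size[b]
        members[node] = members[a] + members[b]
        core_sum[node] = core_sum[a] + core_sum[b] + h
        core_cnt[node] = core_cnt[a] + core_cnt[b] + 1
        if C is not None:
            cross = float(C[np.ix_(members[a], members[b])].sum())
            within_sum[node] = within_sum[a] + within_sum[b] + 2.0 * cross
        parent[a] = parent[b] = node
        parent_h[a] = parent_h[b] = h

    def qualifies(node: int) -> bool:
        k = node - n
        if k < 0 or size[node] < params.min_module_size:
            return False
        h = Z[k, 2]
        if h > h_star:
            return False
        if span > 0:
            core = core_sum[node] / core_cnt[node]
            if (core - base) / span > MAX_CORE_SCATTER:
                return False
            attach = min(parent_h[node], heights.max())
            if (attach - core) / span < MIN_CORE_GAP:
                return False
        if use_floor:
            m = size[node]
            floor = params.cor_floor_z * (0.5 + 2.0 / m) / np.sqrt(n_samples)
            if within_sum[node] / (m * (m - 1)) < floor:
                return False
        return True

    # top-down: a qualifying branch claims its leaves unless an ancestor
    # already qualified
    inside = np.zeros(n_nodes, dtype=bool)
    module_nodes = []
    for k in range(len(Z) - 1, -1, -1):
        node = n + k
        p = parent[node]
        inside[node] = inside[p] if p >= 0 else False
        if not inside[node] and qualifies(node):
            inside[node] = True
            module_nodes.append(node)

    next_label = 1
    # provisional labels; compacted by size below
    for node in module_nodes:
        labels.iloc[members[node]] = next_label
        next_label += 1
    return ModulePartition(labels, prefix=prefix).relabel_by_size()


# ---------------------------------------------------------------------------
# eigennodes, kME, trimming, merging


def _standardize_rows(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    sd = X.std(axis=1, ddof=1)
    ok = sd > 0
    Xs = (X[ok] - X[ok].mean(axis=1, keepdims=True)) / sd[ok][:, None]
    return Xs, ok


def module_eigennode(matrix: OmicsMatrix, partition: ModulePartition) -> EigennodeMatrix:
    """First principal component of each module's standardized member rows,
    restandardized over samples and sign-oriented toward the module mean
    profile.  ``var_explained`` is the leading squared singular value over
    the total."""
    rows, var_exp, names = [], [], []
    X = matrix.values
    n_samples = X.shape[1]
    for lab in partition.module_labels:
        members = partition.members(lab)
        sub = X.loc[members].to_numpy(dtype=float)
        Xs, ok = _standardize_rows(sub)
        if not ok.all():
            logger.warning("module %s: dropped %d zero-variance member(s) from PC computation",
                           lab, int((~ok).sum()))
        if Xs.shape[0] == 0:
            raise ValueError(f"module {lab} has no member with nonzero variance")
        U, s, Vt = np.linalg.svd(Xs, full_matrices=False)
        v = Vt[0]
        sd = v.std(ddof=1)
        if sd == 0:
            raise ValueError(f"module {lab}: degenerate eigennode")
        v = (v - v.mean()) / sd
        mean_prof = Xs.mean(axis=0)
        if np.dot(v, mean_prof - mean_prof.mean()) < 0:
            v = -v
        rows.append(v)
        var_exp.append(float(s[0] ** 2 / np.sum(s**2)))
        names.append(partition.module_column_name(lab))
    if not rows:
        values = pd.DataFrame(np.empty((0, n_samples)), columns=X.columns)
        return EigennodeMatrix(values, pd.Series(dtype=float))
    values = pd.DataFrame(np.vstack(rows), index=names, columns=X.columns)
    return EigennodeMatrix(values, pd.Series(var_exp, index=names))


def kme(
    matrix: OmicsMatrix,
    eigennodes: EigennodeMatrix,
    method: str = "bicor",
    max_p_outliers: float = 0.05,
) -> pd.DataFrame:
    """Node x module table of correlations between each feature profile and
    each eigennode (same correlation flavor as the network by default)."""
    if list(matrix.values.columns) != list(eigennodes.values.columns):
        raise ValueError("matrix and eigennodes must share an identically ordered sample set")
    X = matrix.values.to_numpy(dtype=float)
    E = eigennodes.values.to_numpy(dtype=float)
    if E.shape[0] == 0:
        return pd.DataFrame(index=matrix.values.index)

    def prep(rows: np.ndarray) -> np.ndarray:
        out = np.empty_like(rows)
        for i in range(rows.shape[0]):
            if method == "bicor":
                out[i], _ = _biweight_prepare(rows[i], max_p_outliers)
            else:
                c = rows[i] - rows[i].mean()
                nrm = np.sqrt(np.sum(c * c))
                out[i] = c / nrm if nrm > 0 else 0.0
        return out

    K = np.clip(prep(X) @ prep(E).T, -1.0, 1.0)
    return pd.DataFrame(K, index=matrix.values.index, columns=eigennodes.values.index)


def trim_modules(partition: ModulePartition, kme_table: pd.DataFrame, params: NetworkParams) -> ModulePartition:
    """Remove weakly connected members and dissolve coreless modules.

    Members whose own-module kME falls below ``min_kme_to_stay`` become
    unassigned; a module is dissolved unless at least ``min_core_kme_size``
    remaining members have kME above ``min_core_kme``.
    """
    labels = partition.labels.copy()
    for lab in partition.module_labels:
        col = partition.module_column_name(lab)
        members = partition.members(lab)
        own = kme_table.loc[members, col]
        stay = own >= params.min_kme_to_stay
        labels.loc[[m for m, s in zip(members, stay) if not s]] = 0
        core = int((own[stay] > params.min_core_kme).sum())
        if core < params.min_core_kme_size:
            labels.loc[members] = 0
    return ModulePartition(labels, prefix=partition.prefix).relabel_by_size()


def merge_modules(
    matrix: OmicsMatrix,
    partition: ModulePartition,
    params: NetworkParams,
    max_iter: int = 50,
) -> tuple[ModulePartition, EigennodeMatrix]:
    """Iteratively merge modules whose eigennodes cluster below
    ``merge_cut_height`` on dissimilarity ``1 - cor``, until no pair of
    final eigennodes is closer than the cut."""
    part = partition
    eig = module_eigennode(matrix, part)
    for _ in range(max_iter):
        m = part.n_modules
        if m <= 1:
            break
        E = eig.values.to_numpy(dtype=float)
        if params.merge_corr_method == "bicor":
            C = np.clip(
                np.vstack([_biweight_prepare(e, params.max_p_outliers)[0] for e in E])
                @ np.vstack([_biweight_prepare(e, params.max_p_outliers)[0] for e in E]).T,
                -1.0, 1.0,
            )
        else:
            C = np.corrcoef(E)
        D = np.clip(1.0 - C, 0.0, 2.0)
        np.fill_diagonal(D, 0.0)
        Z = linkage(squareform((D + D.T) / 2.0, checks=False), method="average")
        clusters = fcluster(Z, t=params.merge_cut_height, criterion="distance")
        if len(np.unique(clusters)) == m:
            break
        labels = part.labels.copy()
        module_order = part.module_labels  # aligned with eigennode rows
        for c in np.unique(clusters):
            group = [module_order[i] for i in np.flatnonzero(clusters == c)]
            if len(group) > 1:
                target = group[0]
                for lab in group[1:]:
                    labels[labels == lab] = target
        part = ModulePartition(labels, prefix=part.prefix).relabel_by_size()
        eig = module_eigennode(matrix, part)
    return part, eig


def intramodular_connectivity(adj: pd.DataFrame, partition: ModulePartition) -> pd.DataFrame:
    """Per-node connectivity: kTotal (all neighbors), kWithin (same-module
    neighbors; 0 for unassigned nodes), kOut = kTotal - kWithin, and
    kDiff = kWithin - kOut."""
    if list(adj.index) != list(partition.labels.index):
        raise ValueError("adjacency and partition node sets differ")
    A = adj.to_numpy(dtype=float).copy()
    np.fill_diagonal(A, 0.0)
    k_total = A.sum(axis=1)
    lab = partition.labels.to_numpy()
    same = (lab[:, None] == lab[None, :]) & (lab[:, None] > 0)
    k_within = (A * same).sum(axis=1)
    k_out = k_total - k_within
    return pd.DataFrame(
        {"kTotal": k_total, "kWithin": k_within, "kOut": k_out, "kDiff": k_within - k_out},
        index=adj.index,
    )


# ---------------------------------------------------------------------------
# full inference


def infer_network(matrix: OmicsMatrix, params: NetworkParams | None = None) -> NetworkResult:
    """Run the whole inference chain on a preprocessed matrix.

    correlation -> soft threshold -> signed adjacency -> signed TOM ->
    module detection -> eigennodes -> kME trim -> eigennode merge ->
    intramodular connectivity.  Deterministic given inputs and params.
    """
    params = params or NetworkParams()
    prefix = "hME" if matrix.kingdom == "host" else "mME"
    corr = correlation_matrix(matrix, params)
    n_samples = matrix.shape[1]
    if params.power is not None:
        beta = float(params.power)
        _, fit_table = pick_soft_threshold(corr, (beta,), params.r2_cut, n_samples)
    else:
        beta, fit_table = pick_soft_threshold(
            corr, params.candidate_powers, params.r2_cut, n_samples
        )
    adj = signed_adjacency(corr, beta)
    tom = signed_tom(adj)
    diss = pd.DataFrame(
        1.0 - tom.to_numpy(), index=tom.index, columns=tom.columns
    )
    np.fill_diagonal(diss.values, 0.0)
    partition = detect_modules(diss, params, prefix=prefix, corr=corr, n_samples=n_samples)
    if partition.n_modules > 0:
        eig = module_eigennode(matrix, partition)
        kme_table = kme(matrix, eig, max_p_outliers=params.max_p_outliers)
        partition = trim_modules(partition, kme_table, params)
    if partition.n_modules > 0:
        partition, eig = merge_modules(matrix, partition, params)
    else:
        eig = module_eigennode(matrix, partition)
    kme_table = kme(matrix, eig, max_p_outliers=params.max_p_outliers)
    conn = intramodular_connectivity(adj, partition)
    return NetworkResult(
        partition=partition,
        eigennodes=eig,
        kme=kme_table,
        connectivity=conn,
        fit_table=fit_table,
        power=beta,
    )
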