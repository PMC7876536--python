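"""Reading, writing and validation of the pipeline's tabular artifacts.

All matrices travel as :class:`OmicsMatrix` (features x samples), sample
metadata as :class:`SampleTable`, and gene->term annotations as
:class:`AnnotationMap`.  Files are plain delimited text (TSV by default,
CSV by flag); every writer output round-trips losslessly through the
matching reader.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field


import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

KINGDOMS = ("host", "microbe")
STAGES = ("raw_counts", "normalized_log2", "corrected")
WATER_LEVELS = ("FW", "SW")
FEED_LEVELS = ("FO", "VO", "FOVO", "VOFO")
SEX_LEVELS = ("M", "F", "unknown")

# float format used by every writer; 17 significant digits round-trip
# IEEE doubles exactly
_FLOAT_FMT = "%.17g"


@dataclass
class OmicsMatrix:
    """A features x samples numeric table tagged with kingdom and stage.

    Parameters
    ----------
    values
        DataFrame with feature ids as index and sample ids as columns.
    kingdom
        ``"host"`` (gene expression) or ``"microbe"`` (OTU abundance).
    stage
        ``"raw_counts"``, ``"normalized_log2"`` or ``"corrected"``.
    """

    values: pd.DataFrame
    kingdom: str
    stage: str = "raw_counts"

    def __post_init__(self) -> None:
        if self.kingdom not in KINGDOMS:
            raise ValueError(f"kingdom must be one of {KINGDOMS}, got {self.kingdom!r}")
        if self.stage not in STAGES:
            raise ValueError(f"stage must be one of {STAGES}, got {self.stage!r}")
        if self.values.shape[0] == 0 or self.values.shape[1] == 0:
            raise ValueError("empty omics table")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dups[:5]}")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups[:5]}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            bad = _first_non_numeric(self.values)
            raise ValueError(f"non-numeric cell at {bad}")
        if not np.isfinite(arr).all():
            bad = _first_non_finite(self.values)
            raise ValueError(f"non-finite cell at {bad}")
        if self.stage == "raw_counts" and (arr < 0).any():
            raise ValueError("raw_counts stage requires all values >= 0")
        self.values = self.values.astype(float)

    @property
    def feature_ids(self) -> list[str]:
        return [str(i) for i in self.values.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(c) for c in self.values.columns]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_samples(self, sample_ids) -> "OmicsMatrix":
        missing = [s for s in sample_ids if s not in self.values.columns]
        if missing:
            raise KeyError(f"samples not in matrix: {missing[:5]}")
        return OmicsMatrix(self.values.loc[:, list(sample_ids)].copy(), self.kingdom, self.stage)

    def subset_features(self, feature_ids) -> "OmicsMatrix":
        missing = [f for f in feature_ids if f not in self.values.index]
        if missing:
            raise KeyError(f"features not in matrix: {missing[:5]}")
        return OmicsMatrix(self.values.loc[list(feature_ids)].copy(), self.kingdom, self.stage)


def _first_non_numeric(df: pd.DataFrame) -> str:
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.to_numpy().argmax()]
            return f"row {row!r}, column {col!r}"
    return "unknown position"


def _first_non_finite(df: pd.DataFrame) -> str:
    arr = df.to_numpy(dtype=float)
    i, j = np.argwhere(~np.isfinite(arr))[0]
    return f"row {df.index[i]!r}, column {df.columns[j]!r}"


@dataclass
class SampleTable:
    """Per-sample metadata with the replicate-group key.

    ``group_id`` is synthesized deterministically as ``<feed>_<water>_D<day>``
    so replicate groups are a pure function of (feed, water, day).
    """

    table: pd.DataFrame  # indexed by sample_id

    def __post_init__(self) -> None:
        df = self.table
        required = {"day", "water", "feed", "sex", "weight_g", "length_mm"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"sample table missing columns: {sorted(missing)}")
        if df.index.duplicated().any():
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        bad_water = set(df["water"]) - set(WATER_LEVELS)
        if bad_water:
            raise ValueError(f"unknown water level(s) {sorted(bad_water)}; allowed: {WATER_LEVELS}")
        bad_feed = set(df["feed"]) - set(FEED_LEVELS)
        if bad_feed:
            raise ValueError(f"unknown feed level(s) {sorted(bad_feed)}; allowed: {FEED_LEVELS}")
        bad_sex = set(df["sex"]) - set(SEX_LEVELS)
        if bad_sex:
            raise ValueError(f"unknown sex level(s) {sorted(bad_sex)}; allowed: {SEX_LEVELS}")
        day = pd.to_numeric(df["day"], errors="raise")
        if (day < 0).any() or (day != day.astype(int)).any():
            raise ValueError("day must be a non-negative integer")
        self.table = df.assign(
            day=day.astype(int),
            weight_g=pd.to_numeric(df["weight_g"]),
            length_mm=pd.to_numeric(df["length_mm"]),
        )
        for col in ("weight_g", "length_mm"):
            if (self.table[col] <= 0).any():
                raise ValueError(f"{col} must be positive")
        self.table["group_id"] = [
            f"{r.feed}_{r.water}_D{r.day}" for r in self.table.itertuples()
        ]

    @property
    def sample_ids(self) -> list[str]:
        return [str(i) for i in self.table.index]

    @property
    def group_ids(self) -> pd.Series:
        return self.table["group_id"]

    def subset(self, sample_ids) -> "SampleTable":
        missing = [s for s in sample_ids if s not in self.table.index]
        if missing:
            raise KeyError(f"samples not in table: {missing[:5]}")
        return SampleTable(self.table.loc[list(sample_ids)].drop(columns="group_id"))


@dataclass
class AnnotationMap:
    """gene id -> set of term ids, plus term descriptions."""

    gene_terms: dict[str, set[str]]
    term_description: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        empty = [g for g, t in self.gene_terms.items() if not t]
        if empty:
            raise ValueError(f"genes with empty term sets: {empty[:5]}")

    @property
    def terms(self) -> set[str]:
        out: set[str] = set()
        for t in self.gene_terms.values():
            out |= t
        return out


def _sep(delimiter: str) -> str:
    return {"tsv": "\t", "csv": ","}.get(delimiter, delimiter)


def read_omics_table(
    path,
    kingdom: str,
    orientation: str = "features_in_rows",
    stage: str = "raw_counts",
    delimiter: str = "tsv",
) -> OmicsMatrix:
    """Read a delimited numeric table into an :class:`OmicsMatrix`.

    Orientation is always explicit; nothing is ever silently transposed.
    """
    if orientation not in ("features_in_rows", "samples_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    try:
        df = pd.read_csv(path, sep=_sep(delimiter), index_col=0)
    except pd.errors.ParserError as exc:
        raise ValueError(f"ragged or malformed table {path}: {exc}") from exc
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"empty table: {path}")
    # pandas turns unparsable cells into object columns or NaN; both rejected
    if df.isna().any().any():
        bad = _first_na(df)
        raise ValueError(f"missing/non-numeric cell in {path} at {bad}")
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            coerced = pd.to_numeric(df[col], errors="coerce")
            if coerced.isna().any():
                row = df.index[coerced.isna().to_numpy().argmax()]
                raise ValueError(
                    f"non-numeric cell in {path} at row {row!r}, column {col!r}"
                )
            df[col] = coerced
    if orientation == "samples_in_rows":
        df = df.T
    df.index = pd.Index([str(i) for i in df.index])
    df.columns = pd.Index([str(c) for c in df.columns])
    return OmicsMatrix(df, kingdom=kingdom, stage=stage)


def _first_na(df: pd.DataFrame) -> str:
    mask = df.isna().to_numpy()
    i, j = np.argwhere(mask)[0]
    return f"row {df.index[i]!r}, column {df.columns[j]!r}"


def write_omics_table(matrix: OmicsMatrix, path, delimiter: str = "tsv") -> None:
    matrix.values.to_csv(path, sep=_sep(delimiter), float_format=_FLOAT_FMT, index_label="id")


def read_sample_table(path, delimiter: str = "tsv") -> SampleTable:
    df = pd.read_csv(path, sep=_sep(delimiter), dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise ValueError("sample table requires a 'sample_id' column")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample ids: {dups}")
    df = df.set_index("sample_id")
    df = df.drop(columns=[c for c in ("group_id",) if c in df.columns])
    return SampleTable(df)


def write_sample_table(samples: SampleTable, path, delimiter: str = "tsv") -> None:
    samples.table.to_csv(path, sep=_sep(delimiter), float_format=_FLOAT_FMT, index_label="sample_id")


def read_annotation(path, delimiter: str = "tsv") -> AnnotationMap:
    """Read a (gene_id, term_id, description) table."""
    df = pd.read_csv(path, sep=_sep(delimiter), dtype=str)
    required = {"gene_id", "term_id"}
    if not required <= set(df.columns):
        raise ValueError("annotation table requires columns gene_id, term_id[, description]")
    gene_terms: dict[str, set[str]] = {}
    desc: dict[str, str] = {}
    for row in df.itertuples():
        gene_terms.setdefault(row.gene_id, set()).add(row.term_id)
        if "description" in df.columns and isinstance(row.description, str):
            desc[row.term_id] = row.description
    return AnnotationMap(gene_terms, desc)


def write_module_assignments(partition, kme, connectivity, path, delimiter: str = "tsv") -> None:
    """Write one row per node: module label, own-module kME, and k statistics.

    ``partition`` is a :class:`holonet.network.ModulePartition`, ``kme`` the
    node x module kME DataFrame, ``connectivity`` the per-node connectivity
    DataFrame (kTotal/kWithin/kOut/kDiff).  Unassigned nodes carry label 0
    and an own-module kME of NaN-free 0.0 by convention.
    """
    nodes = list(partition.labels.index)
    if connectivity is not None and set(connectivity.index) != set(nodes):
        raise ValueError("node sets of partition and connectivity differ")
    if kme is not None and not set(nodes) <= set(kme.index):
        raise ValueError("node sets of partition and kME table differ")
    rows = []
    for node in nodes:
        label = int(partition.labels.loc[node])
        own = 0.0
        if kme is not None and label > 0:
            col = partition.module_column_name(label)
            if col in kme.columns:
                own = float(kme.loc[node, col])
        rec = {"id": node, "module": label, "kME_own": own}
        if connectivity is not None:
            for k in ("kTotal", "kWithin", "kOut", "kDiff"):
                rec[k] = float(connectivity.loc[node, k])
        else:
            for k in ("kTotal", "kWithin", "kOut", "kDiff"):
                rec[k] = 0.0
        rows.append(rec)
    out = pd.DataFrame(rows, columns=["id", "module", "kME_own", "kTotal", "kWithin", "kOut", "kDiff"])
    out.to_csv(path, sep=_sep(delimiter), float_format=_FLOAT_FMT, index=False)


def read_module_assignments(path, delimiter: str = "tsv") -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sep(delimiter), dtype={"id": str})
    df = df.set_index("id")
    df["module"] = df["module"].astype(int)
    return df


def align_samples(host: OmicsMatrix, microbe: OmicsMatrix, samples: SampleTable):
    """Intersect sample sets of the two kingdoms and the metadata table.

    Samples missing from any of the three are dropped with a logged warning;
    per-kingdom sample sets may legitimately differ after outlier removal.
    """
    common = [s for s in samples.sample_ids if s in host.values.columns and s in microbe.values.columns]
    dropped = sorted(
        (set(host.sample_ids) | set(microbe.sample_ids) | set(samples.sample_ids)) - set(common)
    )
    if dropped:
        logger.warning("dropping %d sample(s) absent from at least one table: %s", len(dropped), dropped)
    if not common:
        raise ValueError("no samples shared between host, microbe and metadata tables")
    return host.subset_samples(common), microbe.subset_samples(common), samples.subset(common)
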