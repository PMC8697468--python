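"""Parsing and preparation of OTU count tables.

MicrobiomeHD-style inputs are tab-separated: rows are OTUs whose first
column holds a semicolon-delimited taxonomy lineage with two-character
rank prefixes (``k__``, ``p__``, ..., ``s__``), the remaining columns are
per-sample counts.  The preparation pipeline splits lineages, pools OTU
counts at a chosen rank (family or genus), transposes to a
samples-by-features matrix, and attaches per-sample disease-state labels
from a metadata table.  Optional covariates (age, gender, BMI, ...) can be
fused in as extra feature columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Fixed rank order, most to least inclusive.
RANK_ORDER = ("d", "k", "p", "c", "o", "f", "g", "s")

RANK_NAMES = {
    "domain": "d",
    "kingdom": "k",
    "phylum": "p",
    "class": "c",
    "order": "o",
    "family": "f",
    "genus": "g",
    "species": "s",
}

DEFAULT_LABEL_COLUMN = "DiseaseState"


class LineageParseError(ValueError):
    """A lineage field could not be assigned to a taxonomic rank."""


class OtuTableError(ValueError):
    """Structural problem in an OTU table or metadata file."""


def _canonical_rank(rank: str) -> str:
    """Accept either a single-letter rank symbol or a full rank name."""
    if rank in RANK_ORDER:
        return rank
    try:
        return RANK_NAMES[rank.lower()]
    except KeyError:
        raise ValueError(
            f"unknown rank {rank!r}; expected one of {sorted(RANK_NAMES)} "
            f"or symbols {RANK_ORDER}"
        ) from None


@dataclass(frozen=True)
class TaxonomyLineage:
    """Ordered mapping from rank symbol to taxon name; absent ranks omitted."""

    ranks: Mapping[str, str]

    def __post_init__(self) -> None:
        for sym, name in self.ranks.items():
            if sym not in RANK_ORDER:
                raise LineageParseError(f"unknown rank symbol {sym!r}")
            if not name:
                raise LineageParseError("taxon name must not be empty; omit the rank instead")
        # normalize to fixed order
        ordered = {s: self.ranks[s] for s in RANK_ORDER if s in self.ranks}
        object.__setattr__(self, "ranks", ordered)

    def get(self, rank: str) -> str | None:
        return self.ranks.get(_canonical_rank(rank))

    def nearest_classified_ancestor(self, rank: str) -> str | None:
        """Deepest named taxon at or above ``rank``."""
        sym = _canonical_rank(rank)
        for s in reversed(RANK_ORDER[: RANK_ORDER.index(sym) + 1]):
            if s in self.ranks:
                return self.ranks[s]
        return None

    def to_string(self) -> str:
        return ";".join(f"{s}__{n}" for s, n in self.ranks.items())


def parse_lineage(raw: str) -> TaxonomyLineage:
    """Split a semicolon-delimited lineage string into a :class:`TaxonomyLineage`.

    Fields may carry two-character rank prefixes (``f__Lachnospiraceae``);
    prefix-less fields are assigned positionally starting at kingdom.  An
    empty name after the prefix (``g__``) marks the rank as absent.
    """
    if not raw or not raw.strip():
        raise LineageParseError("empty lineage string")
    ranks: dict[str, str] = {}
    # positional fallback starts at kingdom, the usual leading rank
    positional = list(RANK_ORDER[1:])
    for i, fld in enumerate(raw.split(";")):
        fld = fld.strip()
        if not fld:
            continue
        if len(fld) >= 3 and fld[1:3] == "__":
            sym, name = fld[0], fld[3:].strip()
            if sym not in RANK_ORDER:
                raise LineageParseError(f"unknown rank prefix in field {fld!r}")
            if sym in ranks:
                raise LineageParseError(f"rank {sym!r} appears twice in {raw!r}")
            if name:
                ranks[sym] = name
        else:
            if i >= len(positional):
                raise LineageParseError(f"cannot place prefix-less field {fld!r}")
            ranks[positional[i]] = fld
    return TaxonomyLineage(ranks)


@dataclass
class OtuTable:
    """OTU-by-sample count matrix with one taxonomy lineage per row."""

    lineages: list[TaxonomyLineage]
    sample_ids: list[str]
    counts: np.ndarray  # (#OTUs, #samples), non-negative

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise OtuTableError("counts must be a 2-D matrix")
        if len(self.lineages) != self.counts.shape[0]:
            raise OtuTableError(
                f"{len(self.lineages)} lineages but {self.counts.shape[0]} count rows"
            )
        if len(self.sample_ids) != self.counts.shape[1]:
            raise OtuTableError("sample_ids length mismatch with count columns")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise OtuTableError("duplicate sample ids")
        if np.any(self.counts < 0):
            r, c = np.argwhere(self.counts < 0)[0]
            raise OtuTableError(f"negative count at row {r}, column {c}")

    @property
    def n_otus(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]


@dataclass
class SampleFeatureMatrix:
    """Samples-by-features numeric matrix at a chosen taxonomic rank."""

    sample_ids: list[str]
    feature_names: list[str]
    values: np.ndarray  # (#samples, #features), non-negative

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.feature_names)):
            raise OtuTableError("values shape inconsistent with ids/feature names")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise OtuTableError("duplicate feature names")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_names)


@dataclass
class LabeledDataset:
    """A sample-feature matrix plus one class label per sample.

    ``class_names`` is the sorted list of distinct labels; serialized forms
    place the label column last.
    """

    matrix: SampleFeatureMatrix
    labels: list[str]
    class_names: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.matrix.sample_ids):
            raise OtuTableError("one label per sample required")
        observed = sorted(set(self.labels))
        if self.class_names is None:
            self.class_names = observed
        if len(observed) < 2:
            raise OtuTableError(f"need >= 2 classes, got {observed}")

    @property
    def X(self) -> np.ndarray:
        return self.matrix.values

    @property
    def y(self) -> np.ndarray:
        """Integer-encoded labels in ``class_names`` order."""
        index = {c: i for i, c in enumerate(self.class_names)}
        return np.array([index[l] for l in self.labels], dtype=int)

    def to_frame(self) -> pd.DataFrame:
        df = self.matrix.to_frame()
        df[DEFAULT_LABEL_COLUMN] = self.labels
        return df


# ---------------------------------------------------------------------------
# I/O


def read_otu_table(path, sep: str = "\t") -> OtuTable:
    """Read a tab-separated OTU table: header = sample ids, column 1 = lineage."""
    with open(path) as fh:  # pandas silently renames duplicate header fields
        header = fh.readline().rstrip("\n").split(sep)[1:]
    seen = set()
    for sid in header:
        if sid in seen:
            raise OtuTableError(f"duplicate sample id in header: {sid!r}")
        seen.add(sid)
    df = pd.read_csv(path, sep=sep, header=0, index_col=0)
    counts = df.to_numpy()
    if not np.issubdtype(counts.dtype, np.number):
        raise OtuTableError("non-numeric count values")
    if np.any(counts < 0):
        r, c = np.argwhere(counts < 0)[0]
        raise OtuTableError(
            f"negative value at OTU row {df.index[r]!r}, sample {df.columns[c]!r}"
        )
    lineages = [parse_lineage(str(s)) for s in df.index]
    if np.allclose(counts, np.round(counts)):
        counts = np.round(counts).astype(np.int64)
    return OtuTable(lineages, [str(c) for c in df.columns], counts)


def write_otu_table(table: OtuTable, path, sep: str = "\t") -> None:
    df = pd.DataFrame(table.counts, columns=table.sample_ids)
    df.insert(0, "taxonomy", [l.to_string() for l in table.lineages])
    df.to_csv(path, sep=sep, index=False)


def read_metadata(path, sep: str = "\t") -> pd.DataFrame:
    """Metadata table keyed by sample id (first column)."""
    meta = pd.read_csv(path, sep=sep, header=0, index_col=0)
    meta.index = meta.index.astype(str)
    if meta.index.duplicated().any():
        raise OtuTableError("duplicate sample id in metadata")
    return meta


def write_labeled_dataset(ds: LabeledDataset, path, sep: str = "\t",
                          label_column: str = DEFAULT_LABEL_COLUMN) -> None:
    """Serialize as a samples-by-features table, label column last."""
    df = ds.matrix.to_frame()
    df[label_column] = ds.labels
    df.to_csv(path, sep=sep, index_label="sample_id")


def read_labeled_dataset(path, sep: str = "\t",
                         label_column: str = DEFAULT_LABEL_COLUMN) -> LabeledDataset:
    df = pd.read_csv(path, sep=sep, header=0, index_col=0)
    if label_column not in df.columns:
        raise OtuTableError(f"label column {label_column!r} missing")
    labels = df[label_column].astype(str).tolist()
    feats = df.drop(columns=[label_column])
    mat = SampleFeatureMatrix(
        [str(i) for i in df.index], [str(c) for c in feats.columns], feats.to_numpy(float)
    )
    return LabeledDataset(mat, labels)


# ---------------------------------------------------------------------------
# Aggregation and labeling


def aggregate_to_rank(table: OtuTable, rank: str,
                      unclassified_policy: str = "drop",
                      normalize: bool = False) -> SampleFeatureMatrix:
    """Pool OTU counts by taxon name at ``rank`` and transpose to samples x features.

    Each output feature is the column-wise sum of counts over all OTUs whose
    lineage carries that taxon at ``rank``.  OTUs lacking the rank are either
    dropped (default) or bucketed under their nearest classified ancestor
    (``unclassified_policy="bucket"``).  Features are ordered
    lexicographically for determinism.  ``normalize=True`` applies
    total-sum scaling per sample afterwards.
    """
    if unclassified_policy not in ("drop", "bucket"):
        raise ValueError(f"unknown unclassified_policy {unclassified_policy!r}")
    sym = _canonical_rank(rank)
    groups: dict[str, list[int]] = {}
    n_at_rank = 0
    for i, lin in enumerate(table.lineages):
        name = lin.ranks.get(sym)
        if name is not None:
            n_at_rank += 1
        elif unclassified_policy == "bucket":
            anc = lin.nearest_classified_ancestor(sym)
            name = f"unclassified_{anc}" if anc is not None else None
        if name is not None:
            groups.setdefault(name, []).append(i)
    if n_at_rank == 0:
        raise OtuTableError(f"rank {rank!r} absent from table")
    feature_names = sorted(groups)
    values = np.empty((table.n_samples, len(feature_names)), dtype=float)
    for j, name in enumerate(feature_names):
        values[:, j] = table.counts[groups[name], :].sum(axis=0)
    if normalize:
        totals = values.sum(axis=1, keepdims=True)
        totals[totals == 0] = 1.0
        values = values / totals
    return SampleFeatureMatrix(list(table.sample_ids), feature_names, values)


def attach_labels(matrix: SampleFeatureMatrix, metadata: pd.DataFrame,
                  label_column: str = DEFAULT_LABEL_COLUMN) -> LabeledDataset:
    """Join disease-state labels onto the feature matrix by sample id.

    The join is id-based (row order in either table is irrelevant); metadata
    rows for samples absent from the matrix are ignored.
    """
    if label_column not in metadata.columns:
        raise OtuTableError(f"label column {label_column!r} not in metadata")
    missing = [s for s in matrix.sample_ids if s not in metadata.index]
    if missing:
        raise OtuTableError(f"samples missing from metadata: {missing}")
    labels = [str(metadata.at[s, label_column]) for s in matrix.sample_ids]
    return LabeledDataset(matrix, labels)


def fuse_metadata(ds: LabeledDataset, metadata: pd.DataFrame,
                  fields: Sequence[str]) -> LabeledDataset:
    """Append metadata covariates as extra feature columns.

    Numeric fields are appended unchanged; categorical fields are one-hot
    encoded (one column per category).  Missing values are imputed — numeric
    by the median of observed values, categorical by the mode — and each
    imputation is logged.  A field constant after imputation is dropped with
    a warning.
    """
    if not fields:
        return replace(ds)
    missing_fields = [f for f in fields if f not in metadata.columns]
    if missing_fields:
        raise OtuTableError(f"metadata fields absent: {missing_fields}")
    sub = metadata.loc[ds.matrix.sample_ids, list(fields)].copy()
    new_cols: list[pd.Series | pd.DataFrame] = []
    for f in fields:
        col = sub[f]
        if pd.api.types.is_numeric_dtype(col):
            if col.isna().any():
                med = float(col.median())
                logger.info("imputed %d missing values of %r with median %g",
                            int(col.isna().sum()), f, med)
                col = col.fillna(med)
            if col.nunique() <= 1:
                logger.warning("field %r constant after imputation; dropped", f)
                continue
            new_cols.append(col.astype(float))
        else:
            col = col.astype("object")
            if col.isna().any():
                mode = col.mode(dropna=True)
                if mode.empty:
                    logger.warning("field %r entirely missing; dropped", f)
                    continue
                logger.info("imputed %d missing values of %r with mode %r",
                            int(col.isna().sum()), f, mode.iloc[0])
                col = col.fillna(mode.iloc[0])
            if col.nunique() <= 1:
                logger.warning("field %r constant after imputation; dropped", f)
                continue
            dummies = pd.get_dummies(col, prefix=f, dtype=float)
            new_cols.append(dummies)
    if not new_cols:
        return replace(ds)
    extra = pd.concat(new_cols, axis=1)
    values = np.hstack([ds.matrix.values, extra.to_numpy(float)])
    names = list(ds.matrix.feature_names) + [str(c) for c in extra.columns]
    mat = SampleFeatureMatrix(list(ds.matrix.sample_ids), names, values)
    return LabeledDataset(mat, list(ds.labels), list(ds.class_names))


def prepare_dataset(otu_path, meta_path, rank: str = "family",
                    label_column: str = DEFAULT_LABEL_COLUMN,
                    unclassified_policy: str = "drop",
                    fuse_fields: Iterable[str] = (),
                    normalize: bool = False) -> LabeledDataset:
    """End-to-end preparation: read, aggregate, label, optionally fuse metadata."""
    table = read_otu_table(otu_path)
    meta = read_metadata(meta_path)
    mat = aggregate_to_rank(table, rank, unclassified_policy, normalize=normalize)
    ds = attach_labels(mat, meta, label_column)
    fuse_fields = list(fuse_fields)
    if fuse_fields:
        ds = fuse_metadata(ds, meta, fuse_fields)
    return ds
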