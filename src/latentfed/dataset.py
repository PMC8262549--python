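"""Row-aligned tabular datasets and the operations a VFL study needs on them:
CSV I/O, row filtering, class balancing by random undersampling, stratified
train/test splitting, and vertical partitioning across sites.

Internals: features live in a float64 ``pandas.DataFrame`` whose index holds
the stable row IDs.  Categorical cells are level codes (0..card-1); missing
cells of either kind are NaN.  Labels, when present, are a float Series
aligned to the same index with values in {0, 1} (NaN = missing label).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from .errors import (
    DegenerateLabelsError,
    FormatError,
    InputError,
    SchemaError,
    StratificationError,
)
from .schema import CATEGORICAL, CONTINUOUS, TabularSchema, VerticalPlan


class TabularDataset:
    """A schema, a feature grid with stable row IDs, and optional binary labels."""

    def __init__(
        self,
        schema: TabularSchema,
        features: pd.DataFrame,
        labels: Optional[pd.Series] = None,
    ):
        if tuple(features.columns) != schema.feature_names:
            raise SchemaError(
                f"feature columns {tuple(features.columns)} do not match "
                f"schema {schema.feature_names}"
            )
        if features.index.has_duplicates:
            raise SchemaError("row IDs must be unique")
        if labels is not None:
            if not features.index.equals(labels.index):
                raise SchemaError("labels not aligned to feature rows")
            vals = labels.dropna().unique()
            if not np.isin(vals, [0.0, 1.0]).all():
                raise SchemaError(f"labels must be binary, got {sorted(vals)}")
        self.schema = schema
        self.features = features.astype(np.float64, copy=False)
        self.labels = (
            labels.astype(np.float64, copy=False) if labels is not None else None
        )

    # -- basic views -----------------------------------------------------
    @property
    def row_ids(self) -> np.ndarray:
        return self.features.index.to_numpy()

    @property
    def n_rows(self) -> int:
        return len(self.features)

    @property
    def n_features(self) -> int:
        return len(self.schema.columns)

    @property
    def has_labels(self) -> bool:
        return self.labels is not None

    def label_array(self) -> np.ndarray:
        if self.labels is None:
            raise DegenerateLabelsError("dataset carries no labels")
        y = self.labels.to_numpy()
        if np.isnan(y).any():
            raise DegenerateLabelsError("dataset has missing labels")
        return y.astype(np.int64)

    def select_rows(self, row_ids: Sequence) -> "TabularDataset":
        feats = self.features.loc[list(row_ids)]
        labs = self.labels.loc[list(row_ids)] if self.labels is not None else None
        return TabularDataset(self.schema, feats, labs)

    def _take(self, positions: np.ndarray) -> "TabularDataset":
        feats = self.features.iloc[positions]
        labs = self.labels.iloc[positions] if self.labels is not None else None
        return TabularDataset(self.schema, feats, labs)

    def select_columns(self, names: Sequence[str]) -> "TabularDataset":
        """Column-sliced copy (labels dropped: slices travel to sites)."""
        sub = self.schema.subset(names)
        return TabularDataset(sub, self.features[list(names)], None)

    def without_labels(self) -> "TabularDataset":
        return TabularDataset(
            TabularSchema(self.schema.columns, target=None), self.features, None
        )

    def class_counts(self) -> dict[int, int]:
        y = self.label_array()
        return {0: int((y == 0).sum()), 1: int((y == 1).sum())}

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"TabularDataset(n_rows={self.n_rows}, n_features={self.n_features}, "
            f"labels={self.has_labels})"
        )


@dataclass(frozen=True)
class SitePartition:
    """One site's vertical slice: an index and a label-free dataset.

    Row IDs are identical in content and order across all partitions of a
    plan, which is what lets the relay align rows positionally.
    """

    site_index: int
    dataset: TabularDataset


@dataclass(frozen=True)
class FilterCounts:
    dropped_nonnull: int
    dropped_unlabeled: int


# ---------------------------------------------------------------------------
# I/O


def read_table(path, schema: TabularSchema) -> TabularDataset:
    """Read a delimited text file (RFC-4180, header required) against a schema.

    Row IDs are assigned from file order (0-based).  Unparseable continuous
    cells and empty cells become missing (NaN).  Categorical cells are mapped
    through the column's declared levels when present, otherwise parsed as
    integer codes; out-of-range or unknown codes become missing.
    """
    with open(path, newline="") as fh:
        header = next(csv.reader(fh), None)
    if header is None:
        raise FormatError(f"{path}: empty file")
    if len(set(header)) != len(header):
        dupes = sorted({h for h in header if header.count(h) > 1})
        raise FormatError(f"{path}: duplicate header columns {dupes}")
    needed = list(schema.feature_names) + ([schema.target] if schema.target else [])
    missing = [c for c in needed if c not in header]
    if missing:
        raise SchemaError(f"{path}: header lacks declared columns {missing}")

    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    feats = {}
    for col in schema.columns:
        s = raw[col.name].replace("", np.nan)
        if col.kind == CONTINUOUS:
            feats[col.name] = pd.to_numeric(s, errors="coerce")
        else:
            if col.levels is not None:
                mapping = {lv: float(i) for i, lv in enumerate(col.levels)}
                feats[col.name] = s.map(mapping)
            else:
                codes = pd.to_numeric(s, errors="coerce")
                codes[(codes < 0) | (codes >= col.cardinality)] = np.nan
                feats[col.name] = codes
    frame = pd.DataFrame(feats, columns=list(schema.feature_names))
    frame.index = pd.RangeIndex(len(frame))

    labels = None
    if schema.target is not None:
        labels = pd.to_numeric(raw[schema.target].replace("", np.nan), errors="coerce")
        labels.index = frame.index
    return TabularDataset(schema, frame, labels)


def write_table(ds: TabularDataset, path) -> None:
    """Write features (+ labels if present) as CSV; categorical codes as ints."""
    out = ds.features.copy()
    for col in ds.schema.columns:
        if col.kind == CATEGORICAL:
            s = out[col.name]
            out[col.name] = s.map(lambda v: "" if pd.isna(v) else str(int(v)))
    if ds.labels is not None:
        out[ds.schema.target] = ds.labels.map(
            lambda v: "" if pd.isna(v) else str(int(v))
        )
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Row operations


def balance_by_undersampling(ds: TabularDataset, seed: int) -> TabularDataset:
    """Equalize classes by discarding randomly chosen majority rows.

    All minority rows are retained; majority rows are drawn uniformly without
    replacement with the given seed; the output preserves the input's relative
    row order.  Output size is twice the minority count, putting the chance
    level of any downstream classifier at 50%.
    """
    y = ds.label_array()
    n0, n1 = int((y == 0).sum()), int((y == 1).sum())
    if n0 == 0 or n1 == 0:
        raise DegenerateLabelsError("cannot balance: one class is empty")
    minority = 0 if n0 <= n1 else 1
    keep = np.flatnonzero(y == minority)
    maj_pos = np.flatnonzero(y != minority)
    rng = np.random.default_rng(seed)
    chosen = rng.choice(maj_pos, size=len(keep), replace=False)
    order = np.sort(np.concatenate([keep, chosen]))
    return ds._take(order)


def filter_rows(
    ds: TabularDataset, min_nonnull: int, require_label: bool = False
) -> tuple[TabularDataset, FilterCounts]:
    """Keep rows with strictly more than ``min_nonnull`` nonmissing feature
    cells; optionally drop rows whose label is missing.  Returns the filtered
    dataset and the per-rule exclusion counts (nonnull rule applied first).
    """
    if min_nonnull > ds.n_features:
        raise InputError(
            f"min_nonnull={min_nonnull} exceeds feature count {ds.n_features}"
        )
    nonnull = ds.features.notna().sum(axis=1).to_numpy()
    pass_nonnull = nonnull > min_nonnull
    dropped_nonnull = int((~pass_nonnull).sum())
    keep = pass_nonnull
    dropped_unlabeled = 0
    if require_label:
        if ds.labels is None:
            raise DegenerateLabelsError("require_label on an unlabeled dataset")
        labeled = ds.labels.notna().to_numpy()
        dropped_unlabeled = int((pass_nonnull & ~labeled).sum())
        keep = pass_nonnull & labeled
    out = ds._take(np.flatnonzero(keep))
    return out, FilterCounts(dropped_nonnull, dropped_unlabeled)


def split_train_test(
    ds: TabularDataset, test_fraction: float, seed: int
) -> tuple[TabularDataset, TabularDataset]:
    """Stratified, exact, deterministic split into (train, test)."""
    if not 0.0 < test_fraction < 1.0:
        raise InputError(f"test_fraction must be in (0, 1), got {test_fraction}")
    y = ds.label_array()
    if min(np.bincount(y, minlength=2)) < 2:
        raise StratificationError("each class needs at least 2 rows to stratify")
    idx = np.arange(ds.n_rows)
    train_idx, test_idx = train_test_split(
        idx, test_size=test_fraction, random_state=seed, stratify=y
    )
    train_idx.sort()
    test_idx.sort()
    return ds._take(train_idx), ds._take(test_idx)


def vertical_split(ds: TabularDataset, plan: VerticalPlan) -> list[SitePartition]:
    """Split columns across sites per the plan.  Labels never travel to sites:
    only the target label is gathered centrally, so partitions are label-free.
    """
    plan.validate(ds.schema)
    return [
        SitePartition(i, ds.select_columns(cols))
        for i, cols in enumerate(plan.site_assignments)
    ]
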