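"""Typed column metadata for mixed categorical/continuous tabular data.

A :class:`TabularSchema` declares the ordered feature columns of a dataset
(each either continuous or categorical with a known cardinality) and the
name of a binary target column.  A :class:`VerticalPlan` assigns those
feature columns to k sites, modelling data that is vertically partitioned:
every site holds the same individuals but different columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import yaml

from .errors import PlanError, SchemaError

CONTINUOUS = "continuous"
CATEGORICAL = "categorical"


@dataclass(frozen=True)
class Column:
    """One feature column: a name, a kind, and for categoricals a cardinality.

    ``levels`` optionally maps string levels to integer codes 0..card-1 when
    reading text files; synthetic and latent data use integer codes directly.
    """

    name: str
    kind: str
    cardinality: Optional[int] = None
    levels: Optional[tuple[str, ...]] = None

    def __post_init__(self) -> None:
        if self.kind not in (CONTINUOUS, CATEGORICAL):
            raise SchemaError(f"unknown column kind {self.kind!r} for {self.name!r}")
        if self.kind == CATEGORICAL:
            if self.levels is not None and self.cardinality is None:
                object.__setattr__(self, "cardinality", len(self.levels))
            if self.cardinality is None or self.cardinality < 2:
                raise SchemaError(
                    f"categorical column {self.name!r} needs cardinality >= 2"
                )
            if self.levels is not None and len(self.levels) != self.cardinality:
                raise SchemaError(
                    f"column {self.name!r}: {len(self.levels)} levels but "
                    f"cardinality {self.cardinality}"
                )
        elif self.cardinality is not None:
            raise SchemaError(f"continuous column {self.name!r} has a cardinality")


def continuous(name: str) -> Column:
    return Column(name, CONTINUOUS)


def categorical(name: str, cardinality: int, levels: Sequence[str] | None = None) -> Column:
    return Column(name, CATEGORICAL, cardinality, tuple(levels) if levels else None)


@dataclass(frozen=True)
class TabularSchema:
    """Ordered feature columns plus the name of the binary target.

    The target is *not* listed among the feature columns; site slices and
    latent datasets carry ``target=None`` because labels stay with the
    orchestrating caller.
    """

    columns: tuple[Column, ...]
    target: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "columns", tuple(self.columns))
        names = [c.name for c in self.columns]
        if len(set(names)) != len(names):
            raise SchemaError("duplicate feature column names")
        if self.target is not None and self.target in names:
            raise SchemaError(f"target {self.target!r} also listed as a feature")
        if not self.columns:
            raise SchemaError("schema needs at least one feature column")

    @property
    def feature_names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.columns)

    @property
    def continuous_names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.columns if c.kind == CONTINUOUS)

    @property
    def categorical_names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.columns if c.kind == CATEGORICAL)

    def column(self, name: str) -> Column:
        for c in self.columns:
            if c.name == name:
                return c
        raise SchemaError(f"no column named {name!r}")

    def cardinality(self, name: str) -> int:
        col = self.column(name)
        if col.kind != CATEGORICAL:
            raise SchemaError(f"{name!r} is not categorical")
        assert col.cardinality is not None
        return col.cardinality

    def subset(self, names: Iterable[str]) -> "TabularSchema":
        """Schema restricted to ``names`` (in the given order), target dropped."""
        return TabularSchema(tuple(self.column(n) for n in names), target=None)

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        cols = []
        for c in self.columns:
            d: dict = {"name": c.name, "kind": c.kind}
            if c.kind == CATEGORICAL:
                d["cardinality"] = c.cardinality
                if c.levels is not None:
                    d["levels"] = list(c.levels)
            cols.append(d)
        return {"columns": cols, "target": self.target}

    @classmethod
    def from_dict(cls, d: dict) -> "TabularSchema":
        cols = tuple(
            Column(
                c["name"],
                c["kind"],
                c.get("cardinality"),
                tuple(c["levels"]) if c.get("levels") else None,
            )
            for c in d["columns"]
        )
        return cls(cols, d.get("target"))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "TabularSchema":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass(frozen=True)
class VerticalPlan:
    """Assignment of feature columns to sites: one disjoint column list per site."""

    site_assignments: tuple[tuple[str, ...], ...]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "site_assignments", tuple(tuple(a) for a in self.site_assignments)
        )
        if not self.site_assignments:
            raise PlanError("plan has no sites")
        if any(len(a) == 0 for a in self.site_assignments):
            raise PlanError("plan contains an empty site")

    @property
    def n_sites(self) -> int:
        return len(self.site_assignments)

    @property
    def site_widths(self) -> tuple[int, ...]:
        return tuple(len(a) for a in self.site_assignments)

    def validate(self, schema: TabularSchema) -> None:
        """Raise PlanError unless the sites exactly tile the schema's features."""
        assigned = [n for a in self.site_assignments for n in a]
        if len(set(assigned)) != len(assigned):
            dupes = sorted({n for n in assigned if assigned.count(n) > 1})
            raise PlanError(f"columns assigned to more than one site: {dupes}")
        features = set(schema.feature_names)
        extra = sorted(set(assigned) - features)
        if extra:
            raise PlanError(f"plan references unknown columns: {extra}")
        missing = sorted(features - set(assigned))
        if missing:
            raise PlanError(f"plan omits feature columns: {missing}")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"sites": [list(a) for a in self.site_assignments]}, fh)

    @classmethod
    def from_yaml(cls, path) -> "VerticalPlan":
        with open(path) as fh:
            return cls(tuple(tuple(s) for s in yaml.safe_load(fh)["sites"]))

    @classmethod
    def from_widths(cls, schema: TabularSchema, widths: Sequence[int]) -> "VerticalPlan":
        """Contiguous plan: split the schema's column order into runs of ``widths``."""
        if sum(widths) != len(schema.columns):
            raise PlanError(
                f"widths sum to {sum(widths)} but schema has {len(schema.columns)} columns"
            )
        names = schema.feature_names
        out, start = [], 0
        for w in widths:
            out.append(names[start : start + w])
            start += w
        return cls(tuple(out))
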