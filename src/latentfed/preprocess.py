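"""Fitted per-column preprocessing shared by the autoencoder and classifier.

Continuous columns: median imputation then standardization, with statistics
computed on the fitting (training) rows only.  Categorical columns: integer
level codes, with missing cells mapped to a dedicated extra level (index =
declared cardinality), so the effective cardinality seen by embeddings and
reconstruction heads is cardinality + 1.
"""

from __future__ import annotations

import math

import numpy as np

from .dataset import TabularDataset
from .errors import ConfigurationError, EncodeError
from .schema import TabularSchema


def _default_width(cardinality: int) -> int:
    return min(50, math.ceil(cardinality / 2))


#: Registered embedding-width heuristics: name -> f(cardinality) -> width.
EMBEDDING_RULES = {"default": _default_width}


def embedding_widths(schema: TabularSchema, rule: str = "default") -> dict[str, int]:
    """Embedding width (>= 1) per categorical column under a registered rule."""
    try:
        fn = EMBEDDING_RULES[rule]
    except KeyError:
        raise ConfigurationError(
            f"unknown embedding rule {rule!r}; registered: {sorted(EMBEDDING_RULES)}"
        ) from None
    return {name: max(1, fn(schema.cardinality(name))) for name in schema.categorical_names}


def post_embedding_width(schema: TabularSchema, rule: str = "default") -> int:
    """Total model input width n: one unit per continuous column plus the
    embedding widths of all categorical columns."""
    return len(schema.continuous_names) + sum(embedding_widths(schema, rule).values())


class ColumnCodec:
    """Maps a dataset slice to model arrays and remembers the fitted statistics."""

    def __init__(self, schema: TabularSchema):
        self.schema = schema
        self.cont_names = schema.continuous_names
        self.cat_names = schema.categorical_names
        self.cardinalities = [schema.cardinality(n) for n in self.cat_names]
        # effective cardinality reserves one extra level for missing cells
        self.effective_cards = [c + 1 for c in self.cardinalities]
        self.medians: np.ndarray | None = None
        self.means: np.ndarray | None = None
        self.stds: np.ndarray | None = None

    @property
    def n_cont(self) -> int:
        return len(self.cont_names)

    @property
    def n_cat(self) -> int:
        return len(self.cat_names)

    def fit(self, ds: TabularDataset) -> "ColumnCodec":
        self._check(ds)
        if self.n_cont:
            x = ds.features[list(self.cont_names)].to_numpy()
            with np.errstate(all="ignore"):
                med = np.nanmedian(x, axis=0)
            med = np.where(np.isfinite(med), med, 0.0)
            imputed = np.where(np.isnan(x), med, x)
            mean = imputed.mean(axis=0)
            std = imputed.std(axis=0)
            std = np.where(std < 1e-12, 1.0, std)
            self.medians, self.means, self.stds = med, mean, std
        else:
            self.medians = self.means = np.empty(0)
            self.stds = np.empty(0)
        return self

    def transform(self, ds: TabularDataset) -> tuple[np.ndarray, np.ndarray]:
        """Return (standardized continuous block, integer code block)."""
        if self.medians is None:
            raise EncodeError("codec not fitted")
        self._check(ds)
        n = ds.n_rows
        if self.n_cont:
            x = ds.features[list(self.cont_names)].to_numpy()
            x = np.where(np.isnan(x), self.medians, x)
            x_cont = (x - self.means) / self.stds
        else:
            x_cont = np.empty((n, 0))
        if self.n_cat:
            c = ds.features[list(self.cat_names)].to_numpy()
            cards = np.asarray(self.cardinalities, dtype=float)
            bad = np.isnan(c) | (c < 0) | (c >= cards)
            codes = np.where(bad, cards, c).astype(np.int64)
        else:
            codes = np.empty((n, 0), dtype=np.int64)
        return x_cont, codes

    def _check(self, ds: TabularDataset) -> None:
        if ds.schema.feature_names != self.schema.feature_names or any(
            a.kind != b.kind or a.cardinality != b.cardinality
            for a, b in zip(ds.schema.columns, self.schema.columns)
        ):
            raise EncodeError(
                f"columns {ds.schema.feature_names} do not match the fitted "
                f"schema {self.schema.feature_names}"
            )
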