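"""Per-site overcomplete autoencoder over mixed tabular features.

Each data-holding site trains an autoencoder on its own vertical slice and
transmits only the code-layer activations.  The code layer is constrained to
be at least as wide as the post-embedding input (m >= n, overcompleteness),
which limits information loss while still moving the data into a different
feature space.  Training follows SGD with an initial learning rate of 0.01
decayed by 0.99 per epoch and a weight decay of 0.1; the decay discourages
the network from learning the identity map, which would defeat the
perturbation purpose of the transform.

Reconstruction loss for mixed types is the per-row sum of squared error on
standardized continuous columns plus softmax cross-entropy on each
categorical column's original levels, averaged over rows.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .dataset import SitePartition
from .errors import (
    ConfigurationError,
    DivergenceError,
    EncodeError,
    InputError,
    OvercompletenessError,
)
from .nn import MLP, Dense, EmbeddingSet, SGD, softmax_xent
from .preprocess import ColumnCodec, embedding_widths
from .schema import TabularSchema

__all__ = [
    "AutoencoderConfig",
    "AutoencoderModel",
    "LatentDataset",
    "build_embeddings",
    "train_autoencoder",
    "encode",
    "reconstruction_loss",
    "load_autoencoder",
]


def build_embeddings(site_schema: TabularSchema, rule: str = "default") -> dict[str, int]:
    """Embedding width per categorical column of a site's schema.

    Continuous columns pass through standardized at width 1; the total
    post-embedding input width n is ``n_continuous + sum(widths)``.
    """
    return embedding_widths(site_schema, rule)


@dataclass(frozen=True)
class AutoencoderConfig:
    """Architecture and training regime for one site's autoencoder.

    ``hidden_dims`` is an odd-length sequence of layer widths whose middle
    entry is the code layer (default 64-128-64, code_dim m = 128).
    """

    hidden_dims: tuple[int, ...] = (64, 128, 64)
    initial_lr: float = 0.01
    lr_decay: float = 0.99
    weight_decay: float = 0.1
    epochs: int = 50
    batch_size: int = 64
    embedding_rule: str = "default"

    def __post_init__(self) -> None:
        object.__setattr__(self, "hidden_dims", tuple(self.hidden_dims))
        if len(self.hidden_dims) % 2 != 1:
            raise ConfigurationError("hidden_dims needs an odd number of widths")
        if any(w <= 0 for w in self.hidden_dims):
            raise ConfigurationError("layer widths must be positive")
        if self.epochs < 1 or self.batch_size < 1:
            raise ConfigurationError("epochs and batch_size must be >= 1")

    @property
    def code_dim(self) -> int:
        return self.hidden_dims[len(self.hidden_dims) // 2]

    def learning_rate(self, epoch: int) -> float:
        """lr at 0-based epoch t: initial_lr * lr_decay ** t."""
        return self.initial_lr * self.lr_decay**epoch


@dataclass
class LatentDataset:
    """One site's transmitted code matrix, row-aligned with its partition."""

    site_index: int
    row_ids: np.ndarray
    codes: np.ndarray

    def __post_init__(self) -> None:
        self.row_ids = np.asarray(self.row_ids)
        self.codes = np.asarray(self.codes, dtype=np.float64)
        if len(self.row_ids) != self.codes.shape[0]:
            raise InputError("row_ids and code matrix disagree on row count")
        if not np.isfinite(self.codes).all():
            raise InputError("latent codes must be finite")

    @property
    def n_rows(self) -> int:
        return self.codes.shape[0]

    @property
    def code_dim(self) -> int:
        return self.codes.shape[1]

    def to_csv(self, path) -> None:
        cols = [f"code_{i:03d}" for i in range(self.code_dim)]
        frame = pd.DataFrame(self.codes, columns=cols)
        frame.insert(0, "row_id", self.row_ids)
        frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, site_index: int = 0) -> "LatentDataset":
        frame = pd.read_csv(path)
        if "row_id" not in frame.columns:
            raise InputError(f"{path}: latent CSV needs a row_id column")
        ids = frame["row_id"].to_numpy()
        codes = frame.drop(columns="row_id").to_numpy(dtype=np.float64)
        return cls(site_index, ids, codes)


class AutoencoderModel:
    """A trained encoder/decoder pair for one site's slice.

    Holds the fitted column codec (imputation + standardization statistics),
    the embedding tables, the encoder whose post-ReLU middle-layer output is
    the transmitted code, the decoder trunk with per-column reconstruction
    heads, and the training history.
    """

    def __init__(
        self,
        config: AutoencoderConfig,
        codec: ColumnCodec,
        site_index: int,
        rng: np.random.Generator,
    ):
        self.config = config
        self.codec = codec
        self.site_index = site_index
        widths_map = embedding_widths(codec.schema, config.embedding_rule)
        self.embed_widths = [widths_map[n] for n in codec.cat_names]
        self.input_width = codec.n_cont + sum(self.embed_widths)
        if config.code_dim < self.input_width:
            raise OvercompletenessError(
                f"code_dim {config.code_dim} < post-embedding input width "
                f"{self.input_width}: the code layer must not be narrower "
                "than the input"
            )
        mid = len(config.hidden_dims) // 2
        self.embed = EmbeddingSet(rng, codec.effective_cards, self.embed_widths)
        self.encoder = MLP(
            rng, [self.input_width, *config.hidden_dims[: mid + 1]], relu_last=True
        )
        trunk_dims = [config.code_dim, *config.hidden_dims[mid + 1 :]]
        self.trunk = MLP(rng, trunk_dims, relu_last=True) if len(trunk_dims) > 1 else None
        trunk_out = trunk_dims[-1]
        self.cont_head = Dense(rng, trunk_out, codec.n_cont) if codec.n_cont else None
        self.cat_heads = [Dense(rng, trunk_out, c) for c in codec.effective_cards]
        self.loss_history: list[float] = []
        self.lr_history: list[float] = []

    @property
    def code_dim(self) -> int:
        return self.config.code_dim

    @property
    def params(self):
        out = list(self.embed.params) + list(self.encoder.params)
        if self.trunk is not None:
            out += self.trunk.params
        if self.cont_head is not None:
            out += self.cont_head.params
        for h in self.cat_heads:
            out += h.params
        return out

    # -- forward passes --------------------------------------------------
    def _input(self, x_cont: np.ndarray, codes: np.ndarray) -> np.ndarray:
        return np.concatenate([x_cont, self.embed.forward(codes)], axis=1)

    def _encode_arrays(self, x_cont: np.ndarray, codes: np.ndarray) -> np.ndarray:
        return self.encoder.forward(self._input(x_cont, codes))

    def _batch_loss(
        self, x_cont: np.ndarray, codes: np.ndarray, backprop: bool
    ) -> float:
        n = x_cont.shape[0]
        h = self._encode_arrays(x_cont, codes)
        d = self.trunk.forward(h) if self.trunk is not None else h
        loss = 0.0
        grad_d = np.zeros_like(d) if backprop else None
        if self.cont_head is not None:
            pred = self.cont_head.forward(d)
            diff = pred - x_cont
            loss += float((diff**2).sum() / n)
            if backprop:
                grad_d += self.cont_head.backward(2.0 * diff / n)
        for j, head in enumerate(self.cat_heads):
            logits = head.forward(d)
            l_j, g_j = softmax_xent(logits, codes[:, j])
            loss += l_j
            if backprop:
                grad_d += head.backward(g_j)
        if backprop:
            g_h = self.trunk.backward(grad_d) if self.trunk is not None else grad_d
            g_inp = self.encoder.backward(g_h)
            if self.embed.tables:
                self.embed.backward(g_inp[:, self.codec.n_cont :])
        return loss

    # -- persistence -----------------------------------------------------
    def save(self, path) -> None:
        """Single-archive save (NumPy .npz with a JSON metadata entry)."""
        arrays: dict[str, np.ndarray] = {}
        for i, p in enumerate(self.params):
            arrays[f"param_{i:04d}"] = p.value
        arrays["medians"] = self.codec.medians
        arrays["means"] = self.codec.means
        arrays["stds"] = self.codec.stds
        arrays["loss_history"] = np.asarray(self.loss_history)
        arrays["lr_history"] = np.asarray(self.lr_history)
        meta = {
            "config": {
                "hidden_dims": list(self.config.hidden_dims),
                "initial_lr": self.config.initial_lr,
                "lr_decay": self.config.lr_decay,
                "weight_decay": self.config.weight_decay,
                "epochs": self.config.epochs,
                "batch_size": self.config.batch_size,
                "embedding_rule": self.config.embedding_rule,
            },
            "schema": self.codec.schema.to_dict(),
            "site_index": self.site_index,
        }
        arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
        with open(path, "wb") as fh:
            np.savez(fh, **arrays)


def load_autoencoder(path) -> AutoencoderModel:
    with np.load(path) as arc:
        meta = json.loads(bytes(arc["meta"]).decode())
        config = AutoencoderConfig(**{**meta["config"], "hidden_dims": tuple(meta["config"]["hidden_dims"])})
        schema = TabularSchema.from_dict(meta["schema"])
        codec = ColumnCodec(schema)
        codec.medians = arc["medians"]
        codec.means = arc["means"]
        codec.stds = arc["stds"]
        model = AutoencoderModel(
            config, codec, int(meta["site_index"]), np.random.default_rng(0)
        )
        for i, p in enumerate(model.params):
            p.value[...] = arc[f"param_{i:04d}"]
        model.loss_history = [float(v) for v in arc["loss_history"]]
        model.lr_history = [float(v) for v in arc["lr_history"]]
    return model


# ---------------------------------------------------------------------------
# Operations


def train_autoencoder(
    partition: SitePartition,
    config: AutoencoderConfig = AutoencoderConfig(),
    seed: int = 0,
) -> AutoencoderModel:
    """Train one site's autoencoder by mini-batch SGD.

    Deterministic given (partition, config, seed): the seed drives both the
    weight initialization and the per-epoch shuffles.  Raises
    :class:`OvercompletenessError` when the configured code layer is narrower
    than the site's post-embedding input, and :class:`DivergenceError`
    (naming the epoch) if the loss ever turns non-finite.
    """
    ds = partition.dataset
    if ds.n_rows == 0:
        raise InputError("cannot train on an empty partition")
    rng = np.random.default_rng(seed)
    codec = ColumnCodec(ds.schema).fit(ds)
    model = AutoencoderModel(config, codec, partition.site_index, rng)
    x_cont, codes = codec.transform(ds)
    n = ds.n_rows
    opt = SGD(model.params, lr=config.initial_lr, weight_decay=config.weight_decay)
    for epoch in range(config.epochs):
        opt.lr = config.learning_rate(epoch)
        model.lr_history.append(opt.lr)
        perm = rng.permutation(n)
        total = 0.0
        for start in range(0, n, config.batch_size):
            idx = perm[start : start + config.batch_size]
            loss = model._batch_loss(x_cont[idx], codes[idx], backprop=True)
            opt.step()
            total += loss * len(idx)
        epoch_loss = total / n
        if not np.isfinite(epoch_loss):
            raise DivergenceError(epoch)
        model.loss_history.append(epoch_loss)
    return model


def encode(model: AutoencoderModel, partition: SitePartition) -> LatentDataset:
    """Transform a partition into its latent representation.

    A pure function of (model, row values): row order is preserved, repeat
    calls and duplicate rows produce identical codes.
    """
    ds = partition.dataset
    x_cont, codes = model.codec.transform(ds)  # raises EncodeError on mismatch
    z = model._encode_arrays(x_cont, codes)
    return LatentDataset(partition.site_index, ds.row_ids, z)


def reconstruction_loss(model: AutoencoderModel, partition: SitePartition) -> float:
    """Mean per-row reconstruction loss of the model on a partition:
    squared error on standardized continuous columns plus categorical
    cross-entropy, exactly the quantity training minimizes (before weight
    decay)."""
    x_cont, codes = model.codec.transform(partition.dataset)
    return float(model._batch_loss(x_cont, codes, backprop=False))
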