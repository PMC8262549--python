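"""Central tabular neural-network classifier and its evaluation metrics.

The same classifier serves every arm of the benchmark: trained on original
mixed-type features (with categorical embeddings) for the baselines, or on
all-continuous latent features (embeddings bypassed) for the federated arm.
Evaluation is by accuracy at a fixed decision threshold and AUROC in its
rank (Mann-Whitney) formulation: the probability a random positive is
scored above a random negative, ties counted half.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .dataset import TabularDataset
from .errors import DegenerateLabelsError, EncodeError, InputError
from .federation import AggregatedLatent
from .nn import MLP, Adam, Dense, EmbeddingSet, bce_with_logits, sigmoid
from .preprocess import ColumnCodec, embedding_widths

__all__ = [
    "ClassifierConfig",
    "TabularClassifier",
    "EvalResult",
    "train_classifier",
    "accuracy",
    "auroc",
    "evaluate",
]


@dataclass(frozen=True)
class ClassifierConfig:
    """Hyperparameters of the central tabular network.

    Two rectified-linear hidden layers and an adaptive-moment optimizer;
    held fixed across all benchmark arms so that before/after comparisons
    differ only in their inputs.
    """

    hidden_dims: tuple[int, ...] = (200, 100)
    lr: float = 1e-3
    epochs: int = 20
    batch_size: int = 64
    threshold: float = 0.5
    embedding_rule: str = "default"

    def __post_init__(self) -> None:
        object.__setattr__(self, "hidden_dims", tuple(self.hidden_dims))
        if any(w <= 0 for w in self.hidden_dims):
            raise InputError("layer widths must be positive")
        if not 0.0 < self.threshold < 1.0:
            raise InputError("threshold must be in (0, 1)")


@dataclass
class EvalResult:
    """Held-out metrics for one benchmark arm, scores retained for audit."""

    accuracy: float
    auroc: float
    n_eval: int
    scores: np.ndarray

    def __post_init__(self) -> None:
        if not (0.0 <= self.accuracy <= 1.0 and 0.0 <= self.auroc <= 1.0):
            raise InputError("metrics must lie in [0, 1]")
        if self.n_eval <= 0:
            raise InputError("n_eval must be positive")


def _as_arrays(features, codec: ColumnCodec | None):
    """Normalize any accepted feature container to (x_cont, codes)."""
    if isinstance(features, TabularDataset):
        if codec is None:
            raise EncodeError("codec required for tabular features")
        return codec.transform(features)
    if isinstance(features, AggregatedLatent):
        x = features.matrix
    else:
        x = np.asarray(features, dtype=np.float64)
    return x, np.empty((x.shape[0], 0), dtype=np.int64)


class TabularClassifier:
    """A fitted binary classifier emitting positive-class probabilities."""

    def __init__(self, config: ClassifierConfig):
        self.config = config
        self.codec: ColumnCodec | None = None
        self._standardize: tuple[np.ndarray, np.ndarray] | None = None
        self.embed: EmbeddingSet | None = None
        self.net: MLP | None = None
        self.head: Dense | None = None
        self.loss_history: list[float] = []

    # -- training --------------------------------------------------------
    def fit(self, features, labels: np.ndarray, seed: int = 0) -> "TabularClassifier":
        y = np.asarray(labels, dtype=np.float64)
        if isinstance(features, TabularDataset):
            n_rows = features.n_rows
        elif isinstance(features, AggregatedLatent):
            n_rows = features.n_rows
        else:
            n_rows = np.asarray(features).shape[0]
        if len(y) != n_rows:
            raise InputError("labels not aligned to feature rows")
        classes = np.unique(y)
        if len(classes) < 2:
            raise DegenerateLabelsError(
                f"training needs both classes, got only {classes.tolist()}"
            )
        rng = np.random.default_rng(seed)
        if isinstance(features, TabularDataset):
            self.codec = ColumnCodec(features.schema).fit(features)
            x_cont, codes = self.codec.transform(features)
            cards = self.codec.effective_cards
            widths_map = embedding_widths(features.schema, self.config.embedding_rule)
            widths = [widths_map[n] for n in self.codec.cat_names]
        else:
            x_raw, codes = _as_arrays(features, None)
            mean = x_raw.mean(axis=0)
            std = x_raw.std(axis=0)
            std = np.where(std < 1e-12, 1.0, std)
            self._standardize = (mean, std)
            x_cont = (x_raw - mean) / std
            cards, widths = [], []
        self.embed = EmbeddingSet(rng, cards, widths)
        n_in = x_cont.shape[1] + self.embed.out_width
        self.net = MLP(rng, [n_in, *self.config.hidden_dims], relu_last=True)
        self.head = Dense(rng, self.config.hidden_dims[-1], 1)
        params = self.embed.params + self.net.params + self.head.params
        opt = Adam(params, lr=self.config.lr)
        n = x_cont.shape[0]
        for _ in range(self.config.epochs):
            perm = rng.permutation(n)
            total = 0.0
            for start in range(0, n, self.config.batch_size):
                idx = perm[start : start + self.config.batch_size]
                xb = np.concatenate([x_cont[idx], self.embed.forward(codes[idx])], axis=1)
                z = self.head.forward(self.net.forward(xb))[:, 0]
                loss, gz = bce_with_logits(z, y[idx])
                g_in = self.net.backward(self.head.backward(gz[:, None]))
                if self.embed.tables:
                    self.embed.backward(g_in[:, x_cont.shape[1] :])
                opt.step()
                total += loss * len(idx)
            self.loss_history.append(total / n)
        return self

    # -- inference -------------------------------------------------------
    def predict_proba(self, features) -> np.ndarray:
        assert self.net is not None and self.head is not None and self.embed is not None
        if isinstance(features, TabularDataset):
            x_cont, codes = _as_arrays(features, self.codec)
        else:
            x_raw, codes = _as_arrays(features, None)
            if self._standardize is None:
                raise EncodeError("model was trained on tabular, not matrix, input")
            mean, std = self._standardize
            if x_raw.shape[1] != len(mean):
                raise EncodeError(
                    f"expected {len(mean)} feature columns, got {x_raw.shape[1]}"
                )
            x_cont = (x_raw - mean) / std
        xb = np.concatenate([x_cont, self.embed.forward(codes)], axis=1)
        return sigmoid(self.head.forward(self.net.forward(xb))[:, 0])

    def predict(self, features) -> np.ndarray:
        return (self.predict_proba(features) >= self.config.threshold).astype(np.int64)


def train_classifier(
    features,
    labels: np.ndarray,
    config: ClassifierConfig = ClassifierConfig(),
    seed: int = 0,
) -> TabularClassifier:
    """Train the central tabular network on any accepted feature container.

    ``features`` may be a :class:`TabularDataset` (mixed types, embeddings
    used), an :class:`AggregatedLatent`, or a plain matrix (all continuous,
    embeddings bypassed).  Deterministic given seed.
    """
    return TabularClassifier(config).fit(features, labels, seed=seed)


# ---------------------------------------------------------------------------
# Metrics


def accuracy(scores, labels, threshold: float = 0.5) -> float:
    """Fraction of rows whose thresholded score equals the label.

    A score exactly at the threshold counts as a positive call (>=).
    """
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels)
    if s.shape != y.shape:
        raise InputError(f"scores {s.shape} and labels {y.shape} differ in length")
    if s.size == 0:
        raise InputError("empty inputs")
    return float(((s >= threshold).astype(np.int64) == y.astype(np.int64)).mean())


def auroc(scores, labels) -> float:
    """AUROC by midranks: P(score_pos > score_neg) + 0.5 * P(tie)."""
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels).astype(np.int64)
    if s.shape != y.shape:
        raise InputError(f"scores {s.shape} and labels {y.shape} differ in length")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise DegenerateLabelsError("AUROC undefined with a single class")
    ranks = rankdata(s)
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def evaluate(
    model: TabularClassifier, features, labels, threshold: float | None = None
) -> EvalResult:
    """Score a fitted classifier on held-out rows."""
    y = np.asarray(labels).astype(np.int64)
    scores = model.predict_proba(features)
    thr = model.config.threshold if threshold is None else threshold
    return EvalResult(
        accuracy=accuracy(scores, y, thr),
        auroc=auroc(scores, y),
        n_eval=len(y),
        scores=scores,
    )
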