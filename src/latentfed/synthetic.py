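"""Synthetic mixed-type tabular data with a known, tunable label signal.

The generator stands in for the clinical and census tables a federated
study would use but cannot ship: balanced binary labels, continuous
features drawn from class-shifted Gaussians and categoricals from
class-conditional multinomials.  This family is chosen because its Bayes
rate has a closed form on the continuous part, giving tests an analytic
performance ceiling.  Presets reproduce the three study shapes: a census
income table (23,374 x 14, 3 sites), a small surgical-outcome table
(50 x 15, 3 sites) and an ICU mortality extract (15,762 x 32, 7 sites).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Union

import numpy as np
import pandas as pd
from scipy.stats import norm

from .dataset import TabularDataset
from .errors import InputError
from .schema import Column, TabularSchema, VerticalPlan, categorical, continuous

__all__ = [
    "ContinuousSpec",
    "CategoricalSpec",
    "SyntheticSpec",
    "generate",
    "signal_allocation",
    "preset",
    "preset_plan",
    "gaussian_bayes_accuracy",
    "PRESETS",
]


@dataclass(frozen=True)
class ContinuousSpec:
    """A Gaussian feature: class-1 mean is +shift/2, class-0 mean -shift/2."""

    name: str
    shift: float = 0.0


@dataclass(frozen=True)
class CategoricalSpec:
    """A multinomial feature whose level probabilities tilt with the class.

    Levels l = 0..card-1 get scores u_l spread over [-1, 1];
    p(l | y) is proportional to exp((y - 1/2) * skew * u_l), so skew = 0 means
    no signal and larger skew moves probability mass apart between classes.
    """

    name: str
    cardinality: int
    skew: float = 0.0

    def class_probs(self) -> np.ndarray:
        u = np.linspace(-1.0, 1.0, self.cardinality)
        p = np.exp(np.outer([-0.5, 0.5], self.skew * u))
        return p / p.sum(axis=1, keepdims=True)


ColumnSpec = Union[ContinuousSpec, CategoricalSpec]


@dataclass(frozen=True)
class SyntheticSpec:
    """Full description of one synthetic dataset draw."""

    n_rows: int
    columns: tuple[ColumnSpec, ...]
    label_balance: float = 0.5
    noise_scale: float = 1.0
    missing_rate: float = 0.0
    seed: int = 0
    target: str = "y"

    def __post_init__(self) -> None:
        object.__setattr__(self, "columns", tuple(self.columns))
        if self.n_rows < 1 or not self.columns:
            raise InputError("need positive n_rows and at least one column")
        if not 0.0 < self.label_balance < 1.0:
            raise InputError("label_balance must be in (0, 1)")
        if self.noise_scale <= 0:
            raise InputError("noise_scale must be positive")
        if not 0.0 <= self.missing_rate < 1.0:
            raise InputError("missing_rate must be in [0, 1)")

    def schema(self) -> TabularSchema:
        cols: list[Column] = []
        for c in self.columns:
            if isinstance(c, ContinuousSpec):
                cols.append(continuous(c.name))
            else:
                cols.append(categorical(c.name, c.cardinality))
        return TabularSchema(tuple(cols), target=self.target)


def generate(spec: SyntheticSpec) -> TabularDataset:
    """Draw a dataset from the spec; bit-deterministic given spec.seed.

    Labels are assigned by a seeded permutation with class counts differing
    by at most one from the requested balance.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_rows
    n_pos = int(round(n * spec.label_balance))
    y = np.zeros(n, dtype=np.int64)
    y[rng.permutation(n)[:n_pos]] = 1
    data: dict[str, np.ndarray] = {}
    for c in spec.columns:
        if isinstance(c, ContinuousSpec):
            mean = np.where(y == 1, c.shift / 2.0, -c.shift / 2.0)
            x = rng.normal(mean, spec.noise_scale)
            if spec.missing_rate > 0:
                x = np.where(rng.random(n) < spec.missing_rate, np.nan, x)
            data[c.name] = x
        else:
            probs = c.class_probs()
            cum = probs.cumsum(axis=1)[y]  # (n, card)
            draws = rng.random(n)[:, None]
            data[c.name] = (draws > cum).sum(axis=1).astype(np.float64)
    schema = spec.schema()
    frame = pd.DataFrame(data, columns=list(schema.feature_names))
    frame.index = pd.RangeIndex(n)
    labels = pd.Series(y.astype(np.float64), index=frame.index)
    return TabularDataset(schema, frame, labels)


def signal_allocation(
    spec: SyntheticSpec, plan: VerticalPlan, weights
) -> SyntheticSpec:
    """Rescale per-column effect sizes so site i carries ``weights[i]`` of the
    total discriminative signal (measured as the sum of squared shifts and
    skews).  A zero-weight site's columns become pure noise.
    """
    w = np.asarray(weights, dtype=np.float64)
    if len(w) != plan.n_sites:
        raise InputError(f"{len(w)} weights for {plan.n_sites} sites")
    if (w < 0).any():
        raise InputError("weights must be nonnegative")
    if not np.isclose(w.sum(), 1.0):
        raise InputError("weights must sum to 1")
    plan.validate(spec.schema())
    by_name = {c.name: c for c in spec.columns}
    strength = {
        c.name: (c.shift if isinstance(c, ContinuousSpec) else c.skew)
        for c in spec.columns
    }
    site_of = {
        name: i for i, cols in enumerate(plan.site_assignments) for name in cols
    }
    per_site = np.zeros(plan.n_sites)
    for name, s in strength.items():
        per_site[site_of[name]] += s * s
    total = per_site.sum()
    if total <= 0:
        raise InputError("spec carries no signal to reallocate")
    scales = np.zeros(plan.n_sites)
    for i in range(plan.n_sites):
        if w[i] == 0:
            scales[i] = 0.0
        elif per_site[i] <= 0:
            raise InputError(
                f"site {i} has weight {w[i]} but its columns carry no signal"
            )
        else:
            scales[i] = np.sqrt(w[i] * total / per_site[i])
    new_cols: list[ColumnSpec] = []
    for c in spec.columns:
        s = scales[site_of[c.name]]
        if isinstance(c, ContinuousSpec):
            new_cols.append(replace(c, shift=c.shift * s))
        else:
            new_cols.append(replace(c, skew=c.skew * s))
    return replace(spec, columns=tuple(new_cols))


def gaussian_bayes_accuracy(spec: SyntheticSpec) -> float:
    """Closed-form Bayes accuracy of the continuous part of a spec.

    With independent Gaussians shifted by delta_k between classes at common
    sd sigma, the optimal rule projects on the mean difference and achieves
    accuracy Phi(sqrt(sum delta_k^2) / (2 sigma)).  Categorical signal, if
    any, is ignored, so this is a lower bound for mixed specs.
    """
    shifts = np.array(
        [c.shift for c in spec.columns if isinstance(c, ContinuousSpec)]
    )
    return float(norm.cdf(np.sqrt((shifts**2).sum()) / (2.0 * spec.noise_scale)))


# ---------------------------------------------------------------------------
# Presets mirroring the three study shapes


def _adult_like(n_rows: int, seed: int) -> SyntheticSpec:
    # 6 continuous + 8 categorical, interleaved like a census income table
    cols: tuple[ColumnSpec, ...] = (
        ContinuousSpec("age", 0.7),
        CategoricalSpec("workclass", 9, 0.5),
        ContinuousSpec("fnlwgt", 0.1),
        CategoricalSpec("education", 16, 0.7),
        ContinuousSpec("education_num", 0.8),
        CategoricalSpec("marital_status", 7, 0.6),
        CategoricalSpec("occupation", 15, 0.5),
        CategoricalSpec("relationship", 6, 0.4),
        CategoricalSpec("race", 5, 0.2),
        CategoricalSpec("sex", 2, 0.5),
        ContinuousSpec("capital_gain", 0.6),
        ContinuousSpec("capital_loss", 0.3),
        ContinuousSpec("hours_per_week", 0.5),
        CategoricalSpec("native_country", 42, 0.2),
    )
    return SyntheticSpec(n_rows, cols, seed=seed, target="income")


def _schwannoma_like(n_rows: int, seed: int) -> SyntheticSpec:
    # 1 categorical + 14 continuous, tiny surgical cohort
    cols: list[ColumnSpec] = [CategoricalSpec("tumor_side", 2, 0.4)]
    shifts = [0.9, 0.7, 0.6, 0.6, 0.5, 0.5, 0.4, 0.4, 0.3, 0.3, 0.2, 0.2, 0.1, 0.1]
    cols += [ContinuousSpec(f"clinical_{i:02d}", s) for i, s in enumerate(shifts)]
    return SyntheticSpec(n_rows, tuple(cols), seed=seed, target="hearing_loss")


def _eicu_like(n_rows: int, seed: int) -> SyntheticSpec:
    # 32 mixed features (24 continuous labs/vitals with missingness,
    # 8 categoricals), echoing an ICU severity-score variable set
    rng = np.random.default_rng(202_406)  # fixed design, not a data seed
    cols: list[ColumnSpec] = []
    cat_slots = {2, 6, 11, 15, 19, 23, 27, 30}
    cards = [4, 2, 6, 3, 2, 5, 3, 8]
    ci = 0
    for i in range(32):
        if i in cat_slots:
            cols.append(CategoricalSpec(f"apache_cat_{i:02d}", cards[ci], 0.4))
            ci += 1
        else:
            cols.append(
                ContinuousSpec(f"apache_var_{i:02d}", float(rng.uniform(0.1, 0.7)))
            )
    return SyntheticSpec(
        n_rows, tuple(cols), missing_rate=0.2, seed=seed, target="expired"
    )


PRESETS = {
    "adult_like": (_adult_like, 23_374, (5, 5, 4)),
    "schwannoma_like": (_schwannoma_like, 50, (7, 3, 5)),
    "eicu_like": (_eicu_like, 15_762, (3, 4, 9, 3, 3, 4, 6)),
}


def preset(name: str, n_rows: int | None = None, seed: int = 0) -> SyntheticSpec:
    """A named study-shaped spec; ``n_rows`` may be overridden for smaller runs."""
    try:
        build, default_rows, _ = PRESETS[name]
    except KeyError:
        raise InputError(f"unknown preset {name!r}; available: {sorted(PRESETS)}") from None
    return build(default_rows if n_rows is None else n_rows, seed)


def preset_plan(name: str) -> VerticalPlan:
    """The site plan that goes with a preset (contiguous column runs)."""
    build, default_rows, widths = PRESETS[name]
    schema = build(default_rows, 0).schema()
    return VerticalPlan.from_widths(schema, widths)
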