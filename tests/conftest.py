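"""Shared fixtures: all data is generated programmatically at test time."""

import numpy as np
import pandas as pd
import pytest

from latentfed.dataset import TabularDataset
from latentfed.schema import TabularSchema, VerticalPlan, categorical, continuous
from latentfed.synthetic import ContinuousSpec, SyntheticSpec, generate


@pytest.fixture
def mixed_schema() -> TabularSchema:
    """Two continuous + two categorical features and a binary target."""
    return TabularSchema(
        (
            continuous("age"),
            categorical("job", 4),
            continuous("score"),
            categorical("region", 3),
        ),
        target="y",
    )


@pytest.fixture
def mixed_dataset(mixed_schema) -> TabularDataset:
    rng = np.random.default_rng(42)
    n = 40
    y = np.repeat([0, 1], n // 2).astype(float)
    frame = pd.DataFrame(
        {
            "age": rng.normal(y, 1.0),
            "job": rng.integers(0, 4, n).astype(float),
            "score": rng.normal(-y, 1.0),
            "region": rng.integers(0, 3, n).astype(float),
        },
        index=pd.RangeIndex(n),
    )
    return TabularDataset(mixed_schema, frame, pd.Series(y, index=frame.index))


@pytest.fixture
def mixed_plan() -> VerticalPlan:
    return VerticalPlan((("age", "job"), ("score", "region")))


@pytest.fixture
def cont_site():
    """A 5-feature all-continuous single-site partition, 200 rows."""
    from latentfed.dataset import vertical_split

    spec = SyntheticSpec(
        200, tuple(ContinuousSpec(f"f{i}", 0.5) for i in range(5)), seed=7
    )
    ds = generate(spec)
    plan = VerticalPlan((tuple(f"f{i}" for i in range(5)),))
    return vertical_split(ds, plan)[0]
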