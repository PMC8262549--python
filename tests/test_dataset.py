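import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, given, settings
from hypothesis import strategies as st

from latentfed.dataset import (
    TabularDataset,
    balance_by_undersampling,
    filter_rows,
    read_table,
    split_train_test,
    vertical_split,
    write_table,
)
from latentfed.errors import (
    DegenerateLabelsError,
    FormatError,
    SchemaError,
    StratificationError,
)
from latentfed.schema import TabularSchema, VerticalPlan, categorical, continuous


def _write(tmp_path, text, name="data.csv"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadTable:
    SCHEMA = TabularSchema(
        (continuous("age"), categorical("job", 3, levels=["a", "b", "c"])),
        target="y",
    )

    def test_basic_read(self, tmp_path):
        p = _write(tmp_path, "age,job,y\n30,a,0\n40,b,1\n50,c,1\n")
        ds = read_table(p, self.SCHEMA)
        assert ds.n_rows == 3 and ds.n_features == 2
        assert list(ds.row_ids) == [0, 1, 2]
        assert ds.features["job"].tolist() == [0.0, 1.0, 2.0]
        assert ds.label_array().tolist() == [0, 1, 1]

    def test_missing_target_column_is_schema_error(self, tmp_path):
        p = _write(tmp_path, "age,job\n30,a\n")
        with pytest.raises(SchemaError, match="lacks"):
            read_table(p, self.SCHEMA)

    def test_empty_continuous_cell_becomes_missing(self, tmp_path):
        p = _write(tmp_path, "age,job,y\n,a,0\nnope,b,1\n12,c,1\n")
        ds = read_table(p, self.SCHEMA)
        assert np.isnan(ds.features["age"].iloc[0])
        assert np.isnan(ds.features["age"].iloc[1])  # unparseable too
        assert ds.features["age"].iloc[2] == 12.0

    def test_duplicate_header_is_format_error(self, tmp_path):
        p = _write(tmp_path, "age,age,job,y\n1,2,a,0\n")
        with pytest.raises(FormatError, match="duplicate"):
            read_table(p, self.SCHEMA)

    def test_write_read_round_trip(self, mixed_dataset, tmp_path):
        p = tmp_path / "rt.csv"
        write_table(mixed_dataset, p)
        back = read_table(p, mixed_dataset.schema)
        pd.testing.assert_frame_equal(
            back.features, mixed_dataset.features, check_exact=False
        )
        assert back.label_array().tolist() == mixed_dataset.label_array().tolist()


def _labeled(n0, n1, seed=0):
    n = n0 + n1
    y = np.concatenate([np.zeros(n0), np.ones(n1)])
    rng = np.random.default_rng(seed)
    y = y[rng.permutation(n)]
    frame = pd.DataFrame({"x": np.arange(n, dtype=float)}, index=pd.RangeIndex(n))
    schema = TabularSchema((continuous("x"),), target="y")
    return TabularDataset(schema, frame, pd.Series(y, index=frame.index))


class TestBalanceByUndersampling:
    def test_already_balanced_is_identity(self):
        ds = _labeled(10, 10)
        out = balance_by_undersampling(ds, seed=0)
        assert out.row_ids.tolist() == ds.row_ids.tolist()

    @given(n0=st.integers(2, 40), n1=st.integers(2, 40), seed=st.integers(0, 5))
    @settings(max_examples=25, deadline=None)
    def test_equal_classes_and_minority_retained(self, n0, n1, seed):
        ds = _labeled(n0, n1)
        out = balance_by_undersampling(ds, seed=seed)
        counts = out.class_counts()
        m = min(n0, n1)
        assert counts == {0: m, 1: m}
        minority = 0 if n0 <= n1 else 1
        wanted = set(ds.row_ids[ds.label_array() == minority].tolist())
        assert wanted <= set(out.row_ids.tolist())
        # relative row order preserved
        assert out.row_ids.tolist() == sorted(out.row_ids.tolist())

    def test_one_class_empty_is_error(self):
        ds = _labeled(5, 5)
        only = ds.select_rows(ds.row_ids[ds.label_array() == 1])
        with pytest.raises(DegenerateLabelsError):
            balance_by_undersampling(only, seed=0)

    def test_deterministic_given_seed(self):
        ds = _labeled(30, 7)
        a = balance_by_undersampling(ds, seed=3)
        b = balance_by_undersampling(ds, seed=3)
        assert a.row_ids.tolist() == b.row_ids.tolist()


class TestFilterRows:
    def _with_missing(self):
        schema = TabularSchema(
            tuple(continuous(f"f{i}") for i in range(4)), target="y"
        )
        x = np.arange(24, dtype=float).reshape(6, 4)
        x[0, :] = np.nan            # 0 nonnull
        x[1, :2] = np.nan           # 2 nonnull (boundary for min_nonnull=2)
        y = pd.Series([0, 1, 1, np.nan, 0, np.nan], index=pd.RangeIndex(6))
        frame = pd.DataFrame(x, columns=[f"f{i}" for i in range(4)])
        return TabularDataset(schema, frame, y)

    def test_boundary_row_dropped_strictly(self):
        ds = self._with_missing()
        out, counts = filter_rows(ds, min_nonnull=2, require_label=False)
        # rows 0 (0 nonnull) and 1 (exactly 2 nonnull) fail "more than 2"
        assert counts.dropped_nonnull == 2
        assert out.n_rows == 4

    def test_label_rule_applied_after_nonnull_rule(self):
        ds = self._with_missing()
        out, counts = filter_rows(ds, min_nonnull=2, require_label=True)
        assert counts.dropped_nonnull == 2
        assert counts.dropped_unlabeled == 2
        assert ds.n_rows - out.n_rows == counts.dropped_nonnull + counts.dropped_unlabeled

    def test_complete_labeled_data_unchanged(self, mixed_dataset):
        out, counts = filter_rows(mixed_dataset, min_nonnull=0, require_label=True)
        assert out.n_rows == mixed_dataset.n_rows
        assert counts.dropped_nonnull == 0 and counts.dropped_unlabeled == 0


class TestSplitTrainTest:
    def test_exact_stratified_counts(self):
        ds = _labeled(50, 50)
        tr, te = split_train_test(ds, 0.2, seed=0)
        assert tr.n_rows == 80 and te.n_rows == 20
        assert te.class_counts() == {0: 10, 1: 10}
        # exact partition
        assert set(tr.row_ids) | set(te.row_ids) == set(ds.row_ids)
        assert set(tr.row_ids) & set(te.row_ids) == set()

    def test_same_seed_same_split(self):
        ds = _labeled(30, 30)
        a = split_train_test(ds, 0.25, seed=5)
        b = split_train_test(ds, 0.25, seed=5)
        assert a[1].row_ids.tolist() == b[1].row_ids.tolist()

    def test_four_rows_half(self):
        ds = _labeled(2, 2)
        tr, te = split_train_test(ds, 0.5, seed=1)
        assert tr.class_counts() == {0: 1, 1: 1}
        assert te.class_counts() == {0: 1, 1: 1}

    def test_tiny_class_is_stratification_error(self):
        ds = _labeled(5, 1)
        with pytest.raises(StratificationError):
            split_train_test(ds, 0.5, seed=0)


class TestVerticalSplit:
    def test_partitions_match_plan_and_drop_labels(self, mixed_dataset, mixed_plan):
        parts = vertical_split(mixed_dataset, mixed_plan)
        assert [p.dataset.schema.feature_names for p in parts] == [
            ("age", "job"),
            ("score", "region"),
        ]
        assert all(not p.dataset.has_labels for p in parts)
        for p in parts:
            assert p.dataset.row_ids.tolist() == mixed_dataset.row_ids.tolist()

    def test_round_trip_identity(self, mixed_dataset, mixed_plan):
        """Reassembling all partitions column-wise reproduces the grid exactly."""
        parts = vertical_split(mixed_dataset, mixed_plan)
        rebuilt = pd.concat([p.dataset.features for p in parts], axis=1)
        rebuilt = rebuilt[list(mixed_dataset.schema.feature_names)]
        pd.testing.assert_frame_equal(rebuilt, mixed_dataset.features)

    @given(seed=st.integers(0, 100))
    @settings(
        max_examples=20,
        deadline=None,
        suppress_health_check=[HealthCheck.function_scoped_fixture],
    )
    def test_round_trip_identity_random_plans(self, mixed_dataset, seed):
        rng = np.random.default_rng(seed)
        names = list(mixed_dataset.schema.feature_names)
        rng.shuffle(names)
        cut = rng.integers(1, len(names))
        plan = VerticalPlan((tuple(names[:cut]), tuple(names[cut:])))
        parts = vertical_split(mixed_dataset, plan)
        rebuilt = pd.concat([p.dataset.features for p in parts], axis=1)
        rebuilt = rebuilt[list(mixed_dataset.schema.feature_names)]
        pd.testing.assert_frame_equal(rebuilt, mixed_dataset.features)
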