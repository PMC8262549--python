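import numpy as np
import pandas as pd
import pytest

from latentfed.autoencoder import (
    AutoencoderConfig,
    build_embeddings,
    encode,
    load_autoencoder,
    reconstruction_loss,
    train_autoencoder,
)
from latentfed.dataset import SitePartition, TabularDataset, vertical_split
from latentfed.errors import (
    ConfigurationError,
    EncodeError,
    OvercompletenessError,
)
from latentfed.nn import softmax
from latentfed.schema import TabularSchema, VerticalPlan, categorical, continuous

SMALL = AutoencoderConfig(hidden_dims=(8, 16, 8), epochs=5, batch_size=16)


class TestBuildEmbeddings:
    def test_binary_cardinality_gets_width_one(self):
        schema = TabularSchema((categorical("c", 2),))
        assert build_embeddings(schema) == {"c": 1}

    def test_all_continuous_site_has_no_embeddings(self):
        schema = TabularSchema(tuple(continuous(f"f{i}") for i in range(3)))
        assert build_embeddings(schema) == {}

    def test_mixed_site_total_width(self):
        # widths min(50, ceil(card/2)): 9 -> 5, 16 -> 8, plus 3 continuous = 16
        schema = TabularSchema(
            (
                categorical("a", 9),
                categorical("b", 16),
                continuous("x"),
                continuous("y"),
                continuous("z"),
            )
        )
        widths = build_embeddings(schema)
        assert widths == {"a": 5, "b": 8}
        from latentfed.preprocess import post_embedding_width

        assert post_embedding_width(schema) == 16

    def test_large_cardinality_capped_at_fifty(self):
        schema = TabularSchema((categorical("big", 200),))
        assert build_embeddings(schema) == {"big": 50}

    def test_unknown_rule_is_configuration_error(self):
        schema = TabularSchema((categorical("c", 4),))
        with pytest.raises(ConfigurationError, match="unknown embedding rule"):
            build_embeddings(schema, rule="nope")


class TestConfig:
    def test_even_layer_list_rejected(self):
        with pytest.raises(ConfigurationError, match="odd"):
            AutoencoderConfig(hidden_dims=(64, 128))

    def test_code_dim_is_middle_layer(self):
        assert AutoencoderConfig().code_dim == 128
        assert AutoencoderConfig(hidden_dims=(4, 8, 4)).code_dim == 8

    def test_learning_rate_schedule_exact(self):
        cfg = AutoencoderConfig()
        for t in range(60):
            assert cfg.learning_rate(t) == 0.01 * 0.99**t


class TestTraining:
    def test_overcompleteness_enforced(self, cont_site):
        # 5 continuous inputs but code layer of 4
        with pytest.raises(OvercompletenessError):
            train_autoencoder(cont_site, AutoencoderConfig(hidden_dims=(4, 4, 4), epochs=1))

    def test_deterministic_given_seed(self, cont_site):
        m1 = train_autoencoder(cont_site, SMALL, seed=3)
        m2 = train_autoencoder(cont_site, SMALL, seed=3)
        assert m1.loss_history == m2.loss_history

    def test_lr_history_ratio_is_decay(self, cont_site):
        m = train_autoencoder(cont_site, SMALL, seed=0)
        lrs = np.asarray(m.lr_history)
        assert len(lrs) == SMALL.epochs
        np.testing.assert_allclose(lrs[1:] / lrs[:-1], 0.99, rtol=1e-12)

    def test_loss_decreases_on_synthetic_site(self):
        """5-feature site, 1,000 rows, 50 epochs: late loss below the first
        epoch's, and the last 20% of epochs below the first 20%."""
        from latentfed.synthetic import ContinuousSpec, SyntheticSpec, generate

        spec = SyntheticSpec(
            1000, tuple(ContinuousSpec(f"f{i}", 0.5) for i in range(5)), seed=7
        )
        ds = generate(spec)
        plan = VerticalPlan((tuple(f"f{i}" for i in range(5)),))
        part = vertical_split(ds, plan)[0]
        m = train_autoencoder(
            part, AutoencoderConfig(hidden_dims=(16, 32, 16), epochs=50), seed=7
        )
        lh = np.asarray(m.loss_history)
        assert lh[-10:].mean() < lh[0]
        assert lh[-10:].mean() < lh[:10].mean()

    def test_constant_partition_reaches_loss_floor(self):
        schema = TabularSchema((continuous("a"), categorical("b", 3)))
        frame = pd.DataFrame(
            {"a": np.full(64, 2.5), "b": np.zeros(64)}, index=pd.RangeIndex(64)
        )
        part = SitePartition(0, TabularDataset(schema, frame))
        m = train_autoencoder(
            part,
            AutoencoderConfig(hidden_dims=(4, 8, 4), epochs=300, batch_size=4),
            seed=1,
        )
        assert reconstruction_loss(m, part) < 0.1
        codes = encode(m, part).codes
        assert np.allclose(codes.var(axis=0), 0.0)  # identical rows, identical codes


class TestEncode:
    def test_shape_and_row_order(self, cont_site):
        m = train_autoencoder(cont_site, SMALL, seed=0)
        lat = encode(m, cont_site)
        assert lat.codes.shape == (cont_site.dataset.n_rows, 16)
        assert lat.row_ids.tolist() == cont_site.dataset.row_ids.tolist()
        assert np.isfinite(lat.codes).all()

    def test_single_row_partition(self, cont_site):
        m = train_autoencoder(cont_site, SMALL, seed=0)
        one = SitePartition(
            0, cont_site.dataset.select_rows(cont_site.dataset.row_ids[:1])
        )
        assert encode(m, one).codes.shape == (1, 16)

    def test_pure_function_of_rows(self, cont_site):
        """Identical input rows get identical codes regardless of position,
        and repeat calls are identical."""
        m = train_autoencoder(cont_site, SMALL, seed=0)
        ds = cont_site.dataset
        vals = ds.features.iloc[0].to_numpy()
        frame = pd.DataFrame(
            [vals, ds.features.iloc[1].to_numpy(), vals],
            columns=ds.features.columns,
            index=pd.RangeIndex(3),
        )
        dup = SitePartition(0, TabularDataset(ds.schema, frame))
        z = encode(m, dup).codes
        np.testing.assert_array_equal(z[0], z[2])
        np.testing.assert_array_equal(encode(m, dup).codes, z)
        # and matches the code computed within the full partition
        np.testing.assert_allclose(z[0], encode(m, cont_site).codes[0])

    def test_schema_mismatch_is_encode_error(self, cont_site):
        m = train_autoencoder(cont_site, SMALL, seed=0)
        wrong = SitePartition(
            0, cont_site.dataset.select_columns(["f0", "f1"])
        )
        with pytest.raises(EncodeError):
            encode(m, wrong)

    def test_save_load_round_trip(self, cont_site, tmp_path):
        m = train_autoencoder(cont_site, SMALL, seed=0)
        p = tmp_path / "site.npz"
        m.save(p)
        back = load_autoencoder(p)
        np.testing.assert_array_equal(
            encode(back, cont_site).codes, encode(m, cont_site).codes
        )
        assert back.loss_history == m.loss_history


class TestReconstructionLoss:
    def test_matches_independent_forward_pass(self, mixed_dataset, mixed_plan):
        """Arithmetic oracle: recompute the loss from the model's raw weight
        matrices with plain NumPy and compare."""
        part = vertical_split(mixed_dataset, mixed_plan)[0]  # age (cont) + job (cat)
        cfg = AutoencoderConfig(hidden_dims=(4, 8, 4), epochs=2, batch_size=8)
        m = train_autoencoder(part, cfg, seed=5)

        x_cont, codes = m.codec.transform(part.dataset)
        emb = m.embed.tables[0].value[codes[:, 0]]
        h = np.concatenate([x_cont, emb], axis=1)
        for layer in m.encoder.layers:
            if hasattr(layer, "W"):
                h = h @ layer.W.value + layer.b.value
            else:
                h = np.maximum(h, 0.0)
        d = h
        for layer in m.trunk.layers:
            if hasattr(layer, "W"):
                d = d @ layer.W.value + layer.b.value
            else:
                d = np.maximum(d, 0.0)
        pred = d @ m.cont_head.W.value + m.cont_head.b.value
        sse = ((pred - x_cont) ** 2).sum(axis=1)
        logits = d @ m.cat_heads[0].W.value + m.cat_heads[0].b.value
        p = softmax(logits)
        ce = -np.log(p[np.arange(len(codes)), codes[:, 0]])
        expected = float((sse + ce).mean())

        assert reconstruction_loss(m, part) == pytest.approx(expected, abs=1e-9)

    def test_uniform_categorical_head_gives_log_cardinality(self, mixed_dataset):
        """Zeroed head weights make the softmax uniform, so the categorical
        term is log(levels) per column exactly."""
        part = SitePartition(0, mixed_dataset.select_columns(["job"]))
        cfg = AutoencoderConfig(hidden_dims=(2, 4, 2), epochs=1, batch_size=8)
        m = train_autoencoder(part, cfg, seed=0)
        head = m.cat_heads[0]
        head.W.value[...] = 0.0
        head.b.value[...] = 0.0
        levels = head.b.value.shape[0]
        assert reconstruction_loss(m, part) == pytest.approx(np.log(levels), abs=1e-12)

    def test_anti_identity_after_training(self, cont_site):
        """The trained code is wider than the input and no latent column is an
        exact copy of a standardized input column."""
        m = train_autoencoder(cont_site, SMALL, seed=2)
        lat = encode(m, cont_site)
        assert lat.code_dim != cont_site.dataset.n_features
        x_cont, _ = m.codec.transform(cont_site.dataset)
        for i in range(x_cont.shape[1]):
            for j in range(lat.code_dim):
                z = lat.codes[:, j]
                if z.std() < 1e-12:
                    continue
                r = np.corrcoef(x_cont[:, i], z)[0, 1]
                assert abs(r) <= 0.999
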