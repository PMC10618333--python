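"""Label scaling, attention pooling, metrics and predictor training."""

import numpy as np
import pandas as pd
import pytest

from hitgen import nn
from hitgen.nn import Dense, Tensor
from hitgen.predictor import (
    CONFIGURATIONS,
    LabelScaler,
    Pic50Predictor,
    PredictorConfig,
    attention_pool,
    fine_tune,
    regression_metrics,
    standardize_labels,
    train_predictor,
)


class TestLabelScaler:
    def test_median_maps_to_zero(self):
        scaler, z = standardize_labels([2.0, 4.0, 6.0, 8.0, 10.0])
        assert scaler.transform(scaler.median) == pytest.approx(0.0)

    def test_linear_interpolation_quartiles(self):
        scaler = LabelScaler.fit(np.array([5, 6, 7, 8, 9], dtype=float))
        assert scaler.median == 7.0
        assert scaler.iqr == pytest.approx(2.0)  # Q1=6, Q3=8
        assert scaler.transform(8.0) == pytest.approx(0.5)

    def test_round_trip(self, rng):
        y = rng.normal(6, 1.5, size=40)
        scaler, z = standardize_labels(y)
        assert np.allclose(scaler.invert(z), y, atol=1e-12)

    def test_constant_labels_rejected(self):
        with pytest.raises(ValueError):
            LabelScaler.fit(np.full(10, 5.0))

    def test_too_few_labels_rejected(self):
        with pytest.raises(ValueError):
            LabelScaler.fit(np.array([1.0, 2.0]))


class TestAttentionPool:
    def _pool(self, hidden, rng_seed=0):
        B, T, H = hidden.shape
        net = Dense(H, 1, np.random.default_rng(rng_seed))
        return attention_pool(Tensor(hidden), net)

    def test_singleton_sequence_returns_hidden_state(self, rng):
        h = rng.normal(size=(2, 1, 4))
        context, alphas = self._pool(h)
        assert np.allclose(alphas.data, 1.0)
        assert np.allclose(context.data, h[:, 0])

    def test_equal_scores_give_mean_of_hidden_states(self, rng):
        h = np.repeat(rng.normal(size=(1, 1, 4)), 3, axis=1)
        context, alphas = self._pool(h)
        assert np.allclose(alphas.data, 1 / 3)
        assert np.allclose(context.data, h.mean(axis=1))

    def test_weights_sum_to_one(self, rng):
        h = rng.normal(size=(5, 7, 3))
        _, alphas = self._pool(h)
        assert np.allclose(alphas.data.sum(axis=1), 1.0, atol=1e-6)
        assert (alphas.data >= 0).all()

    def test_context_is_weighted_average(self, rng):
        h = rng.normal(size=(2, 4, 3))
        context, alphas = self._pool(h)
        manual = (h * alphas.data[:, :, None]).sum(axis=1)
        assert np.allclose(context.data, manual, atol=1e-12)

    def test_mask_excludes_padding(self, rng):
        h = rng.normal(size=(1, 4, 3))
        B, T, H = h.shape
        net = Dense(H, 1, np.random.default_rng(0))
        mask = np.array([[1.0, 1.0, 0.0, 0.0]])
        _, alphas = attention_pool(Tensor(h), net, mask)
        assert alphas.data[0, 2:].sum() == pytest.approx(0.0, abs=1e-12)


class TestRegressionMetrics:
    def test_perfect_predictions(self):
        y = np.array([1.0, 2.0, 3.0])
        m = regression_metrics(y, y)
        assert m.mse == 0.0 and m.q2 == 1.0 and m.ccc == pytest.approx(1.0)

    def test_mean_prediction_gives_zero_q2(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        m = regression_metrics(y, np.full(4, y.mean()))
        assert m.q2 == pytest.approx(0.0)

    def test_ccc_closed_form(self):
        y = np.array([1.0, 2.0, 3.0])
        yhat = np.array([1.0, 2.0, 4.0])
        sy2 = y.var()
        syh2 = yhat.var()
        cov = np.mean((y - y.mean()) * (yhat - yhat.mean()))
        expected = 2 * cov / (sy2 + syh2 + (y.mean() - yhat.mean()) ** 2)
        assert regression_metrics(y, yhat).ccc == pytest.approx(expected)

    def test_rmse_squares_to_mse(self, rng):
        y = rng.normal(size=30)
        yhat = y + rng.normal(scale=0.3, size=30)
        m = regression_metrics(y, yhat)
        assert m.rmse ** 2 == pytest.approx(m.mse, abs=1e-10)
        assert m.q2 <= 1.0
        assert -1.0 <= m.ccc <= 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            regression_metrics([1.0, 2.0], [1.0])


class TestConfigurationTable:
    def test_ten_rows(self):
        assert sorted(CONFIGURATIONS) == list("ABCDEFGHIJ")

    def test_attention_only_with_sequence_descriptor(self):
        for name, (desc, arch, attn) in CONFIGURATIONS.items():
            if attn:
                assert desc == "smiles"

    def test_unknown_configuration_rejected(self):
        with pytest.raises(ValueError):
            PredictorConfig(configuration="Z")


def _tiny_table(n=80, seed=0):
    from hitgen.fixtures import FixtureSpec, make_corpus, substructure_counts

    smiles = make_corpus(FixtureSpec(n=n, seed=seed))
    y = np.array([4.0 + 0.8 * substructure_counts(s)[0] for s in smiles])
    return pd.DataFrame({"smiles": smiles, "pic50": y})


class TestTraining:
    def test_fold_assignment_deterministic(self):
        df = _tiny_table()
        cfg = PredictorConfig(configuration="I", embedding_dim=8,
                              recurrent_units=8, max_len=60, batch_size=32)
        _, rep1 = train_predictor(df, cfg, seed=5, epochs=1, run_cv=False)
        _, rep2 = train_predictor(df, cfg, seed=5, epochs=1, run_cv=False)
        assert rep1["n_holdout"] == rep2["n_holdout"]
        assert rep1["holdout"].keys() == rep2["holdout"].keys()

    def test_duplicate_rows_collapsed_before_split(self):
        df = _tiny_table(60)
        doubled = pd.concat([df, df], ignore_index=True)
        cfg = PredictorConfig(configuration="I", embedding_dim=8,
                              recurrent_units=8, max_len=60)
        _, report = train_predictor(doubled, cfg, seed=0, epochs=1, run_cv=False)
        assert report["n_train"] + report["n_holdout"] == len(df)

    def test_unparseable_rows_dropped_with_count(self):
        df = _tiny_table(60)
        df.loc[len(df)] = ["C(", 5.0]
        cfg = PredictorConfig(configuration="I", embedding_dim=8,
                              recurrent_units=8, max_len=60)
        _, report = train_predictor(df, cfg, seed=0, epochs=1, run_cv=False)
        assert report["dropped_rows"] == 1

    def test_canonical_spellings_predict_identically(self, toy_predictor):
        a, _ = toy_predictor.predict(["OCC(=O)Nc1ccccc1"])
        b, _ = toy_predictor.predict(["c1ccccc1NC(=O)CO"])
        assert a[0] == pytest.approx(b[0], abs=1e-5)

    def test_batch_equals_per_item_prediction(self, toy_predictor):
        smiles = ["CCOc1ccccc1", "NC(=O)c1ccc(F)cc1", "CNC(=O)c1cccs1"]
        batch, _ = toy_predictor.predict(smiles)
        singles = [toy_predictor.predict([s])[0][0] for s in smiles]
        assert np.allclose(batch, singles, atol=1e-5)

    def test_invalid_smiles_flagged_not_scored(self, toy_predictor):
        values, flags = toy_predictor.predict(["CCO", "C("])
        assert flags.tolist() == [True, False]
        assert np.isnan(values[1]) and np.isfinite(values[0])

    def test_attention_weight_length_matches_tokens(self, toy_predictor, vocab):
        from hitgen.tokenizer import tokenize

        smi = "CC(=O)Nc1ccc(Cl)cc1"
        ctx = toy_predictor.attention_weights(smi)
        assert len(ctx.alphas) == len(tokenize(smi, vocab))


class TestFineTune:
    def test_zero_epochs_is_identity(self, toy_predictor):
        before = [a.copy() for a in toy_predictor.state_arrays()]
        fine_tune(toy_predictor, _tiny_table(60), epochs=0)
        for a, b in zip(before, toy_predictor.state_arrays()):
            assert np.array_equal(a, b)

    def test_empty_subset_rejected(self, toy_predictor):
        with pytest.raises(ValueError):
            fine_tune(toy_predictor, pd.DataFrame({"smiles": [], "pic50": []}))

    def test_shifted_labels_pull_predictions(self):
        df = _tiny_table(120, seed=3)
        cfg = PredictorConfig(configuration="D", embedding_dim=16,
                              recurrent_units=16, max_len=60, batch_size=32)
        model = Pic50Predictor(config=cfg, seed=0)
        model.fit(list(df.smiles), df.pic50.to_numpy(), seed=0, epochs=8)
        subset = df.iloc[:40].copy()
        before, _ = model.predict(list(subset.smiles))
        subset["pic50"] = subset["pic50"] + 1.0
        fine_tune(model, subset, epochs=8, lr_factor=1.0)
        after, _ = model.predict(list(subset.smiles))
        assert np.nanmean(after) > np.nanmean(before)
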