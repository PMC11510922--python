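"""Bidirectional LSTM stack: parameter counts, gradients, training."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import emgait as eg
import emgait.model as M
from emgait.dataset import LabeledSequence, SequenceDataset


def toy_dataset(n=16, T=50, input_dim=2, seed=0, split="train"):
    """Separable sequences: the first channel's level encodes the label."""
    rng = np.random.default_rng(seed)
    seqs = []
    for _ in range(n):
        y = np.repeat((rng.random(T // 10) < 0.5).astype(np.int8), 10)
        x = np.column_stack(
            [y + 0.1 * rng.standard_normal(T)] +
            [0.1 * rng.standard_normal(T) for _ in range(input_dim - 1)])
        seqs.append(LabeledSequence(x, y, "S01", "WO", 500.0, 0.0))
    return SequenceDataset(seqs, [split] * n)


class TestCountParameters:
    def test_reference_stack_input2(self):
        cfg = eg.ModelConfig.reference_counts()
        assert eg.count_parameters(cfg) == 1_233_677

    def test_first_layer_alone(self):
        # 8 * u * (d + u + 1) for u=200 units on d=2 inputs
        assert 8 * 200 * (2 + 200 + 1) == 324_800

    def test_unit_case_by_hand(self):
        # one bidirectional layer, 1 unit, input_dim 1: 2*4*(1+1+1) = 24
        cfg = eg.ModelConfig(input_dim=1, seq_len=4, bi_units=(1,),
                             dense_units=(), n_classes=2)
        assert eg.count_parameters(cfg) == 24 + (2 + 1) * 2

    def test_reference_stack_input4(self):
        assert eg.count_parameters(eg.ModelConfig(input_dim=4)) == 1_236_877

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        input_dim=st.integers(1, 6),
        bi=st.lists(st.integers(1, 24), min_size=1, max_size=3),
        dense=st.lists(st.integers(1, 24), min_size=0, max_size=3),
    )
    def test_closed_form_matches_realized(self, input_dim, bi, dense):
        cfg = eg.ModelConfig(input_dim=input_dim, seq_len=8,
                             bi_units=tuple(bi), dense_units=tuple(dense),
                             dropout=0.0)
        model = eg.build_model(cfg, seed=0)
        assert model.n_parameters() == eg.count_parameters(cfg)


@pytest.fixture(scope="module")
def small_model():
    cfg = eg.ModelConfig(input_dim=3, seq_len=20, bi_units=(6, 4),
                         dense_units=(5,), dropout=0.5)
    return eg.build_model(cfg, seed=2)


class TestBuildAndPredict:
    def test_invalid_config(self):
        with pytest.raises(ValueError):
            eg.ModelConfig(input_dim=0)
        with pytest.raises(ValueError):
            eg.ModelConfig(dropout=1.0)
        with pytest.raises(ValueError):
            eg.ModelConfig(bi_units=(0,))

    def test_output_shape_and_softmax(self, small_model):
        x = np.random.default_rng(0).standard_normal((20, 3))
        probs = small_model.predict_proba(x)
        assert probs.shape == (20, 2)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert probs.min() >= 0.0

    def test_inference_deterministic(self, small_model):
        x = np.random.default_rng(1).standard_normal((4, 20, 3))
        a = small_model.predict_proba(x)
        b = small_model.predict_proba(x)
        np.testing.assert_array_equal(a, b)

    def test_batch_equals_sample_by_sample(self, small_model):
        x = np.random.default_rng(2).standard_normal((5, 20, 3))
        batch = small_model.predict_proba(x)
        singles = np.stack([small_model.predict_proba(x[i]) for i in range(5)])
        np.testing.assert_allclose(batch, singles, atol=1e-6)

    def test_shape_mismatch_rejected(self, small_model):
        with pytest.raises(ValueError, match="expected input"):
            small_model.predict_proba(np.zeros((20, 5)))

    def test_save_load_round_trip(self, small_model, tmp_path):
        small_model.save(tmp_path / "m")
        back = M.BiLSTMPhaseModel.load(tmp_path / "m")
        x = np.random.default_rng(3).standard_normal((2, 20, 3))
        np.testing.assert_array_equal(back.predict_proba(x),
                                      small_model.predict_proba(x))


class TestGradients:
    def test_bptt_matches_finite_differences(self):
        """Analytic gradients vs central differences in float64."""
        old = M.DTYPE
        M.DTYPE = np.float64
        try:
            cfg = eg.ModelConfig(input_dim=2, seq_len=7, bi_units=(3, 2),
                                 dense_units=(4,), dropout=0.0)
            model = eg.build_model(cfg, seed=1)
            rng = np.random.default_rng(0)
            x = rng.standard_normal((2, 7, 2))
            y = rng.integers(0, 2, (2, 7))
            _, grads = model.loss_and_grads(x, y, training=False)
            for k, g in grads.items():
                P = model.params[k]
                for idx in [tuple(rng.integers(0, s) for s in P.shape)
                            for _ in range(3)]:
                    eps, orig = 1e-6, P[idx]
                    P[idx] = orig + eps
                    lp, _ = model.loss_and_grads(x, y, training=False)
                    P[idx] = orig - eps
                    lm, _ = model.loss_and_grads(x, y, training=False)
                    P[idx] = orig
                    num = (lp - lm) / (2 * eps)
                    denom = max(1e-8, abs(num) + abs(g[idx]))
                    assert abs(num - g[idx]) / denom < 1e-4, k
        finally:
            M.DTYPE = old


class TestTraining:
    def test_zero_epochs_leaves_weights(self):
        ds = toy_dataset()
        model = eg.build_model(eg.ModelConfig(input_dim=2, seq_len=50,
                                              bi_units=(4,), dense_units=(4,)))
        before = {k: v.copy() for k, v in model.params.items()}
        eg.train(model, ds, eg.TrainConfig(epochs=0))
        for k in before:
            np.testing.assert_array_equal(model.params[k], before[k])

    def test_single_batch_overfits(self):
        """Capacity sanity: one batch is memorized to >=99% accuracy."""
        ds = toy_dataset(n=16, T=50)
        cfg = eg.ModelConfig(input_dim=2, seq_len=50, bi_units=(8,),
                             dense_units=(8,), dropout=0.0)
        model = eg.build_model(cfg, seed=0)
        tc = eg.TrainConfig(epochs=60, batch_size=16, learning_rate=3e-3, seed=0)
        eg.train(model, ds, tc)
        X, Y = ds.arrays("train")
        acc = np.mean(model.predict_labels(X) == Y)
        assert acc >= 0.99

    def test_empty_train_split_rejected(self):
        ds = toy_dataset(split="test")
        model = eg.build_model(eg.ModelConfig(input_dim=2, seq_len=50,
                                              bi_units=(4,), dense_units=()))
        with pytest.raises(ValueError):
            eg.train(model, ds, eg.TrainConfig(epochs=1))

    def test_training_reproducible(self):
        results = []
        for _ in range(2):
            ds = toy_dataset(n=8, T=30)
            cfg = eg.ModelConfig(input_dim=2, seq_len=30, bi_units=(4,),
                                 dense_units=(4,), dropout=0.2)
            model = eg.build_model(cfg, seed=5)
            eg.train(model, ds, eg.TrainConfig(epochs=3, seed=5))
            results.append({k: v.copy() for k, v in model.params.items()})
        for k in results[0]:
            np.testing.assert_array_equal(results[0][k], results[1][k])


class TestPartialRetrain:
    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            eg.TrainConfig(retrain_fraction=0.0)
        with pytest.raises(ValueError):
            eg.TrainConfig(retrain_fraction=1.5)

    def test_subset_is_seeded(self):
        """Same seed, same subset: identical retrained weights."""
        outs = []
        for _ in range(2):
            ds = toy_dataset(n=12, T=30)
            cfg = eg.ModelConfig(input_dim=2, seq_len=30, bi_units=(4,),
                                 dense_units=(), dropout=0.0)
            model = eg.build_model(cfg, seed=1)
            eg.partial_retrain(model, ds, eg.TrainConfig(
                epochs=2, seed=9, retrain_fraction=0.3))
            outs.append({k: v.copy() for k, v in model.params.items()})
        for k in outs[0]:
            np.testing.assert_array_equal(outs[0][k], outs[1][k])

    def test_full_fraction_is_continued_training(self):
        ds = toy_dataset(n=8, T=30)
        cfg = eg.ModelConfig(input_dim=2, seq_len=30, bi_units=(4,),
                             dense_units=(), dropout=0.0)
        model = eg.build_model(cfg, seed=1)
        before = {k: v.copy() for k, v in model.params.items()}
        eg.partial_retrain(model, ds, eg.TrainConfig(
            epochs=1, seed=0, retrain_fraction=1.0))
        changed = any(not np.array_equal(model.params[k], before[k])
                      for k in before)
        assert changed
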