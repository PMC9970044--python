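import numpy as np
import pytest

from ecgtf.features import FusedFeature
from ecgtf.model import (CLASS_ORDER, ModelSpec, TrainConfig, build_model,
                         cross_entropy, evaluate, load_model, predict,
                         save_model, stratified_split, train)


def double_loop_cross_entropy(y_true, y_pred, eps=1e-12):
    total = 0.0
    for i in range(y_true.shape[0]):
        for c in range(y_true.shape[1]):
            total += y_true[i, c] * np.log(max(y_pred[i, c], eps))
    return -total / y_true.shape[0]


def make_features(n, seed=0, input_len=480, separation=4.0):
    """Five-class set with class-specific block patterns plus noise."""
    rng = np.random.default_rng(seed)
    feats = []
    block = input_len // 5
    for i in range(n):
        c = i % 5
        v = rng.normal(scale=1.0, size=input_len)
        v[c * block:(c + 1) * block] += separation
        feats.append(FusedFeature(v, time_len=300, freq_len=input_len - 300,
                                  label=CLASS_ORDER[c]))
    return feats


@pytest.fixture(scope="module")
def memorized_model():
    feats = make_features(10, seed=1, separation=2.0)
    cfg = TrainConfig(epochs=200, batch_size=10, seed=3)
    return feats, train(feats, cfg, spec=ModelSpec(seed=3))


class TestArchitecture:
    def test_layer_shape_ledger(self):
        model = build_model(ModelSpec(input_len=480))
        shapes = [s for _, s in model.layer_shapes]
        assert shapes == [(480, 1), (480, 4), (240, 4), (240, 16), (120, 16),
                          (120, 32), (60, 32), (60, 64), (3840, 1), (128, 1),
                          (5, 1)]

    def test_flatten_width_scales_with_input(self):
        assert ModelSpec(input_len=480).flatten_width == 3840
        assert ModelSpec(input_len=8).flatten_width == 64

    def test_indivisible_input_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            build_model(ModelSpec(input_len=100))

    def test_same_seed_same_parameter_count_and_weights(self):
        a = build_model(ModelSpec(seed=5))
        b = build_model(ModelSpec(seed=5))
        assert a.n_parameters() == b.n_parameters()
        for (pa, _), (pb, _) in zip(a.network.params(), b.network.params()):
            np.testing.assert_array_equal(pa, pb)


class TestCrossEntropy:
    def test_perfect_prediction_is_zero(self):
        y = np.eye(5)
        assert cross_entropy(y, y) == pytest.approx(0.0, abs=1e-10)

    def test_uniform_prediction(self):
        y = np.eye(5)[[0, 2, 4]]
        p = np.full((3, 5), 0.2)
        assert cross_entropy(y, p) == pytest.approx(-np.log(0.2), abs=1e-10)

    def test_half_confidence(self):
        y = np.array([[1.0, 0, 0, 0, 0]])
        p = np.array([[0.5, 0.2, 0.1, 0.1, 0.1]])
        assert cross_entropy(y, p) == pytest.approx(-np.log(0.5), abs=1e-10)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cross_entropy(np.eye(5), np.full((3, 5), 0.2))

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            z = rng.random((8, 5))
            p = z / z.sum(axis=1, keepdims=True)
            y = np.eye(5)[rng.integers(0, 5, size=8)]
            assert abs(cross_entropy(y, p) - double_loop_cross_entropy(y, p)) < 1e-10


class TestTraining:
    def test_separable_data_overfits(self):
        feats = make_features(200, seed=4)
        model = train(feats, TrainConfig(epochs=30, seed=4),
                      spec=ModelSpec(seed=4))
        assert model.training_history["accuracy"][-1] >= 0.99

    def test_loss_decreases_monotonically_within_tolerance(self):
        feats = make_features(200, seed=4)
        model = train(feats, TrainConfig(epochs=30, seed=4),
                      spec=ModelSpec(seed=4))
        loss = model.training_history["loss"]
        assert all(b <= a + 0.05 for a, b in zip(loss, loss[1:]))

    def test_memorization(self, memorized_model):
        feats, model = memorized_model
        assert model.training_history["loss"][-1] < 0.05
        _, labels = predict(model, feats)
        assert labels == [f.label for f in feats]

    def test_training_is_deterministic_given_seed(self):
        feats = make_features(40, seed=6)
        cfg = TrainConfig(epochs=3, seed=9)
        h1 = train(feats, cfg, spec=ModelSpec(seed=9)).training_history
        h2 = train(feats, cfg, spec=ModelSpec(seed=9)).training_history
        assert h1 == h2

    def test_single_class_rejected(self):
        feats = [f for f in make_features(20, seed=1) if f.label == "N"]
        with pytest.raises(ValueError):
            train(feats, TrainConfig(epochs=1))


class TestPredictEvaluate:
    def test_rows_are_probabilities(self, memorized_model):
        feats, model = memorized_model
        probs, _ = predict(model, feats)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert probs.shape[1] == 5

    def test_permutation_equivariance(self, memorized_model):
        feats, model = memorized_model
        p1, _ = predict(model, feats)
        p2, _ = predict(model, feats[::-1])
        np.testing.assert_allclose(p2, p1[::-1], atol=1e-6)

    def test_wrong_length_rejected(self, memorized_model):
        _, model = memorized_model
        bad = [FusedFeature(np.zeros(200), time_len=100, freq_len=100, label="N")]
        with pytest.raises(ValueError):
            predict(model, bad)

    def test_perfect_predictions_metrics(self, memorized_model):
        feats, model = memorized_model
        m = evaluate(model, feats)
        assert m["accuracy"] == 1.0
        conf = m["confusion_matrix"]
        assert np.all(conf == np.diag(np.diag(conf)))

    def test_confusion_rows_equal_support(self, memorized_model):
        feats, model = memorized_model
        m = evaluate(model, feats)
        support = m["confusion_matrix"].sum(axis=1)
        for i, sym in enumerate(m["class_order"]):
            assert support[i] == sum(f.label == sym for f in feats)

    def test_empty_input_rejected(self, memorized_model):
        _, model = memorized_model
        with pytest.raises(ValueError):
            evaluate(model, [])


class TestSplitAndSerialization:
    def test_stratified_fractions(self):
        feats = make_features(100, seed=3)
        tr, te = stratified_split(feats, 0.7, seed=1)
        assert len(tr) + len(te) == 100
        for sym in CLASS_ORDER:
            n_tr = sum(f.label == sym for f in tr)
            assert n_tr == 14  # 70% of the 20 per class

    def test_starved_class_rejected(self):
        feats = make_features(41, seed=3)  # one class has a single example
        feats = [f for f in feats if f.label != "R"] + \
                [f for f in feats if f.label == "R"][:1]
        with pytest.raises(ValueError, match="at least 2"):
            stratified_split(feats, 0.7)

    def test_save_load_roundtrip(self, memorized_model, tmp_path):
        feats, model = memorized_model
        save_model(model, tmp_path / "m")
        clone = load_model(tmp_path / "m")
        p1, _ = predict(model, feats)
        p2, _ = predict(clone, feats)
        np.testing.assert_allclose(p2, p1, atol=1e-6)
        assert clone.training_history == model.training_history
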