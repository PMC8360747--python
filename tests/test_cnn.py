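"""CNN architecture contracts, optimization sanity, evaluation metrics."""

import numpy as np
import pytest

from ppgbp.cnn import (
    CNNConfig,
    TrainConfig,
    _bce_with_logits,
    build_model,
    evaluate,
    grid_search,
    train,
)
from ppgbp.synthetic import generate_dataset


def _toy_data(n=24, size=16, seed=0):
    """Trivially separable images: class 1 bright upper half, class 0 dark."""
    rng = np.random.default_rng(seed)
    y = np.arange(n) % 2
    x = rng.uniform(0.0, 0.3, size=(n, 3, size, size)).astype(np.float32)
    x[y == 1, :, : size // 2, :] += 0.6
    return x, y.astype(np.float64)


class TestArchitecture:
    def test_canonical_feature_shapes(self):
        """224 input: conv/pool halvings give 112 and 56, flatten 401408."""
        model = build_model(CNNConfig(), seed=0)
        shapes = model.feature_shapes()
        assert shapes["conv1"] == (224, 224, 64)
        assert shapes["pool1"] == (112, 112, 64)
        assert shapes["pool2"] == (56, 56, 128)
        assert shapes["flatten"] == (401408,)

    def test_conv1_parameter_count(self):
        model = build_model(CNNConfig(), seed=0)
        assert model.conv1.n_params == 1792  # 64 * (3*3*3 + 1)

    def test_conv2_parameter_count(self):
        model = build_model(CNNConfig(), seed=0)
        assert model.conv2.n_params == 128 * (5 * 5 * 64 + 1)

    def test_full_size_forward_prob_in_unit_interval(self):
        model = build_model(CNNConfig(), seed=1)
        x = np.random.default_rng(0).uniform(size=(1, 3, 224, 224)).astype(np.float32)
        p = model.predict_proba(x)
        assert p.shape == (1,) and 0.0 <= p[0] <= 1.0

    def test_odd_input_same_padding_pools_to_ceil(self):
        model = build_model(CNNConfig(input_size=15), seed=0)
        x = np.zeros((2, 3, 15, 15), dtype=np.float32)
        assert model.predict_proba(x).shape == (2,)
        assert model.feature_shapes()["pool2"] == (4, 4, 128)

    def test_wrong_input_shape_rejected(self):
        model = build_model(CNNConfig(input_size=16), seed=0)
        with pytest.raises(ValueError):
            model.forward_logits(np.zeros((1, 3, 32, 32), dtype=np.float32))


class TestGradients:
    def test_numerical_gradient_check(self):
        """Backprop matches central finite differences on a tiny model."""
        model = build_model(CNNConfig(input_size=8, conv1_filters=4,
                                      conv2_filters=6, dense1_units=10,
                                      dense2_units=5), seed=3).astype(np.float64)
        rng = np.random.default_rng(4)
        x = rng.uniform(size=(3, 3, 8, 8))
        y = np.array([1.0, 0.0, 1.0])

        def loss_at():
            z = model.forward_logits(x, train=True)
            return _bce_with_logits(z, y)

        loss, dz = loss_at()
        model.backward(dz)
        eps = 1e-6
        for layer, flat_idx in ((model.conv1, 5), (model.conv2, 101),
                                (model.dense2, 17), (model.out, 2)):
            analytic = layer.dW.ravel()[flat_idx]
            w = layer.W.ravel()
            orig = w[flat_idx]
            w[flat_idx] = orig + eps
            lp = loss_at()[0]
            w[flat_idx] = orig - eps
            lm = loss_at()[0]
            w[flat_idx] = orig
            numeric = (lp - lm) / (2 * eps)
            assert analytic == pytest.approx(numeric, rel=1e-4, abs=1e-8)


class TestTraining:
    def test_memorizes_separable_set(self):
        x, y = _toy_data(n=40)
        model = build_model(CNNConfig(input_size=16), seed=0)
        cfg = TrainConfig(learning_rate=1e-3, batch_size=8, epochs=30, seed=0,
                          input_size=16)
        history = train(model, (x, y), cfg)
        report = evaluate(model, (x, y))
        assert report.accuracy == 1.0
        assert history["train_loss"][-1] <= history["train_loss"][0]
        assert len(history["train_loss"]) == cfg.epochs

    def test_seed_reproducibility_checksum(self):
        x, y = _toy_data(n=12)
        sums = []
        for _ in range(2):
            model = build_model(CNNConfig(input_size=16), seed=5)
            train(model, (x, y), TrainConfig(learning_rate=1e-3, batch_size=4,
                                             epochs=2, seed=5, input_size=16))
            sums.append(model.weights_checksum())
        assert sums[0] == sums[1]

    def test_single_class_rejected(self):
        x, y = _toy_data(n=8)
        model = build_model(CNNConfig(input_size=16), seed=0)
        with pytest.raises(ValueError, match="both classes"):
            train(model, (x, np.zeros_like(y)),
                  TrainConfig(epochs=1, seed=0, input_size=16))


class TestEvaluate:
    class _Stub:
        """Fixed-score classifier standing in for a trained model."""

        def __init__(self, scores):
            self._scores = np.asarray(scores, dtype=float)
            self.config = CNNConfig(input_size=16)

        def predict_proba(self, x, batch_size=32):
            return self._scores

    def test_perfect_scores(self):
        y = np.array([0.0, 0.0, 1.0, 1.0])
        report = evaluate(self._Stub([0.0, 0.1, 0.9, 1.0]),
                          (np.zeros((4, 3, 16, 16)), y))
        assert report.accuracy == 1.0 and report.auc == 1.0

    def test_constant_score_balanced(self):
        y = np.array([0.0, 1.0] * 10)
        report = evaluate(self._Stub(np.full(20, 0.7)),
                          (np.zeros((20, 3, 16, 16)), y))
        assert report.accuracy == 0.5
        assert report.auc == pytest.approx(0.5)

    def test_random_scores_auc_near_half(self):
        rng = np.random.default_rng(0)
        y = np.tile([0.0, 1.0], 1000)
        report = evaluate(self._Stub(rng.uniform(size=2000)),
                          (np.zeros((2000, 3, 16, 16)), y))
        assert report.auc == pytest.approx(0.5, abs=0.05)

    def test_roc_monotone_with_endpoints(self):
        rng = np.random.default_rng(3)
        y = np.tile([0.0, 1.0], 25)
        scores = np.clip(rng.normal(0.4, 0.2, 50) + 0.2 * y, 0, 1)
        report = evaluate(self._Stub(scores), (np.zeros((50, 3, 16, 16)), y))
        fpr = np.array([p[0] for p in report.roc])
        tpr = np.array([p[1] for p in report.roc])
        assert (fpr[0], tpr[0]) == (0.0, 0.0) and (fpr[-1], tpr[-1]) == (1.0, 1.0)
        assert np.all(np.diff(fpr) >= 0) and np.all(np.diff(tpr) >= 0)

    def test_accuracy_recomputed_from_scores(self):
        rng = np.random.default_rng(9)
        y = np.tile([0.0, 1.0], 20)
        scores = rng.uniform(size=40)
        report = evaluate(self._Stub(scores), (np.zeros((40, 3, 16, 16)), y))
        tp = np.sum((scores >= 0.5) & (y == 1))
        tn = np.sum((scores < 0.5) & (y == 0))
        assert report.accuracy == pytest.approx((tp + tn) / 40)

    def test_empty_split_rejected(self):
        with pytest.raises(ValueError):
            evaluate(self._Stub([]), (np.zeros((0, 3, 16, 16)), np.array([])))


class TestGridSearch:
    def test_micro_grid_completes(self, tmp_path):
        records = generate_dataset(6, (0.5, 0.0, 0.0, 0.5), base_seed=1,
                                   n_samples=1500)
        cfg = TrainConfig(learning_rate=1e-3, batch_size=8, epochs=2, seed=0,
                          input_size=16)
        result = grid_search(records, [make_spec_safe("mexh"), None], [300],
                             cfg, tmp_path)
        assert result.accuracies.shape == (2, 1)
        assert result.errors == {}
        vals = result.accuracies.to_numpy().ravel()
        assert np.all((vals >= 0.0) & (vals <= 1.0))

    def test_empty_grid_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            grid_search([], [], [300], TrainConfig(), tmp_path)


def make_spec_safe(name):
    from ppgbp.wavelets import make_spec

    return make_spec(name)
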