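"""Network construction, gradient correctness, training behaviour."""

import numpy as np
import pytest

from ogtpred import _nn
from ogtpred.corpus import ProteinRecord
from ogtpred.model import (
    GridSearchResult,
    ModelConfig,
    TrainedModel,
    build_model,
    grid_search,
    min_input_length,
    train,
)

RNG = np.random.default_rng(42)
AA = "ACDEFGHIKLMNPQRSTVWY"


def _random_proteins(n, length, rng, labels=None):
    prots = []
    for i in range(n):
        seq = "".join(rng.choice(list(AA), size=length))
        label = labels[i] if labels is not None else None
        prots.append(ProteinRecord(f"p{i:03d}", "g", seq, label_celsius=label))
    return prots


def _composition_labelled(n, length, seed):
    """Labels are a linear function of E-content: easily learnable."""
    rng = np.random.default_rng(seed)
    prots = []
    for i in range(n):
        n_e = rng.integers(0, length + 1)
        seq = "E" * n_e + "".join(rng.choice(list("AGKT"), size=length - n_e))
        seq = "".join(rng.permutation(list(seq)))
        label = 10.0 + 80.0 * n_e / length
        prots.append(ProteinRecord(f"p{i:03d}", "g", seq, label_celsius=label))
    return prots


class TestBuildModel:
    def test_filter_count_and_width(self):
        cfg = ModelConfig(kernel_size=18, n_neurons=256)
        net = build_model(cfg, l_max=100)
        conv1 = net.layers[0]
        assert conv1.k == 18 and conv1.c_out == 256 and conv1.c_in == 20

    def test_parameter_count_matches_closed_form(self):
        cfg = ModelConfig(kernel_size=3, n_neurons=4)
        net = build_model(cfg, l_max=40)
        # conv1: (3*20)*4+4; pool -> 19; conv2: (3*4)*4+4; pool -> 8
        # dense1: (8*4)*4+4; dense2: 4*4+4; out: 4+1
        expected = (3 * 20 * 4 + 4) + (3 * 4 * 4 + 4) + (32 * 4 + 4) + (4 * 4 + 4) + (4 + 1)
        assert net.n_parameters() == expected

    def test_same_seed_identical_initial_weights(self):
        cfg = ModelConfig(kernel_size=3, n_neurons=4, seed=5)
        w1 = build_model(cfg, l_max=40).get_weights()
        w2 = build_model(cfg, l_max=40).get_weights()
        for a, b in zip(w1, w2):
            np.testing.assert_array_equal(a, b)

    def test_too_small_l_max_reports_minimum(self):
        cfg = ModelConfig(kernel_size=18, n_neurons=4)
        with pytest.raises(ValueError, match=str(min_input_length(cfg))):
            build_model(cfg, l_max=20)

    @pytest.mark.parametrize(
        "bad_kwargs",
        [
            {"kernel_size": 0},
            {"dropout_rate": 1.0},
            {"dropout_rate": -0.1},
            {"batch_size": 0},
        ],
    )
    def test_invalid_config_rejected(self, bad_kwargs):
        with pytest.raises(ValueError):
            ModelConfig(**bad_kwargs)


class TestGradients:
    """Backprop against central-difference numeric gradients."""

    def _loss_of(self, net, x, y):
        pred = net.forward(x, train=True)
        return float(np.mean((pred - y) ** 2))

    def test_numeric_gradient_agreement(self):
        rng = np.random.default_rng(3)
        net = _nn.Sequential(
            [
                _nn.Conv1D(20, 3, 3, rng),
                _nn.ReLU(),
                _nn.MaxPool1D(2),
                _nn.Flatten(),
                _nn.Dense(3 * 5, 4, rng),
                _nn.ReLU(),
                _nn.Dense(4, 1, rng),
            ]
        )
        x = rng.random((4, 12, 20)).astype(np.float32)
        y = rng.random((4, 1)).astype(np.float32)
        pred = net.forward(x, train=True)
        _, grad = _nn.mse_loss(pred, y)
        net.backward(grad)
        eps = 1e-3
        checked = 0
        for p in net.params():
            w = p["value"]
            analytic = p["grad"]()
            flat = w.reshape(-1)
            for idx in rng.choice(flat.size, size=min(5, flat.size), replace=False):
                orig = flat[idx]
                flat[idx] = orig + eps
                up = self._loss_of(net, x, y)
                flat[idx] = orig - eps
                down = self._loss_of(net, x, y)
                flat[idx] = orig
                numeric = (up - down) / (2 * eps)
                assert analytic.reshape(-1)[idx] == pytest.approx(numeric, rel=0.05, abs=1e-3)
                checked += 1
        assert checked >= 15

    def test_adam_amsgrad_reduces_loss_on_quadratic(self):
        rng = np.random.default_rng(0)
        layer = _nn.Dense(4, 1, rng)
        net = _nn.Sequential([layer])
        opt = _nn.Adam(net.params(), learning_rate=0.05, amsgrad=True)
        x = rng.random((16, 4)).astype(np.float32)
        true_w = np.array([[1.0], [-2.0], [0.5], [3.0]], dtype=np.float32)
        y = x @ true_w
        first = None
        for _ in range(200):
            pred = net.forward(x, train=True)
            loss, grad = _nn.mse_loss(pred, y)
            if first is None:
                first = loss
            net.backward(grad)
            opt.step()
        assert loss < first * 1e-3


class TestTrain:
    def test_training_loss_decreases_on_learnable_signal(self):
        prots = _composition_labelled(50, 30, seed=1)
        cfg = ModelConfig(
            kernel_size=3, n_neurons=8, max_epochs=5, early_stop_patience=5, seed=1
        )
        fitted = train(prots, prots[:10], cfg, l_max=30)
        losses = fitted.training_history["train_loss"].to_numpy()
        assert losses[-1] < losses[0]

    def test_early_stopping_on_constant_labels(self):
        rng = np.random.default_rng(2)
        prots = [
            ProteinRecord(p.protein_id, "g", p.sequence, label_celsius=37.0)
            for p in _random_proteins(40, 25, rng)
        ]
        cfg = ModelConfig(
            kernel_size=3,
            n_neurons=4,
            max_epochs=100,
            early_stop_patience=3,
            learning_rate=0.05,  # converge to the constant quickly, then plateau
            seed=2,
        )
        fitted = train(prots, prots[:8], cfg, l_max=25)
        assert len(fitted.training_history) < 100
        # best weights restored: prediction has moved toward the constant label
        preds = fitted.predict(prots[:5])
        assert np.all(np.abs(preds - 37.0) < 15.0)

    def test_same_seed_reproduces_weights_and_history(self):
        prots = _composition_labelled(30, 20, seed=3)
        cfg = ModelConfig(kernel_size=3, n_neurons=4, max_epochs=4, seed=3)
        m1 = train(prots, prots[:6], cfg, l_max=20)
        m2 = train(prots, prots[:6], cfg, l_max=20)
        assert m1.stopped_epoch == m2.stopped_epoch
        for a, b in zip(m1.weights, m2.weights):
            np.testing.assert_array_equal(a, b)

    def test_empty_split_rejected(self):
        prots = _composition_labelled(10, 20, seed=4)
        cfg = ModelConfig(kernel_size=3, n_neurons=4)
        with pytest.raises(ValueError, match="non-empty"):
            train(prots, [], cfg, l_max=20)


class TestPredict:
    @pytest.fixture(scope="class")
    def fitted(self):
        prots = _composition_labelled(40, 20, seed=5)
        cfg = ModelConfig(kernel_size=3, n_neurons=4, max_epochs=3, seed=5)
        return train(prots, prots[:8], cfg, l_max=20), prots

    def test_duplicate_sequences_identical_predictions(self, fitted):
        model, prots = fitted
        dup = [prots[0], ProteinRecord("copy", "g", prots[0].sequence)]
        preds = model.predict(dup)
        assert preds[0] == preds[1]

    def test_batch_equals_one_at_a_time(self, fitted):
        model, prots = fitted
        batch = model.predict(prots[:6])
        singles = np.array([model.predict([p])[0] for p in prots[:6]])
        np.testing.assert_allclose(batch, singles, atol=1e-5)

    def test_serialise_round_trip_preserves_predictions(self, fitted, tmp_path):
        model, prots = fitted
        path = tmp_path / "model.npz"
        model.save(path)
        loaded = TrainedModel.load(path)
        np.testing.assert_allclose(
            model.predict(prots[:5]), loaded.predict(prots[:5]), atol=1e-6
        )
        assert loaded.config == model.config

    def test_schema_mismatch_rejected(self, fitted, tmp_path):
        import json

        model, _ = fitted
        path = tmp_path / "model.npz"
        model.save(path)
        # tamper with the schema tag
        with np.load(path) as payload:
            arrays = {k: payload[k] for k in payload.files}
        meta = json.loads(bytes(arrays["meta"]).decode())
        meta["schema"] = "other-schema"
        arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
        np.savez(path, **arrays)
        with pytest.raises(ValueError, match="schema"):
            TrainedModel.load(path)


class TestGridSearch:
    def test_single_pair(self):
        prots = _composition_labelled(30, 20, seed=6)
        cfg = ModelConfig(max_epochs=2, seed=6)
        result = grid_search([3], [8], prots, prots[:8], cfg, l_max=20)
        assert isinstance(result, GridSearchResult)
        assert len(result.tried) == 1
        assert (result.best.kernel_size, result.best.n_neurons) == (3, 8)

    def test_tie_broken_by_smaller_kernel(self):
        prots = _composition_labelled(30, 20, seed=7)
        cfg = ModelConfig(max_epochs=2, seed=7)
        # duplicated kernel candidate -> identical r for both rows
        result = grid_search([3, 3], [4], prots, prots[:8], cfg, l_max=20)
        assert len(result.tried) == 2
        rs = result.tried["validation_r"].to_numpy()
        assert rs[0] == rs[1]
        assert result.best.kernel_size == 3

    def test_failing_pair_recorded_and_skipped(self):
        prots = _composition_labelled(30, 20, seed=8)
        cfg = ModelConfig(max_epochs=2, seed=8)
        # kernel 50 cannot fit l_max=20 -> recorded as failed, 3 wins
        result = grid_search([3, 50], [4], prots, prots[:8], cfg, l_max=20)
        statuses = set(result.tried["status"].str.split(":").str[0])
        assert statuses == {"ok", "failed"}
        assert result.best.kernel_size == 3

    def test_all_failures_raise(self):
        prots = _composition_labelled(10, 20, seed=9)
        cfg = ModelConfig(max_epochs=1, seed=9)
        with pytest.raises(RuntimeError, match="every candidate"):
            grid_search([50], [4], prots, prots[:4], cfg, l_max=20)
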