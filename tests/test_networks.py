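import numpy as np
import pytest

from chemrel.candidates import CandidateBatch
from chemrel.models import (ModelConfig, PretrainingNetwork,
                            RecognitionNetwork, SharedLayers, load_checkpoint,
                            save_checkpoint)
from chemrel.nn import LSTM, Tensor
from chemrel.nn import autograd as ag
from chemrel.pretrain import LengthBatch


def _shared(cfg, vocab_size=30, seed=0):
    return SharedLayers(cfg, vocab_size, np.random.default_rng(seed))


def _pretrain_batch(rng, b=2, t=5, vocab_size=30):
    ids = lambda: rng.integers(1, vocab_size, size=(b, t))
    y = lambda: rng.integers(0, 2, size=(b, t)).astype(float)
    mask = np.ones((b, t))
    return LengthBatch(i1=ids(), i2=ids(), i3=ids(), y_left=y(), y_right=y(),
                       mask_left=mask, mask_right=mask)


def _recog_batch(rng, b=3, t=6, vocab_size=30):
    return CandidateBatch(
        token_ids=rng.integers(1, vocab_size, size=(b, t)),
        context_features=rng.integers(0, 2, size=(b, t, 10)).astype(float),
        pair_features=rng.integers(0, 2, size=(b, t, 2)).astype(float),
        labels=rng.integers(0, 6, size=b),
        indices=np.arange(b))


class TestArchitectureContracts:
    def test_default_concatenation_widths(self, rng):
        """Default geometry: c1 is 600 wide (LSTM 300 + embedding 300); the
        recognition concat is the sum of its parts (300+300+48+6); pooling
        keeps the 256 bidirectional features; output is 6-way."""
        cfg = ModelConfig()
        shared = _shared(cfg)
        pre = PretrainingNetwork(cfg, shared, np.random.default_rng(1))
        _, _, _, c1 = pre.forward(_pretrain_batch(rng, b=1, t=3))
        assert c1.shape[-1] == 600
        recog = RecognitionNetwork(cfg, shared, np.random.default_rng(2))
        widths = recog.probe_widths()
        assert widths["c3"] == 300 + 300 + 48 + 6
        assert widths == {"c3": 654, "l3": 256, "p1": 256, "d5": 6}

    def test_scaled_widths(self, rng):
        cfg = ModelConfig.scaled(emb_dim=8, shared_lstm_units=8,
                                 l3_units_per_direction=4)
        pre = PretrainingNetwork(cfg, _shared(cfg), np.random.default_rng(1))
        _, _, _, c1 = pre.forward(_pretrain_batch(rng, b=1, t=3))
        assert c1.shape[-1] == 16

    def test_shared_lstm_parameter_count(self):
        lstm = LSTM(300, 300, rng=np.random.default_rng(0))
        expected = 4 * ((300 + 300) * 300 + 300)
        assert expected == 721_200
        actual = sum(p.data.size for p in lstm.params)
        assert actual == expected == lstm.n_params

    def test_softmax_outputs_normalised(self, rng):
        cfg = ModelConfig.scaled(emb_dim=6, shared_lstm_units=6,
                                 l3_units_per_direction=4)
        net = RecognitionNetwork(cfg, _shared(cfg), np.random.default_rng(1))
        scores = net.predict(_recog_batch(rng, b=8))
        assert (scores >= 0).all()
        np.testing.assert_allclose(scores.sum(axis=1), 1.0, atol=1e-6)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(emb_dim=0)


class TestSharedLayers:
    def _nets(self, seed=0):
        cfg = ModelConfig.scaled(emb_dim=6, shared_lstm_units=6,
                                 l3_units_per_direction=4)
        shared = _shared(cfg, seed=seed)
        pre = PretrainingNetwork(cfg, shared, np.random.default_rng(1))
        recog = RecognitionNetwork(cfg, shared, np.random.default_rng(2))
        return shared, pre, recog

    def test_phase1_update_visible_to_recognition(self, rng):
        """e1/l1/l2 are the same tensors in both networks, not copies."""
        shared, pre, recog = self._nets()
        recog_shared = recog.params[:len(shared.params)]
        for a, b in zip(shared.params, recog_shared):
            assert a is b
        before = [p.data.copy() for p in shared.params]
        pre.train_step(_pretrain_batch(rng), rng)
        changed = [not np.array_equal(p.data, old)
                   for p, old in zip(shared.params, before)]
        assert any(changed)
        for a, b in zip(shared.params, recog_shared):
            assert a is b  # still the identical tensor objects

    def test_embedding_init_matrix_used(self):
        cfg = ModelConfig.scaled(emb_dim=4, shared_lstm_units=4,
                                 l3_units_per_direction=2)
        init = np.arange(20.0).reshape(5, 4)
        shared = SharedLayers(cfg, 5, np.random.default_rng(0),
                              embedding_init=init)
        np.testing.assert_array_equal(shared.embedding.data, init)
        with pytest.raises(ValueError, match="shape"):
            SharedLayers(cfg, 6, np.random.default_rng(0),
                         embedding_init=init)


class TestTraining:
    def test_overfit_single_batch(self, rng):
        cfg = ModelConfig.scaled(emb_dim=8, shared_lstm_units=8,
                                 l3_units_per_direction=4)
        net = RecognitionNetwork(cfg, _shared(cfg, seed=3),
                                 np.random.default_rng(1))
        batch = _recog_batch(rng, b=4)
        losses = [net.train_step(batch, rng) for _ in range(50)]
        assert losses[-1] < losses[0]

    def test_pretrain_loss_decreases(self, rng):
        cfg = ModelConfig.scaled(emb_dim=8, shared_lstm_units=8,
                                 l3_units_per_direction=4)
        net = PretrainingNetwork(cfg, _shared(cfg, seed=3),
                                 np.random.default_rng(1))
        batch = _pretrain_batch(rng, b=4, t=7)
        losses = [net.train_step(batch, rng) for _ in range(50)]
        assert losses[-1] < losses[0]

    def test_predict_deterministic_with_dropout_off(self, rng):
        cfg = ModelConfig.scaled(emb_dim=6, shared_lstm_units=6,
                                 l3_units_per_direction=4)
        net = RecognitionNetwork(cfg, _shared(cfg), np.random.default_rng(1))
        batch = _recog_batch(rng)
        np.testing.assert_array_equal(net.predict(batch), net.predict(batch))

    def test_one_score_vector_per_instance(self, rng):
        cfg = ModelConfig.scaled(emb_dim=6, shared_lstm_units=6,
                                 l3_units_per_direction=4)
        net = RecognitionNetwork(cfg, _shared(cfg), np.random.default_rng(1))
        assert net.predict(_recog_batch(rng, b=7)).shape == (7, 6)

    def test_conv_l3_variant(self, rng):
        cfg = ModelConfig.scaled(emb_dim=6, shared_lstm_units=6,
                                 l3_units_per_direction=4, l3_conv=True)
        net = RecognitionNetwork(cfg, _shared(cfg), np.random.default_rng(1))
        assert net.probe_widths()["p1"] == 8
        batch = _recog_batch(rng, b=4)
        losses = [net.train_step(batch, rng) for _ in range(30)]
        assert losses[-1] < losses[0]

    def test_checkpoint_roundtrip(self, tmp_path, rng):
        cfg = ModelConfig.scaled(emb_dim=6, shared_lstm_units=6,
                                 l3_units_per_direction=4)
        shared = _shared(cfg)
        net = RecognitionNetwork(cfg, shared, np.random.default_rng(1))
        batch = _recog_batch(rng)
        ref = net.predict(batch)
        save_checkpoint(tmp_path / "ck.npz", shared, recog_net=net,
                        meta={"epoch": 3})
        shared2 = _shared(cfg, seed=9)
        net2 = RecognitionNetwork(cfg, shared2, np.random.default_rng(8))
        meta = load_checkpoint(tmp_path / "ck.npz", shared2, recog_net=net2)
        assert meta["epoch"] == 3
        np.testing.assert_array_equal(net2.predict(batch), ref)


class TestGradients:
    def test_recognition_gradients_match_numerical(self, rng):
        """Spot-check the autodiff graph against central differences."""
        cfg = ModelConfig.scaled(emb_dim=4, shared_lstm_units=4,
                                 l3_units_per_direction=3)
        shared = _shared(cfg, vocab_size=10, seed=5)
        net = RecognitionNetwork(cfg, shared, np.random.default_rng(6))
        batch = _recog_batch(rng, b=2, t=4, vocab_size=10)
        onehot = np.eye(6)[batch.labels]

        def loss_value():
            scores, _ = net.forward(batch)
            return float(ag.mse_loss(scores, onehot).data)

        scores, _ = net.forward(batch)
        loss = ag.mse_loss(scores, onehot)
        net.optimizer.zero_grad()
        loss.backward()
        eps = 1e-6
        for p in (shared.lstm_fwd.w, net.l3_fwd.u, net.v1.w, net.d5.w,
                  shared.embedding):
            flat = p.data.ravel()
            idx = rng.integers(0, flat.size, size=4)
            for i in idx:
                orig = flat[i]
                flat[i] = orig + eps
                up = loss_value()
                flat[i] = orig - eps
                down = loss_value()
                flat[i] = orig
                num = (up - down) / (2 * eps)
                ana = p.grad.ravel()[i]
                assert ana == pytest.approx(num, abs=1e-7, rel=1e-4)
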