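"""GRU cell contract, network architecture, training, and latent extraction."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gruclust import _nn
from gruclust.backbone import (
    BackboneConfig,
    EarlyStopping,
    GRUParams,
    RecurrentNetClassifier,
    TrainConfig,
    build_backbone,
    extract_latent,
    gru_cell_step,
    train_supervised,
)
from gruclust.preprocess import KmerVectorizer
from gruclust.seqdata import SyntheticConfig, generate_synthetic


class TestGRUCellStep:
    def test_zero_parameters_halve_the_state(self):
        params = GRUParams.zeros(3, 4)
        h_prev = np.array([1.0, -2.0, 0.5, 4.0])
        state = gru_cell_step(np.zeros(3), h_prev, params)
        assert np.allclose(state.z_t, 0.5) and np.allclose(state.r_t, 0.5)
        assert np.allclose(state.C_hat_t, 0.0)
        assert np.allclose(state.h_t, 0.5 * h_prev)

    def test_saturated_update_gate_retains_state(self):
        params = GRUParams.zeros(3, 4)
        params.b_z[:] = 1000.0
        h_prev = np.array([1.0, -2.0, 0.5, 4.0])
        state = gru_cell_step(np.array([0.3, -0.1, 2.0]), h_prev, params)
        assert np.allclose(state.h_t, h_prev, atol=1e-6)

    def test_open_update_gate_adopts_candidate(self):
        params = GRUParams.zeros(2, 2)
        params.b_z[:] = -1000.0
        params.b_C[:] = 0.7
        state = gru_cell_step(np.zeros(2), np.array([5.0, -5.0]), params)
        assert np.allclose(state.h_t, state.C_hat_t)

    def test_hand_computed_two_unit_step(self):
        # integer weights, evaluated independently with scalar arithmetic
        params = GRUParams(
            W_z=np.array([[1.0, 0.0], [0.0, 1.0]]),
            W_r=np.array([[0.0, 1.0], [1.0, 0.0]]),
            W_C=np.array([[1.0, 1.0], [0.0, 1.0]]),
            V_z=np.array([[1.0, 0.0], [1.0, 1.0]]),
            V_r=np.array([[0.0, 1.0], [0.0, 1.0]]),
            V_C=np.array([[1.0, 0.0], [0.0, 2.0]]),
            b_z=np.array([1.0, -1.0]),
            b_r=np.array([0.0, 1.0]),
            b_C=np.array([-1.0, 0.0]),
        )
        x = [1.0, 2.0]
        h = [0.5, -1.0]

        def sig(v):
            return 1.0 / (1.0 + math.exp(-v))

        z = [sig(1 * 1 + 0.5 * 1 + (-1.0) * 1 + 1.0), sig(2 * 1 + 0.5 * 0 + (-1) * 1 - 1.0)]
        r = [sig(2 * 1 + 0.0), sig(1 * 1 + 0.5 * 1 + (-1) * 1 + 1.0)]
        rh = [r[0] * 0.5, r[1] * (-1.0)]
        c = [math.tanh(1.0 + rh[0] * 1 + rh[1] * 0 - 1.0), math.tanh(1 + 2 + rh[1] * 2 + 0.0)]
        expected = [z[0] * 0.5 + (1 - z[0]) * c[0], z[1] * (-1.0) + (1 - z[1]) * c[1]]

        state = gru_cell_step(np.array(x), np.array(h), params)
        assert np.allclose(state.z_t, z, atol=1e-10)
        assert np.allclose(state.r_t, r, atol=1e-10)
        assert np.allclose(state.C_hat_t, c, atol=1e-10)
        assert np.allclose(state.h_t, expected, atol=1e-10)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_convexity_identity(self, seed):
        rng = np.random.default_rng(seed)
        d, h = 3, 4
        params = GRUParams(
            W_z=rng.normal(size=(d, h)), W_r=rng.normal(size=(d, h)),
            W_C=rng.normal(size=(d, h)), V_z=rng.normal(size=(h, h)),
            V_r=rng.normal(size=(h, h)), V_C=rng.normal(size=(h, h)),
            b_z=rng.normal(size=h), b_r=rng.normal(size=h), b_C=rng.normal(size=h),
        )
        state = gru_cell_step(rng.normal(size=d), rng.normal(size=h), params)
        assert np.all(state.z_t > 0) and np.all(state.z_t < 1)
        assert np.all(state.r_t > 0) and np.all(state.r_t < 1)
        assert np.all(np.abs(state.C_hat_t) < 1)
        lo = np.minimum(state.h_prev, state.C_hat_t)
        hi = np.maximum(state.h_prev, state.C_hat_t)
        assert np.all(state.h_t >= lo - 1e-12) and np.all(state.h_t <= hi + 1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            gru_cell_step(np.zeros(5), np.zeros(4), GRUParams.zeros(3, 4))

    def test_matches_vectorized_gru_layer(self):
        """The batched BPTT layer computes the same recurrence as the cell."""
        rng = np.random.default_rng(0)
        layer = _nn.GRU(rng, in_dim=3, units=4, dtype=np.float64)
        W, V2, Vc, b = layer.weights
        params = GRUParams(
            W_z=W[:, :4], W_r=W[:, 4:8], W_C=W[:, 8:],
            V_z=V2[:, :4], V_r=V2[:, 4:], V_C=Vc,
            b_z=b[:4], b_r=b[4:8], b_C=b[8:],
        )
        X = rng.normal(size=(1, 5, 3))
        h_layer = layer.forward(X, np.ones((1, 5)))
        h = np.zeros(4)
        for t in range(5):
            h = gru_cell_step(X[0, t], h, params).h_t
        assert np.allclose(h_layer[0], h, atol=1e-12)


class TestArchitecture:
    def test_default_layer_widths(self):
        cfg = BackboneConfig(vocab_size=16)
        assert cfg.feature_widths == (200, 128, 64, 32, 16)
        assert cfg.latent_dim == 32
        net = build_backbone(cfg, seed=0)
        assert net.recurrent.units == 200
        assert [d.weights[0].shape[1] for d, _ in net.dense_blocks] == [128, 64, 32, 16]
        assert net.head.weights[0].shape == (16, 1)

    def test_outputs_strictly_between_zero_and_one(self):
        net = build_backbone(BackboneConfig(vocab_size=10, gru_units=8,
                                            dense_units=(6, 4),
                                            latent_layer_index=2), seed=0)
        rng = np.random.default_rng(1)
        tokens = rng.integers(1, 11, size=(20, 12)).astype(np.int32)
        proba = net.predict_proba(tokens, np.full(20, 12))
        assert np.all(proba > 0) and np.all(proba < 1)

    def test_parameter_count_closed_form(self):
        V, D, H = 10, 5, 7
        dense = (6, 4)
        cfg = BackboneConfig(vocab_size=V, embedding_dim=D, gru_units=H,
                             dense_units=dense, latent_layer_index=2)
        net = build_backbone(cfg, seed=0)
        expected = (V + 1) * D                      # embedding (id 0 included)
        expected += 3 * (D * H + H * H + H)         # GRU gates
        widths = (H,) + dense + (1,)
        for a, b in zip(widths, widths[1:]):
            expected += a * b + b                   # dense + head
        assert net.n_params() == expected

    def test_invalid_latent_index_rejected(self):
        with pytest.raises(ValueError, match="latent"):
            BackboneConfig(vocab_size=4, dense_units=(8,), latent_layer_index=5)

    @pytest.mark.parametrize("kind", ["gru", "bigru", "lstm", "bilstm"])
    def test_variants_share_the_contract(self, kind):
        rng = np.random.default_rng(0)
        tokens = rng.integers(1, 9, size=(30, 10)).astype(np.int32)
        y = rng.integers(0, 2, size=30)
        clf = RecurrentNetClassifier(
            gru_units=6, dense_units=(5, 3), embedding_dim=4, latent_layer_index=2,
            backbone_kind=kind, epochs=2, early_stopping_patience=1, batch_size=8,
            random_state=0,
        ).fit(tokens, y)
        assert set(np.unique(clf.predict(tokens))) <= {0, 1}
        assert clf.transform(tokens).shape == (30, 5)


class TestGradients:
    @pytest.mark.parametrize("kind", ["gru", "lstm", "bilstm"])
    def test_backprop_matches_numerical_gradient(self, kind):
        cfg = BackboneConfig(vocab_size=6, embedding_dim=3, gru_units=4,
                             dense_units=(5, 3), dropout_rate=0.0,
                             latent_layer_index=2, backbone_kind=kind)
        net = build_backbone(cfg, seed=0, dtype=np.float64)
        rng = np.random.default_rng(1)
        tokens = rng.integers(1, 7, size=(4, 6)).astype(np.int32)
        lengths = np.array([6, 4, 6, 3])
        for i, L in enumerate(lengths):
            tokens[i, L:] = 0
        y = rng.integers(0, 2, size=4).astype(float)
        loss, dl = _nn.bce_with_logits(net.forward(tokens, lengths, train=True), y)
        net.zero_grad()
        net.backward(dl)
        for w, g in zip(net.weights, net.grads):
            flat, gflat = w.reshape(-1), g.reshape(-1)
            for j in rng.choice(flat.size, size=min(8, flat.size), replace=False):
                eps, old = 1e-6, flat[j]
                flat[j] = old + eps
                lp, _ = _nn.bce_with_logits(net.forward(tokens, lengths, train=True), y)
                flat[j] = old - eps
                lm, _ = _nn.bce_with_logits(net.forward(tokens, lengths, train=True), y)
                flat[j] = old
                assert (lp - lm) / (2 * eps) == pytest.approx(gflat[j], abs=1e-8)


class TestTraining:
    def _tiny_dataset(self, seed, n=60):
        records = generate_synthetic(SyntheticConfig(n_per_class=n // 2, seq_length=30,
                                                     seed=seed))
        vec = KmerVectorizer(unknown="zero").fit([r.sequence for r in records])
        return vec.encode(records)

    def test_one_epoch_reduces_loss_in_most_seeded_runs(self):
        wins = 0
        for seed in range(10):
            data = self._tiny_dataset(seed)
            cfg = BackboneConfig(vocab_size=len(data.vocab), embedding_dim=8,
                                 gru_units=8, dense_units=(8, 4), dropout_rate=0.0,
                                 latent_layer_index=2)
            net = build_backbone(cfg, seed=seed)
            y = data.labels.astype(float)
            initial, _ = _nn.bce_with_logits(
                net.forward(data.tokens, data.lengths, train=False), y
            )
            train_supervised(
                net, data, data,
                TrainConfig(epochs=2, early_stopping_patience=1, batch_size=16,
                            seed=seed),
            )
            final, _ = _nn.bce_with_logits(
                net.forward(data.tokens, data.lengths, train=False), y
            )
            wins += final < initial
        assert wins >= 9

    def test_learns_separable_data(self):
        """The default backbone fits the default motif-planted classes to
        >= 0.95 training accuracy within 20 epochs."""
        records = generate_synthetic(SyntheticConfig(seed=0))
        vec = KmerVectorizer(unknown="zero").fit([r.sequence for r in records])
        data = vec.encode(records)
        clf = RecurrentNetClassifier(
            epochs=20, early_stopping_patience=19, batch_size=64, random_state=0,
        ).fit(data)
        train_acc = float(np.mean(clf.predict(data.tokens) == data.labels))
        assert train_acc >= 0.95

    def test_unlabelled_input_rejected(self):
        data = self._tiny_dataset(0)
        object.__setattr__(data, "labels", None)
        cfg = BackboneConfig(vocab_size=16, gru_units=4, dense_units=(4,),
                             latent_layer_index=1)
        net = build_backbone(cfg, seed=0)
        with pytest.raises(ValueError, match="unlabelled"):
            train_supervised(net, data, data, TrainConfig(epochs=2,
                                                          early_stopping_patience=1))

    def test_history_columns_and_length(self):
        data = self._tiny_dataset(1, n=40)
        clf = RecurrentNetClassifier(gru_units=4, dense_units=(4,), embedding_dim=4,
                                     latent_layer_index=1, epochs=3,
                                     early_stopping_patience=2, batch_size=16,
                                     random_state=0).fit(data)
        h = clf.history_
        assert list(h.columns) == ["epoch", "loss", "accuracy", "val_loss", "val_accuracy"]
        assert len(h) <= 3


class TestEarlyStopping:
    def test_constant_monitor_stops_patience_after_best(self):
        es = EarlyStopping(patience=3, mode="min")
        stopped_at = None
        for epoch in range(1, 50):
            es.update(0.7, epoch)
            if es.should_stop:
                stopped_at = epoch
                break
        assert es.best_epoch == 1
        assert stopped_at == 1 + 3

    def test_improvement_resets_patience(self):
        es = EarlyStopping(patience=2, mode="min")
        for epoch, value in enumerate([1.0, 0.9, 0.95, 0.8, 0.85, 0.85], start=1):
            es.update(value, epoch)
            assert not es.should_stop or epoch == 6
        assert es.best_epoch == 4

    def test_max_mode(self):
        es = EarlyStopping(patience=1, mode="max")
        assert es.update(0.5, 1)
        assert es.update(0.6, 2)
        assert not es.update(0.55, 3)
        assert es.should_stop


class TestLatentExtraction:
    @pytest.fixture(scope="class")
    def fitted(self):
        records = generate_synthetic(SyntheticConfig(n_per_class=40, seq_length=40, seed=3))
        vec = KmerVectorizer(unknown="zero").fit([r.sequence for r in records])
        data = vec.encode(records)
        clf = RecurrentNetClassifier(epochs=2, early_stopping_patience=1, batch_size=16,
                                     random_state=0).fit(data)
        return clf, data

    def test_default_latent_width_is_32(self, fitted):
        clf, data = fitted
        latent = clf.transform(data.tokens[:10])
        assert latent.shape == (10, 32)

    def test_duplicate_rows_identical_latents(self, fitted):
        clf, data = fitted
        doubled = np.vstack([data.tokens[:1], data.tokens[:1]])
        latent = clf.transform(doubled)
        assert np.array_equal(latent[0], latent[1])

    def test_two_calls_bitwise_equal(self, fitted):
        clf, data = fitted
        a = clf.transform(data.tokens[:20])
        b = clf.transform(data.tokens[:20])
        assert np.array_equal(a, b)

    def test_extract_latent_function(self, fitted):
        clf, data = fitted
        latent = extract_latent(clf.network_, data, layer_index=4)
        assert latent.shape == (len(data), 32)

    def test_save_load_roundtrip(self, fitted, tmp_path):
        clf, data = fitted
        clf.save(tmp_path / "ckpt")
        back = RecurrentNetClassifier.load(tmp_path / "ckpt")
        assert np.array_equal(back.predict(data.tokens), clf.predict(data.tokens))
        assert np.array_equal(back.transform(data.tokens), clf.transform(data.tokens))
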