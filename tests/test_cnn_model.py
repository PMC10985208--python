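import numpy as np
import pytest

from mircnn.cnn_model import (
    CNNConfig,
    build_model,
    conv_forward,
    fit_model,
    layer_shapes,
    load_checkpoint,
    maxpool_forward,
    oversample_indices,
    predict,
    save_checkpoint,
    train,
)
from mircnn.encoding import EncodedMatrix


def naive_conv(x, kernels, activation="relu"):
    """Quadruple-loop convolution oracle (valid, stride 1) + ReLU."""
    F, C, kh, kw = kernels.shape
    _, H, W = x.shape
    out = np.zeros((F, H - kh + 1, W - kw + 1))
    for f in range(F):
        for i in range(H - kh + 1):
            for j in range(W - kw + 1):
                s = 0.0
                for c in range(C):
                    for p in range(kh):
                        for q in range(kw):
                            s += kernels[f, c, p, q] * x[c, i + p, j + q]
                out[f, i, j] = max(0.0, s) if activation == "relu" else s
    return out


def naive_pool(x, ph=2, pw=2):
    C, H, W = x.shape
    out = np.zeros((C, H // ph, W // pw))
    for c in range(C):
        for i in range(H // ph):
            for j in range(W // pw):
                out[c, i, j] = x[c, i * ph : i * ph + ph, j * pw : j * pw + pw].max()
    return out


class TestConvForward:
    def test_matches_naive_oracle(self, rng):
        for _ in range(25):
            C, H, W = (int(v) for v in rng.integers(1, 6, 3))
            kh = int(rng.integers(1, H + 1))
            kw = int(rng.integers(1, W + 1))
            F = int(rng.integers(1, 5))
            x = rng.normal(size=(C, H, W))
            k = rng.normal(size=(F, C, kh, kw))
            assert np.max(np.abs(conv_forward(x, k) - naive_conv(x, k))) < 1e-6

    def test_hand_convolution(self):
        x = np.ones((1, 3, 3))
        k = np.ones((1, 1, 2, 2))
        assert np.allclose(conv_forward(x, k), 4.0)
        assert conv_forward(x, k).shape == (1, 2, 2)

    def test_zero_input_zero_output(self):
        out = conv_forward(np.zeros((1, 7, 200)), np.ones((20, 1, 2, 2)))
        assert out.shape == (20, 6, 199)
        assert np.allclose(out, 0.0)

    def test_kernel_larger_than_input_raises(self):
        with pytest.raises(ValueError):
            conv_forward(np.ones((1, 2, 2)), np.ones((1, 1, 3, 3)))


class TestMaxPool:
    def test_matches_naive_oracle(self, rng):
        for _ in range(25):
            C, H, W = (int(v) for v in rng.integers(1, 7, 3))
            x = rng.normal(size=(C, max(2, H), max(2, W)))
            assert np.allclose(maxpool_forward(x), naive_pool(x))

    def test_odd_trailing_dropped(self):
        x = np.arange(20 * 6 * 199, dtype=float).reshape(20, 6, 199)
        assert maxpool_forward(x).shape == (20, 3, 99)

    def test_constant_input(self):
        assert np.allclose(maxpool_forward(np.full((3, 4, 4), 2.5)), 2.5)

    def test_window_maximum(self):
        x = np.array([[[0.1, 0.9], [-0.5, 0.3]]])
        assert maxpool_forward(x)[0, 0, 0] == 0.9


class TestArchitecture:
    def test_shape_chain_for_200_wide_input(self):
        chain = layer_shapes(CNNConfig(), (1, 7, 200))
        assert chain["input"] == (1, 7, 200)
        assert chain["conv1"] == (20, 6, 199)
        assert chain["pool1"] == (20, 3, 99)
        assert chain["conv2"] == (60, 2, 98)
        assert chain["pool2"] == (60, 1, 49)
        assert chain["flatten"] == 2940
        assert chain["fc1"] == 500
        assert chain["output"] == 2

    def test_degenerate_chain_raises_with_trace(self):
        with pytest.raises(ValueError, match="chain"):
            layer_shapes(CNNConfig(), (1, 2, 3))

    def test_softmax_outputs_sum_to_one(self, rng):
        model = build_model(CNNConfig(conv1_filters=4, conv2_filters=6, fc_units=10),
                            (1, 7, 40), seed=0)
        X = rng.normal(size=(64, 1, 7, 40)).astype(np.float32)
        probs, _ = model.forward(X)
        assert np.max(np.abs(probs.sum(axis=1) - 1.0)) < 1e-6

    def test_dropout_retain_one_matches_eval_forward(self, rng):
        cfg = CNNConfig(conv1_filters=4, conv2_filters=6, fc_units=10, dropout_retain=1.0)
        model = build_model(cfg, (1, 7, 40), seed=0)
        X = rng.normal(size=(8, 1, 7, 40)).astype(np.float32)
        p_train, _ = model.forward(X, train=True, rng=np.random.default_rng(0))
        p_eval, _ = model.forward(X, train=False)
        assert np.array_equal(p_train, p_eval)

    def test_invalid_dropout_raises(self):
        with pytest.raises(ValueError):
            CNNConfig(dropout_retain=0.0)

    def test_same_seed_identical_weights(self):
        a = build_model(seed=42)
        b = build_model(seed=42)
        assert all(np.array_equal(a.params[k], b.params[k]) for k in a.params)

    def test_checkpoint_roundtrip(self, tmp_path, rng):
        cfg = CNNConfig(conv1_filters=3, conv2_filters=4, fc_units=8)
        model = build_model(cfg, (1, 7, 30), seed=5)
        path = tmp_path / "model.npz"
        save_checkpoint(model, path)
        again = load_checkpoint(path)
        X = rng.normal(size=(4, 1, 7, 30)).astype(np.float32)
        assert np.array_equal(model.forward(X)[0], again.forward(X)[0])


def _toy_matrices(rng, n=60, L=40):
    """Linearly separable toy set: the positive class carries a strong
    coverage block in the last row."""
    mats = []
    for i in range(n):
        label = i % 2
        v = (rng.random((7, L)) * 0.2).astype(np.float32)
        if label:
            v[6, 10:30] = 1.0
        mats.append(EncodedMatrix(values=v, label=label, candidate_id=f"m{i}"))
    return mats


class TestTraining:
    def test_loss_trend_decreases_on_memorization_set(self, rng):
        mats = _toy_matrices(rng, n=50)
        cfg = CNNConfig(conv1_filters=6, conv2_filters=8, fc_units=20, epochs=30,
                        batch_size=10, L=40)
        model = build_model(cfg, (1, 7, 40), seed=1)
        X = np.stack([m.values for m in mats])[:, None]
        y = np.array([m.label for m in mats])
        fit_model(model, X, y, np.random.default_rng(1))
        log = model.training_log
        assert len(log) == 30
        assert np.mean(log[20:]) < np.mean(log[:10])

    def test_oversampling_balances_exactly(self, rng):
        y = np.array([0] * 750 + [1] * 250)
        idx = oversample_indices(y, rng)
        yb = y[idx]
        assert (yb == 0).sum() == 750 and (yb == 1).sum() == 750
        # majority items appear exactly once
        assert np.array_equal(np.sort(idx[: len(y)]), np.arange(len(y)))
        assert set(idx[len(y):]) <= set(np.flatnonzero(y == 1))

    def test_oversampling_balanced_input_unchanged(self, rng):
        y = np.array([0, 1] * 10)
        assert np.array_equal(oversample_indices(y, rng), np.arange(20))

    def test_oversampling_single_class_raises(self, rng):
        with pytest.raises(ValueError):
            oversample_indices(np.zeros(10, dtype=int), rng)

    def test_cross_validation_protocol(self, rng):
        mats = _toy_matrices(rng, n=100)
        cfg = CNNConfig(conv1_filters=4, conv2_filters=6, fc_units=12, epochs=12, L=40)
        cv = train(mats, config=cfg, folds=5, seed=3)
        # each sample in exactly one test fold
        all_test = np.concatenate(cv.fold_test_indices)
        assert np.array_equal(np.sort(all_test), np.arange(100))
        assert all(len(te) == 20 for te in cv.fold_test_indices)
        # separable toy set is learned well
        assert cv.mean.accuracy > 0.9

    def test_train_rejects_single_class(self, rng):
        mats = _toy_matrices(rng, n=10)
        for mat in mats:
            mat.label = 0
        with pytest.raises(ValueError):
            train(mats, folds=2, seed=0)

    def test_train_rejects_bad_folds(self, rng):
        with pytest.raises(ValueError):
            train(_toy_matrices(rng, n=10), folds=1, seed=0)


class TestPredict:
    def test_probabilities_complementary(self, rng):
        model = build_model(CNNConfig(conv1_filters=3, conv2_filters=4, fc_units=8),
                            (1, 7, 30), seed=2)
        mat = EncodedMatrix(values=rng.random((7, 30)).astype(np.float32))
        p, cls = predict(model, mat)
        assert 0.0 <= p <= 1.0
        assert cls in (0, 1)

    def test_exact_tie_goes_to_positive_class(self):
        model = build_model(CNNConfig(conv1_filters=3, conv2_filters=4, fc_units=8),
                            (1, 7, 30), seed=2)
        for k in model.params:  # zero weights -> logits (0, 0) -> p = 0.5
            model.params[k][:] = 0.0
        p, cls = predict(model, EncodedMatrix(values=np.ones((7, 30), dtype=np.float32)))
        assert p == 0.5
        assert cls == 1

    def test_shape_mismatch_raises(self, rng):
        model = build_model(CNNConfig(conv1_filters=3, conv2_filters=4, fc_units=8),
                            (1, 7, 30), seed=2)
        with pytest.raises(ValueError):
            predict(model, EncodedMatrix(values=rng.random((7, 31)).astype(np.float32)))
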