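"""CNN engine: convolution/pooling against brute-force oracles, architecture
auditing, training behaviour and prediction semantics."""

import numpy as np
import pytest

from nirmeat import nn


def conv_oracle(x, weights, offsets):
    """Nested-loop same-padded stride-1 convolution (NHWC)."""
    n, h, w, c_in = x.shape
    k = weights.shape[0]
    p = k // 2
    c_out = weights.shape[3]
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
    out = np.zeros((n, h, w, c_out))
    for b in range(n):
        for i in range(h):
            for j in range(w):
                for f in range(c_out):
                    acc = 0.0
                    for di in range(k):
                        for dj in range(k):
                            for c in range(c_in):
                                acc += xp[b, i + di, j + dj, c] * weights[di, dj, c, f]
                    out[b, i, j, f] = acc + offsets[f]
    return out


def pool_oracle(x, size=2):
    n, h, w, c = x.shape
    ho, wo = h // size, w // size
    out = np.zeros((n, ho, wo, c))
    for b in range(n):
        for i in range(ho):
            for j in range(wo):
                for ch in range(c):
                    block = x[b, i * size:(i + 1) * size,
                              j * size:(j + 1) * size, ch]
                    out[b, i, j, ch] = block.max()
    return out


class TestConvolution:
    def test_identity_kernel_preserves_input(self, rng):
        x = rng.random((2, 5, 5, 1))
        w = np.ones((1, 1, 1, 1))
        np.testing.assert_allclose(nn.conv2d_same(x, w, np.zeros(1)), x)

    def test_zero_input_yields_constant_offset(self):
        x = np.zeros((1, 4, 4, 2))
        w = np.ones((3, 3, 2, 3))
        out = nn.conv2d_same(x, w, np.array([1.0, -2.0, 0.5]))
        np.testing.assert_allclose(out[..., 0], 1.0)
        np.testing.assert_allclose(out[..., 1], -2.0)
        np.testing.assert_allclose(out[..., 2], 0.5)

    @pytest.mark.parametrize("k", [1, 3, 5, 7])
    def test_matches_nested_loop_oracle(self, k, rng):
        for _ in range(10):
            c_in, c_out = int(rng.integers(1, 4)), int(rng.integers(1, 4))
            h = int(rng.integers(k, k + 4))
            x = rng.normal(size=(2, h, h, c_in))
            w = rng.normal(size=(k, k, c_in, c_out))
            b = rng.normal(size=c_out)
            np.testing.assert_allclose(nn.conv2d_same(x, w, b),
                                       conv_oracle(x, w, b), atol=1e-10)

    def test_channel_mismatch_rejected(self, rng):
        x = rng.random((1, 4, 4, 2))
        w = rng.random((3, 3, 3, 4))
        with pytest.raises(ValueError, match="channels"):
            nn.conv2d_same(x, w, np.zeros(4))

    def test_even_kernel_rejected(self, rng):
        x = rng.random((1, 4, 4, 1))
        with pytest.raises(ValueError, match="odd"):
            nn.conv2d_same(x, rng.random((2, 2, 1, 1)), np.zeros(1))


class TestActivationAndPooling:
    def test_relu_branches_and_idempotence(self):
        x = np.array([-2.0, 0.0, 3.5])
        np.testing.assert_array_equal(nn.relu(x), [0.0, 0.0, 3.5])
        np.testing.assert_array_equal(nn.relu(nn.relu(x)), nn.relu(x))

    def test_single_block_max(self):
        x = np.array([[1.0, 2.0], [3.0, 4.0]]).reshape(1, 2, 2, 1)
        np.testing.assert_allclose(nn.max_pool(x), [[[[4.0]]]])

    def test_constant_map_halved(self):
        x = np.full((1, 6, 6, 2), 1.5)
        out = nn.max_pool(x)
        assert out.shape == (1, 3, 3, 2)
        np.testing.assert_allclose(out, 1.5)

    def test_matches_blockwise_oracle(self, rng):
        for _ in range(30):
            h = int(rng.integers(2, 10))
            w = int(rng.integers(2, 10))
            x = rng.normal(size=(2, h, w, 3))
            np.testing.assert_allclose(nn.max_pool(x), pool_oracle(x))


class TestArchitecture:
    def test_flattened_size_after_three_pools(self):
        spec = nn.CNNSpec(input_size=230)
        assert spec.flattened_size == 64 * 28 * 28
        spec64 = nn.CNNSpec(input_size=64)
        assert spec64.flattened_size == 64 * 8 * 8

    def test_layer_graph_audit(self):
        net = nn.build(nn.CNNSpec(input_size=32, kernel_size=3))
        names = net.layer_summary()
        assert names.count("Conv") == 3
        assert names.count("MaxPool") == 3
        assert names.count("Dense") == 2
        assert names.count("Dropout") == 2
        assert names[-1] == "Dense"

    def test_same_seed_same_initial_weights(self):
        spec = nn.CNNSpec(input_size=32, kernel_size=3, seed=9)
        a, b = nn.build(spec), nn.build(spec)
        for wa, wb in zip(a.get_weights(), b.get_weights()):
            np.testing.assert_array_equal(wa, wb)

    def test_two_conv_layers_rejected(self):
        with pytest.raises(ValueError, match="three convolution"):
            nn.CNNSpec(input_size=32, filter_counts=(8, 16))

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            nn.CNNSpec(input_size=32, kernel_size=4)

    def test_bad_dropout_rejected(self):
        with pytest.raises(ValueError, match="dropout"):
            nn.CNNSpec(input_size=32, dropout_rate=1.0)


def _toy_problem(n_per_class=8, side=16, seed=0):
    """Five well-separated rank-1 matrix classes (bumps at distinct sites)."""
    rng = np.random.default_rng(seed)
    t = np.arange(side)
    mats, labels = [], []
    for c in range(5):
        base = 0.2 + 0.75 * np.exp(-0.5 * ((t - (2 + 3 * c)) / 2.0) ** 2)
        for _ in range(n_per_class):
            x = np.clip(base + rng.normal(0, 0.01, side), 0, 1)
            mats.append(np.outer(x, x))
            labels.append(c)
    return np.asarray(mats), np.asarray(labels)


class TestTraining:
    def test_zero_epochs_leaves_model_unchanged(self):
        mats, labels = _toy_problem(2)
        spec = nn.CNNSpec(input_size=16, kernel_size=3, seed=1)
        net = nn.build(spec)
        before = [w.copy() for w in net.get_weights()]
        net.train(mats, nn.one_hot(labels), epochs=0)
        for wa, wb in zip(before, net.get_weights()):
            np.testing.assert_array_equal(wa, wb)
        assert net.history["loss"] == []

    def test_loss_decreases_on_learnable_set(self):
        mats, labels = _toy_problem(6)
        spec = nn.CNNSpec(input_size=16, kernel_size=3,
                          filter_counts=(4, 8, 8), fc_hidden=32, seed=0)
        net = nn.build(spec).train(mats, nn.one_hot(labels), epochs=15,
                                   batch_size=16)
        assert net.history["loss"][-1] < net.history["loss"][0]
        assert len(net.history["loss"]) == 15

    def test_training_is_seed_deterministic(self):
        mats, labels = _toy_problem(3)
        spec = nn.CNNSpec(input_size=16, kernel_size=3,
                          filter_counts=(2, 4, 4), fc_hidden=16, seed=3)
        a = nn.build(spec).train(mats, nn.one_hot(labels), epochs=3,
                                 batch_size=8)
        b = nn.build(spec).train(mats, nn.one_hot(labels), epochs=3,
                                 batch_size=8)
        for wa, wb in zip(a.get_weights(), b.get_weights()):
            np.testing.assert_array_equal(wa, wb)

    def test_missing_class_warns(self):
        mats, labels = _toy_problem(2)
        keep = labels != 4
        spec = nn.CNNSpec(input_size=16, kernel_size=3,
                          filter_counts=(2, 4, 4), fc_hidden=8, seed=0)
        with pytest.warns(UserWarning, match="absent"):
            nn.build(spec).train(mats[keep], nn.one_hot(labels[keep]),
                                 epochs=1)

    def test_full_pipeline_learns_separable_classes(self):
        # learnability smoke test: noiseless, well-separated classes
        mats, labels = _toy_problem(6)
        spec = nn.CNNSpec(input_size=16, kernel_size=3,
                          filter_counts=(4, 8, 8), fc_hidden=32,
                          dropout_rate=0.0, seed=0)
        net = nn.build(spec).train(mats, nn.one_hot(labels), epochs=60,
                                   batch_size=16)
        pred, _ = net.predict_softmax(mats)
        assert (pred == labels).mean() == 1.0


class TestInference:
    @pytest.fixture(scope="class")
    def trained(self):
        mats, labels = _toy_problem(3)
        spec = nn.CNNSpec(input_size=16, kernel_size=3,
                          filter_counts=(2, 4, 4), fc_hidden=16, seed=0)
        return nn.build(spec).train(mats, nn.one_hot(labels), epochs=2), mats

    def test_softmax_scores_normalised(self, trained):
        net, mats = trained
        _, scores = net.predict_softmax(mats)
        np.testing.assert_allclose(scores.sum(axis=1), 1.0, atol=1e-6)

    def test_softmax_closed_form_cases(self):
        s = nn.softmax(np.array([[10.0, 0, 0, 0, 0]]))
        assert s[0, 0] > 0.99
        np.testing.assert_allclose(nn.softmax(np.zeros((1, 5))), 0.2)

    def test_feature_width_and_determinism(self, trained):
        net, mats = trained
        f = net.extract_features(mats[:4])
        assert f.shape == (4, 16)
        np.testing.assert_array_equal(f, net.extract_features(mats[:4]))

    def test_identical_inputs_identical_features(self, trained):
        net, mats = trained
        f = net.extract_features(np.repeat(mats[:1], 3, axis=0))
        np.testing.assert_array_equal(f[0], f[1])
        np.testing.assert_array_equal(f[0], f[2])

    def test_features_permute_with_batch(self, trained):
        net, mats = trained
        perm = np.array([3, 0, 2, 1])
        f = net.extract_features(mats[:4])
        fp = net.extract_features(mats[:4][perm])
        np.testing.assert_allclose(fp, f[perm], atol=1e-12)
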