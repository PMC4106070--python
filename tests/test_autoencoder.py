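import math

import numpy as np
import pytest

from rsae.autoencoder import (
    AEConfig, AEParams, StackedNet, autoencoder_cost, correntropy_estimate,
    cost_gradient, decode, encode, extract_features, fine_tune,
    finetune_objective, gaussian_kernel, load_model, mcc_loss, mse_loss,
    pretrain_stack, predict, rsae_cost, save_model, softmax_predict_proba,
    sparsity_penalty, ssae_cost, train_autoencoder, train_softmax,
    weight_decay, _net_flatten, _net_unflatten,
)

KAPPA0 = 1.0 / (math.sqrt(2.0 * math.pi) * 0.05)  # kernel peak at sigma=0.05


def random_params(d, h, seed=0, scale=0.5):
    rng = np.random.default_rng(seed)
    return AEParams(W1=scale * rng.standard_normal((h, d)), b1=scale * rng.standard_normal(h),
                    W2=scale * rng.standard_normal((d, h)), b2=scale * rng.standard_normal(d))


class TestEncodeDecode:
    def test_zero_params_give_half(self):
        p = AEParams(W1=np.zeros((3, 4)), b1=np.zeros(3), W2=np.zeros((4, 3)), b2=np.zeros(4))
        np.testing.assert_allclose(encode(np.ones(4), p), 0.5)
        np.testing.assert_allclose(decode(np.ones(3), p), 0.5)

    def test_scalar_identity_case(self):
        p = AEParams(W1=np.array([[1.0]]), b1=np.zeros(1), W2=np.array([[1.0]]), b2=np.zeros(1))
        assert encode(np.array([0.0]), p)[0] == pytest.approx(0.5)

    def test_outputs_strictly_inside_unit_interval(self, rng):
        p = random_params(6, 3, scale=5.0)
        h = encode(rng.uniform(0, 1, size=(20, 6)), p)
        y = decode(h, p)
        assert np.all((h > 0) & (h < 1)) and np.all((y > 0) & (y < 1))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            AEParams(W1=np.zeros((3, 4)), b1=np.zeros(3), W2=np.zeros((3, 4)), b2=np.zeros(4))


class TestLossOracles:
    """Each cost term against an independent brute-force recomputation."""

    def test_mse_examples(self):
        assert mse_loss(np.array([[0.0]]), np.array([[1.0]])) == pytest.approx(0.5)
        X = np.array([[0.0], [0.0]])
        Y = np.array([[1.0], [0.0]])
        assert mse_loss(X, Y) == pytest.approx(0.25)
        assert mse_loss(Y, Y) == 0.0

    def test_mse_brute_force(self, rng):
        for _ in range(20):
            X = rng.uniform(0, 1, size=(5, 7))
            Y = rng.uniform(0, 1, size=(5, 7))
            brute = sum(0.5 * sum((Y[i, j] - X[i, j]) ** 2 for j in range(7))
                        for i in range(5)) / 5
            assert mse_loss(X, Y) == pytest.approx(brute, rel=1e-12)

    def test_kernel_closed_forms(self):
        assert gaussian_kernel(0.0, 0.05) == pytest.approx(7.9788456, rel=1e-6)
        assert gaussian_kernel(3 * 0.05, 0.05) / gaussian_kernel(0.0, 0.05) == \
            pytest.approx(math.exp(-4.5), rel=1e-12)
        u = 0.123
        assert gaussian_kernel(u, 0.05) == gaussian_kernel(-u, 0.05)

    def test_correntropy_brute_force_and_peak(self, rng):
        x = rng.uniform(0, 1, 30)
        assert correntropy_estimate(x, x, 0.05) == pytest.approx(KAPPA0)
        y = x + rng.normal(0, 0.02, 30)
        brute = np.mean([gaussian_kernel(xi - yi, 0.05) for xi, yi in zip(x, y)])
        assert correntropy_estimate(x, y, 0.05) == pytest.approx(brute, rel=1e-12)

    def test_correntropy_outlier_contributes_nothing(self):
        x = np.zeros(10)
        y = np.zeros(10)
        y[0] = 100 * 0.05  # one 100-sigma outlier
        v_clean = correntropy_estimate(x, x, 0.05)
        v = correntropy_estimate(x, y, 0.05)
        assert v_clean - v == pytest.approx(KAPPA0 / 10, rel=1e-9)
        assert gaussian_kernel(100 * 0.05, 0.05) < 1e-10 * KAPPA0

    def test_mcc_perfect_reconstruction_peak(self):
        X = np.random.default_rng(0).uniform(0, 1, size=(3, 784))
        assert mcc_loss(X, X, 0.05) == pytest.approx(784 * KAPPA0, rel=1e-9)
        assert 784 * KAPPA0 == pytest.approx(6255.4, rel=1e-4)

    def test_mcc_single_huge_error_bounded_influence(self):
        X = np.random.default_rng(1).uniform(0, 1, size=(4, 10))
        Y = X.copy()
        Y[2, 5] = 1e6
        drop = mcc_loss(X, X, 0.05) - mcc_loss(X, Y, 0.05)
        assert 0 < drop <= KAPPA0 / 4 + 1e-12

    def test_mcc_brute_force(self, rng):
        X = rng.uniform(0, 1, size=(3, 4))
        Y = rng.uniform(0, 1, size=(3, 4))
        brute = sum(sum(gaussian_kernel(X[i, j] - Y[i, j], 0.05) for j in range(4))
                    for i in range(3)) / 3
        assert mcc_loss(X, Y, 0.05) == pytest.approx(brute, rel=1e-12)

    def test_sparsity_at_target_zero_and_positive_otherwise(self):
        H = np.full((10, 4), 0.1)
        assert sparsity_penalty(H, 0.1, 3.0) == pytest.approx(0.0, abs=1e-12)
        H2 = np.full((10, 1), 0.2)
        assert sparsity_penalty(H2, 0.1, 3.0) == pytest.approx(0.1100700, rel=1e-5)
        H3 = np.full((10, 4), 0.11)
        assert sparsity_penalty(H3, 0.1, 3.0) > 0

    def test_weight_decay_examples(self, rng):
        assert weight_decay(np.zeros((2, 2)), np.zeros((2, 2)), 0.003) == 0.0
        assert weight_decay(np.array([[1.0, 2.0]]), np.array([[2.0], [1.0]]), 0.003) == \
            pytest.approx(0.015)
        W1, W2 = rng.standard_normal((3, 4)), rng.standard_normal((4, 3))
        assert weight_decay(W1, W2, 0.1) == weight_decay(-W1, -W2, 0.1)


class TestFullCosts:
    def test_rsae_cost_composes_terms(self, rng):
        p = random_params(6, 3)
        X = rng.uniform(0, 1, size=(8, 6))
        c = AEConfig(loss_type="mcc")
        H = encode(X, p)
        Y = decode(H, p)
        expected = (-mcc_loss(X, Y, c.sigma, c.kernel_normalized)
                    + weight_decay(p.W1, p.W2, c.weight_decay)
                    + sparsity_penalty(H, c.sparsity_target, c.sparsity_weight))
        assert rsae_cost(p, X, c) == pytest.approx(expected, rel=1e-14)

    def test_ssae_cost_composes_terms(self, rng):
        p = random_params(6, 3)
        X = rng.uniform(0, 1, size=(8, 6))
        c = AEConfig(loss_type="mse")
        H = encode(X, p)
        Y = decode(H, p)
        expected = (mse_loss(X, Y) + weight_decay(p.W1, p.W2, c.weight_decay)
                    + sparsity_penalty(H, c.sparsity_target, c.sparsity_weight))
        assert ssae_cost(p, X, c) == pytest.approx(expected, rel=1e-14)

    def test_weight_growth_raises_cost(self, rng):
        p = random_params(4, 2)
        X = rng.uniform(0, 1, size=(5, 4))
        c = AEConfig(loss_type="mse", sparsity_weight=0.0)
        base = weight_decay(p.W1, p.W2, c.weight_decay)
        grown = weight_decay(3 * p.W1, p.W2, c.weight_decay)
        assert grown > base


def finite_difference(f, theta, h=1e-5):
    g = np.zeros_like(theta)
    for i in range(len(theta)):
        tp, tm = theta.copy(), theta.copy()
        tp[i] += h
        tm[i] -= h
        g[i] = (f(tp) - f(tm)) / (2 * h)
    return g


class TestGradients:
    @pytest.mark.parametrize("loss", ["mcc", "mse"])
    def test_cost_gradient_matches_central_differences(self, loss):
        rng = np.random.default_rng(3)
        d, h = 10, 5
        X = np.clip(0.5 + 0.05 * rng.standard_normal((12, d)), 0, 1)
        p = random_params(d, h, seed=4, scale=0.3)
        c = AEConfig(loss_type=loss, sigma=0.05, weight_decay=0.003,
                     sparsity_weight=3.0, sparsity_target=0.1)
        analytic = cost_gradient(p, X, c).flatten()
        numeric = finite_difference(
            lambda th: autoencoder_cost(AEParams.unflatten(th, d, h), X, c), p.flatten())
        rel = np.linalg.norm(analytic - numeric) / (np.linalg.norm(analytic) + np.linalg.norm(numeric))
        assert rel <= 1e-6

    def test_weight_decay_part_of_gradient(self):
        d, h = 4, 2
        p = random_params(d, h, seed=1)
        X = np.full((3, d), 0.5)
        c0 = AEConfig(loss_type="mse", weight_decay=0.0, sparsity_weight=0.0)
        c1 = AEConfig(loss_type="mse", weight_decay=0.01, sparsity_weight=0.0)
        g0 = cost_gradient(p, X, c0)
        g1 = cost_gradient(p, X, c1)
        np.testing.assert_allclose(g1.W1 - g0.W1, 0.01 * p.W1, atol=1e-14)
        np.testing.assert_allclose(g1.W2 - g0.W2, 0.01 * p.W2, atol=1e-14)

    def test_decoder_bias_gradient_zero_at_perfect_reconstruction(self):
        # with symmetric data around 0.5 and zero weights, Y == X == 0.5
        d, h = 4, 2
        p = AEParams(W1=np.zeros((h, d)), b1=np.zeros(h), W2=np.zeros((d, h)), b2=np.zeros(d))
        X = np.full((6, d), 0.5)
        c = AEConfig(loss_type="mcc", sparsity_weight=0.0, weight_decay=0.0,
                     sparsity_target=0.5)
        g = cost_gradient(p, X, c)
        np.testing.assert_allclose(g.b2, 0.0, atol=1e-14)

    def test_finetune_gradient_matches_central_differences(self):
        rng = np.random.default_rng(5)
        net = StackedNet(
            encoder_layers=[(0.3 * rng.standard_normal((5, 10)), 0.1 * rng.standard_normal(5)),
                            (0.3 * rng.standard_normal((3, 5)), 0.1 * rng.standard_normal(3))],
            softmax_W=0.3 * rng.standard_normal((2, 3)), softmax_b=np.zeros(2))
        X = rng.uniform(0, 1, size=(15, 10))
        y = rng.integers(0, 2, size=15)
        _, analytic = finetune_objective(net, X, y, lam=0.003)
        numeric = finite_difference(
            lambda th: finetune_objective(_net_unflatten(th, net), X, y, 0.003)[0],
            _net_flatten(net))
        rel = np.linalg.norm(analytic - numeric) / (np.linalg.norm(analytic) + np.linalg.norm(numeric))
        assert rel <= 1e-6


class TestTraining:
    def test_descent_and_determinism(self, rng):
        X = np.clip(0.5 + 0.1 * rng.standard_normal((40, 8)), 0, 1)
        c = AEConfig(loss_type="mcc", seed=7, max_iter=100)
        p = train_autoencoder(X, c, 4)
        p2 = train_autoencoder(X, c, 4)
        np.testing.assert_array_equal(p.flatten(), p2.flatten())
        rng_init = np.random.default_rng(7)
        from rsae.autoencoder import _init_params
        p0 = _init_params(8, 4, rng_init)
        assert autoencoder_cost(p, X, c) <= autoencoder_cost(p0, X, c)

    def test_rank2_data_well_reconstructed(self):
        # two latent factors -> a 2-unit bottleneck captures most variance
        rng = np.random.default_rng(9)
        Z = rng.standard_normal((200, 2))
        A = rng.standard_normal((2, 10))
        X = 1.0 / (1.0 + np.exp(-(Z @ A)))
        c = AEConfig(loss_type="mse", sparsity_weight=0.0, weight_decay=1e-5,
                     seed=2, max_iter=400)
        p = train_autoencoder(X, c, 2)
        Y = decode(encode(X, p), p)
        assert np.mean((Y - X) ** 2) < 0.1 * X.var()

    def test_nonfinite_cost_reported(self):
        X = np.full((4, 3), 0.5)
        c = AEConfig(loss_type="mse", weight_decay=np.inf)
        with pytest.raises(FloatingPointError):
            train_autoencoder(X, c, 2)


class TestStack:
    def test_single_pair_equals_one_autoencoder(self, rng):
        X = np.clip(0.5 + 0.1 * rng.standard_normal((30, 6)), 0, 1)
        c = AEConfig(loss_type="mse", seed=3, max_iter=60)
        net = pretrain_stack(X, [6, 3], c)
        assert len(net.encoder_layers) == 1
        assert net.layer_sizes == [6, 3]

    def test_hidden_activations_feed_next_layer_in_unit_interval(self, rng):
        X = np.clip(0.5 + 0.1 * rng.standard_normal((30, 6)), 0, 1)
        c = AEConfig(loss_type="mcc", seed=3, max_iter=60)
        net = pretrain_stack(X, [6, 4, 2], c)
        h1 = extract_features(net, X, 1)
        assert np.all((h1 > 0) & (h1 < 1))
        assert extract_features(net, X, 2).shape == (30, 2)

    def test_extract_features_depth_zero_is_input(self, rng):
        X = rng.uniform(0, 1, size=(5, 6))
        net = pretrain_stack(X, [6, 3], AEConfig(loss_type="mse", max_iter=10))
        np.testing.assert_array_equal(extract_features(net, X, 0), X)
        with pytest.raises(ValueError):
            extract_features(net, X, 5)

    def test_three_unit_top_layer_supported(self, small_features):
        X, _ = small_features
        c = AEConfig(seed=0, max_iter=60)
        net = pretrain_stack(X[:80], [64, 20, 3], c)
        assert extract_features(net, X[:80]).shape == (80, 3)


class TestSoftmaxHead:
    def test_zero_weights_uniform_posteriors(self, rng):
        net = StackedNet(encoder_layers=[(rng.standard_normal((3, 4)), np.zeros(3))],
                         softmax_W=np.zeros((2, 3)), softmax_b=np.zeros(2))
        P = softmax_predict_proba(net, rng.uniform(0, 1, size=(6, 4)))
        np.testing.assert_allclose(P, 0.5)
        # posterior tie -> nonseizure (class 0)
        assert np.all(predict(net, rng.uniform(0, 1, size=(6, 4))) == 0)

    def test_rows_sum_to_one_and_logit_shift_invariance(self, rng):
        net = StackedNet(encoder_layers=[(rng.standard_normal((3, 4)), np.zeros(3))],
                         softmax_W=rng.standard_normal((2, 3)),
                         softmax_b=rng.standard_normal(2))
        X = rng.uniform(0, 1, size=(10, 4))
        P = softmax_predict_proba(net, X)
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-12)
        shifted = StackedNet(encoder_layers=net.encoder_layers,
                             softmax_W=net.softmax_W, softmax_b=net.softmax_b + 7.0)
        np.testing.assert_allclose(softmax_predict_proba(shifted, X), P, atol=1e-12)


class TestFineTune:
    def _toy_net_and_data(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0.25, 0.05, size=(30, 2)),
                       rng.normal(0.75, 0.05, size=(30, 2))])
        y = np.repeat([0, 1], 30)
        net = pretrain_stack(X, [2, 4], AEConfig(loss_type="mse", seed=1, max_iter=50))
        return net, np.clip(X, 0, 1), y

    def test_separable_toy_reaches_perfect_training_accuracy(self):
        net, X, y = self._toy_net_and_data()
        net = train_softmax(net, X, y, AEConfig(max_iter=100))
        net = fine_tune(net, X, y, AEConfig(max_iter=200))
        assert np.mean(predict(net, X) == y) == 1.0

    def test_train_softmax_freezes_encoder(self):
        net, X, y = self._toy_net_and_data()
        W_before = net.encoder_layers[0][0].copy()
        net2 = train_softmax(net, X, y, AEConfig(max_iter=50))
        np.testing.assert_array_equal(net2.encoder_layers[0][0], W_before)
        assert np.any(net2.softmax_W != 0)

    def test_fine_tune_reduces_training_cross_entropy(self):
        net, X, y = self._toy_net_and_data()
        c = AEConfig(max_iter=100)
        before, _ = finetune_objective(net, X, y, c.weight_decay)
        tuned = fine_tune(net, X, y, c)
        after, _ = finetune_objective(tuned, X, y, c.weight_decay)
        assert after <= before

    def test_huge_weight_decay_drives_posteriors_uniform(self):
        net, X, y = self._toy_net_and_data()
        tuned = fine_tune(net, X, y, AEConfig(weight_decay=1e4, max_iter=200))
        P = softmax_predict_proba(tuned, X)
        np.testing.assert_allclose(P, 0.5, atol=0.01)


class TestSerialization:
    def test_round_trip(self, tmp_path, rng):
        X = np.clip(0.5 + 0.1 * rng.standard_normal((20, 6)), 0, 1)
        c = AEConfig(loss_type="mcc", seed=3, max_iter=30)
        net = pretrain_stack(X, [6, 4, 2], c)
        path = tmp_path / "model.json"
        save_model(path, net, c, extra={"band": "alpha"})
        net2, c2, extra = load_model(path)
        assert c2 == c and extra == {"band": "alpha"}
        np.testing.assert_array_equal(
            extract_features(net, X), extract_features(net2, X))

    def test_unknown_version_rejected(self, tmp_path):
        path = tmp_path / "model.json"
        path.write_text('{"format_version": 99}')
        with pytest.raises(ValueError):
            load_model(path)
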