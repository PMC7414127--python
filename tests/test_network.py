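"""Forward-pass oracles, loss arithmetic, and gradient correctness.

The convolution/pooling, attention, and loss operations are checked
against independent brute-force loop implementations; the full backward
pass is checked against central finite differences in float64.
"""

import numpy as np
import pytest

from attnbind.network import (
    Adam,
    ModelConfig,
    attention_forward,
    backward,
    bce_loss,
    bilstm_forward,
    conv_pool_forward,
    forward,
    head_forward,
    init_params,
    n_parameters,
    pre_pool_activations,
)


def brute_force_conv_pool(x, F, w):
    """Triple-loop oracle: valid cross-correlation, ReLU, window max."""
    S = x.shape[0]
    h, l, _ = F.shape
    P = S - l + 1
    conv = np.zeros((P, h))
    for k in range(h):
        for i in range(P):
            acc = 0.0
            for j in range(l):
                for b in range(4):
                    acc += x[i + j, b] * F[k, j, b]
            conv[i, k] = max(0.0, acc)
    t = P // w
    pooled = np.zeros((t, h))
    for k in range(h):
        for u in range(t):
            pooled[u, k] = conv[u * w:(u + 1) * w, k].max()
    return pooled


class TestConfig:
    def test_full_scale_dimension_chain(self):
        cfg = ModelConfig()
        assert cfg.conv_length == 975
        assert cfg.pooled_length == 75
        assert cfg.hidden == 320
        assert cfg.flat_dim == 75 * 640
        assert cfg.attention_param_count() == 321

    def test_derived_pooled_length(self):
        cfg = ModelConfig(seq_length=100, kernel_len=11, pool_window=7)
        assert cfg.pooled_length == (100 - 11 + 1) // 7

    def test_sequence_shorter_than_kernel_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(seq_length=10, kernel_len=26)


class TestConvPool:
    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(100):
            S = int(rng.integers(15, 40))
            l = int(rng.integers(3, 9))
            w = int(rng.integers(2, 6))
            h = int(rng.integers(1, 5))
            if (S - l + 1) // w < 1:
                continue
            cfg = ModelConfig(seq_length=S, kernel_len=l, n_kernels=h,
                              pool_window=w, lstm_hidden=2, fc_dim=3, n_tasks=1)
            F = rng.standard_normal((h, l, 4))
            x = rng.standard_normal((S, 4))
            got = conv_pool_forward(x, {"F": F}, cfg)
            expect = brute_force_conv_pool(x, F, w)
            np.testing.assert_allclose(got, expect, atol=1e-6)

    def test_zero_input_gives_zero_map(self, tiny_config, tiny_params):
        x = np.zeros((tiny_config.seq_length, 4))
        assert not conv_pool_forward(x, tiny_params, tiny_config).any()

    def test_activation_map_nonnegative(self, tiny_config, tiny_params, rng):
        x = rng.standard_normal((tiny_config.seq_length, 4))
        assert (conv_pool_forward(x, tiny_params, tiny_config) >= 0).all()

    def test_wrong_length_rejected(self, tiny_config, tiny_params):
        with pytest.raises(ValueError):
            conv_pool_forward(np.zeros((7, 4)), tiny_params, tiny_config)

    def test_pre_pool_tie_breaks_leftmost(self, rng):
        cfg = ModelConfig(seq_length=20, kernel_len=4, n_kernels=1, pool_window=2,
                          lstm_hidden=2, fc_dim=2, n_tasks=1)
        F = np.zeros((1, 4, 4))  # zero kernel: all activations equal (zero)
        A = pre_pool_activations(np.ones((20, 4)) * 0.25, {"F": F}, cfg)
        assert A.argmax(axis=0)[0] == 0


class TestAttention:
    def test_constant_map_gives_uniform_attention(self, rng):
        C = np.tile(rng.standard_normal(4), (6, 1))  # identical rows
        a, _ = attention_forward(C, rng.standard_normal(4), 0.7)
        np.testing.assert_allclose(a, np.full(6, 1 / 6), atol=1e-12)

    def test_zero_key_gives_uniform_regardless_of_map(self, rng):
        C = rng.standard_normal((5, 3))
        a, Cs = attention_forward(C, np.zeros(3), 0.0)
        np.testing.assert_allclose(a, np.full(5, 0.2), atol=1e-12)
        # uniform attention scales every column by exactly 1/t
        np.testing.assert_allclose(Cs, C / 5, atol=1e-12)

    def test_normalization_and_shapes(self, rng):
        C = rng.standard_normal((8, 11, 4))
        a, Cs = attention_forward(C, rng.standard_normal(4), rng.standard_normal())
        assert a.shape == (8, 11) and Cs.shape == C.shape
        np.testing.assert_allclose(a.sum(axis=1), 1.0, atol=1e-6)
        assert (a >= 0).all()

    def test_matches_loop_oracle(self, rng):
        C = rng.standard_normal((7, 5))
        p = rng.standard_normal(5)
        b = 0.3
        scores = np.array([C[i] @ p + b for i in range(7)])
        e = np.exp(scores - scores.max())
        a_expect = e / e.sum()
        a, Cs = attention_forward(C, p, b)
        np.testing.assert_allclose(a, a_expect, atol=1e-9)
        for j in range(5):
            np.testing.assert_allclose(Cs[:, j], C[:, j] * a_expect, atol=1e-9)

    def test_bias_is_softmax_shift_invariant(self, rng):
        C = rng.standard_normal((6, 4))
        p = rng.standard_normal(4)
        a0, _ = attention_forward(C, p, 0.0)
        a1, _ = attention_forward(C, p, 5.0)
        np.testing.assert_allclose(a0, a1, atol=1e-9)

    def test_non_finite_rejected(self):
        C = np.full((3, 2), np.nan)
        with pytest.raises(ValueError):
            attention_forward(C, np.zeros(2))

    def test_attention_adds_key_count_plus_one_parameters(self, tiny_config):
        with_att = init_params(tiny_config, np.random.default_rng(0))
        cfg_no = ModelConfig(**{**tiny_config.__dict__, "use_attention": False})
        without = init_params(cfg_no, np.random.default_rng(0))
        assert n_parameters(with_att) - n_parameters(without) == tiny_config.n_kernels + 1


class TestBiLSTM:
    def test_output_shape(self, tiny_config, tiny_params, rng):
        t, H = tiny_config.pooled_length, tiny_config.hidden
        L = bilstm_forward(rng.standard_normal((t, tiny_config.n_kernels)),
                           tiny_params, tiny_config)
        assert L.shape == (t, 2 * H)

    def test_zero_input_zero_weights_zero_output(self, tiny_config):
        params = init_params(tiny_config, np.random.default_rng(0), dtype=np.float64)
        for k in ("b_fwd", "b_bwd"):
            params[k] = np.zeros_like(params[k])  # clear forget bias
        t = tiny_config.pooled_length
        L = bilstm_forward(np.zeros((t, tiny_config.n_kernels)), params, tiny_config)
        np.testing.assert_allclose(L, 0.0, atol=1e-12)

    def test_time_reversal_swaps_direction_blocks(self, tiny_config, rng):
        # with shared weights across directions, reversing the input
        # reverses time and swaps the forward/backward output blocks
        params = init_params(tiny_config, np.random.default_rng(1), dtype=np.float64)
        for k in ("Wx", "Wh", "b"):
            params[f"{k}_bwd"] = params[f"{k}_fwd"].copy()
        t, H = tiny_config.pooled_length, tiny_config.hidden
        X = rng.standard_normal((t, tiny_config.n_kernels))
        L = bilstm_forward(X, params, tiny_config)
        L_rev = bilstm_forward(X[::-1], params, tiny_config)
        np.testing.assert_allclose(L_rev[::-1, :H], L[:, H:], atol=1e-10)
        np.testing.assert_allclose(L_rev[::-1, H:], L[:, :H], atol=1e-10)


class TestHead:
    def test_zero_weights_give_half_probability(self, tiny_config, tiny_params):
        params = {k: np.zeros_like(v) for k, v in tiny_params.items()}
        t, H = tiny_config.pooled_length, tiny_config.hidden
        yhat = head_forward(np.zeros((t, 2 * H)), params)
        np.testing.assert_allclose(yhat, 0.5, atol=1e-12)

    def test_outputs_strictly_inside_unit_interval(self, tiny_config, tiny_params, rng):
        t, H = tiny_config.pooled_length, tiny_config.hidden
        yhat = head_forward(rng.standard_normal((t, 2 * H)) * 10, tiny_params)
        assert ((yhat > 0) & (yhat < 1)).all()


class TestLoss:
    def test_half_probability_gives_log_two(self):
        y = np.array([[0.0, 1.0, 1.0]])
        assert bce_loss(np.full((1, 3), 0.5), y) == pytest.approx(np.log(2), abs=1e-9)

    def test_perfect_prediction_is_near_zero(self):
        y = np.array([[0.0, 1.0]])
        assert bce_loss(y, y) <= 2e-7  # bounded by the clipping epsilon

    def test_matches_scalar_loop(self, rng):
        yhat = rng.uniform(0.01, 0.99, size=(4, 5))
        y = rng.integers(0, 2, size=(4, 5)).astype(float)
        acc = 0.0
        for n in range(4):
            for t in range(5):
                acc += y[n, t] * np.log(yhat[n, t]) + (1 - y[n, t]) * np.log(1 - yhat[n, t])
        np.testing.assert_allclose(bce_loss(yhat, y), -acc / 20, atol=1e-9)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            bce_loss(np.zeros((2, 3)), np.zeros((3, 2)))

    def test_invariant_to_sample_order(self, rng):
        yhat = rng.uniform(0.01, 0.99, size=(10, 4))
        y = rng.integers(0, 2, size=(10, 4)).astype(float)
        perm = rng.permutation(10)
        assert bce_loss(yhat, y) == pytest.approx(bce_loss(yhat[perm], y[perm]), abs=1e-12)


class TestGradients:
    def test_backward_matches_finite_differences(self, tiny_config):
        """Full-network analytic gradients vs central differences (float64)."""
        cfg = tiny_config
        rng = np.random.default_rng(42)
        params = init_params(cfg, rng, dtype=np.float64)
        X = rng.random((3, cfg.seq_length, 4))
        y = rng.integers(0, 2, size=(3, cfg.n_tasks)).astype(float)

        out = forward(X, params, cfg, return_cache=True)
        grads = backward(y, out["cache"], params, cfg)

        def loss_fn():
            return bce_loss(forward(X, params, cfg)["y_hat"], y)

        h = 1e-6
        check_rng = np.random.default_rng(7)
        for name, value in params.items():
            if value.ndim == 0:
                idxs = [None]
            else:
                size = value.size
                idxs = check_rng.choice(size, size=min(6, size), replace=False)
            for idx in idxs:
                flat = params[name].reshape(-1) if value.ndim else None
                if idx is None:
                    params[name] = value + h
                    lp = loss_fn()
                    params[name] = value - h
                    lm = loss_fn()
                    params[name] = value
                    analytic = float(grads[name])
                else:
                    flat[idx] += h
                    lp = loss_fn()
                    flat[idx] -= 2 * h
                    lm = loss_fn()
                    flat[idx] += h
                    analytic = grads[name].reshape(-1)[idx]
                numeric = (lp - lm) / (2 * h)
                assert numeric == pytest.approx(analytic, abs=5e-8), name

    def test_ablation_backward_consistent(self):
        cfg = ModelConfig(seq_length=20, kernel_len=4, n_kernels=3, pool_window=3,
                          lstm_hidden=3, fc_dim=4, n_tasks=2, use_attention=False)
        rng = np.random.default_rng(0)
        params = init_params(cfg, rng, dtype=np.float64)
        X = rng.random((2, 20, 4))
        y = rng.integers(0, 2, size=(2, 2)).astype(float)
        out = forward(X, params, cfg, return_cache=True)
        grads = backward(y, out["cache"], params, cfg)
        assert "p" not in grads and out["attention"] is None

        def loss_fn():
            return bce_loss(forward(X, params, cfg)["y_hat"], y)

        h = 1e-6
        flat = params["F"].reshape(-1)
        flat[0] += h
        lp = loss_fn()
        flat[0] -= 2 * h
        lm = loss_fn()
        flat[0] += h
        assert (lp - lm) / (2 * h) == pytest.approx(grads["F"].reshape(-1)[0], abs=5e-8)


class TestAdam:
    def test_descends_simple_quadratic(self):
        params = {"x": np.array([5.0, -3.0])}
        opt = Adam(params, lr=0.1)
        for _ in range(400):
            opt.step(params, {"x": 2 * params["x"]})
        np.testing.assert_allclose(params["x"], 0.0, atol=1e-3)
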