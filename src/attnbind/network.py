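"""Functional core of the attention-augmented CNN-BiLSTM network.

The architecture: a one-hot S x 4 sequence is scanned by h convolution
kernels of length l (valid cross-correlation, no bias), rectified, and
max-pooled in non-overlapping windows of w, yielding the activation map
C in R^{t x h} with t = floor((S - l + 1) / w).  A positional attention
layer scores each pooled position by a dot product with a trainable key
vector p (plus a scalar bias), softmax-normalizes the scores into an
attention vector a, and rescales every column of C element-wise by a.
A bidirectional LSTM reads the scaled map in both directions; its
concatenated outputs are flattened through a ReLU hidden layer into
per-task sigmoid outputs trained with mean binary cross-entropy.

Everything here is plain NumPy with hand-written backward passes (no
autodiff framework is assumed); gradients are validated against finite
differences in the test suite.  Public single-input helpers
(:func:`conv_pool_forward`, :func:`attention_forward`, ...) accept either
one S x 4 matrix or a batch (n, S, 4).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Any

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

GATES = 4  # input, forget, candidate, output


@dataclass(frozen=True)
class ModelConfig:
    """Architecture dimensions.

    Defaults are the full-scale values: 1,000 bp inputs, 320 kernels of
    length 26, pool window 13 (pooled length 75), per-direction LSTM width
    equal to the kernel count, 695-unit hidden layer, 690 tasks.
    """

    seq_length: int = 1000
    kernel_len: int = 26
    n_kernels: int = 320
    pool_window: int = 13
    lstm_hidden: int | None = None  # defaults to n_kernels
    fc_dim: int = 695
    n_tasks: int = 690
    use_attention: bool = True

    def __post_init__(self) -> None:
        for name in ("seq_length", "kernel_len", "n_kernels", "pool_window",
                     "fc_dim", "n_tasks"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.seq_length < self.kernel_len:
            raise ValueError("sequence shorter than kernel")
        if self.pooled_length < 1:
            raise ValueError("pooled length < 1; reduce pool_window")

    @property
    def hidden(self) -> int:
        return self.n_kernels if self.lstm_hidden is None else self.lstm_hidden

    @property
    def conv_length(self) -> int:
        return self.seq_length - self.kernel_len + 1

    @property
    def pooled_length(self) -> int:
        return self.conv_length // self.pool_window

    @property
    def flat_dim(self) -> int:
        return self.pooled_length * 2 * self.hidden

    def attention_param_count(self) -> int:
        """Trainable scalars added by the attention layer (key vector + bias)."""
        return (self.n_kernels + 1) if self.use_attention else 0


def _glorot(rng: np.random.Generator, shape: tuple[int, ...],
            fan_in: int, fan_out: int, dtype) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


def _he(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int,
        dtype) -> np.ndarray:
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


def _orthogonal_gates(rng: np.random.Generator, H: int, dtype) -> np.ndarray:
    """(H, 4H) recurrent weight: one orthogonal block per gate."""
    blocks = []
    for _ in range(GATES):
        q, _r = np.linalg.qr(rng.standard_normal((H, H)))
        blocks.append(q)
    return np.concatenate(blocks, axis=1).astype(dtype)


def init_params(config: ModelConfig, rng: np.random.Generator,
                dtype=np.float32) -> dict[str, np.ndarray]:
    """Parameter initialization (the trained architecture's paper leaves
    initialization unstated; these are standard choices).

    Conv kernels: He-uniform (the layer feeds a ReLU).  Attention key:
    small random uniform (the key vector is randomly initialized), scalar
    bias 0.  LSTM: Glorot-uniform input weights, orthogonal recurrent
    blocks per gate, forget-gate bias 1.  Dense layers: Glorot-uniform
    with zero biases.

    With attention active, a near-uniform initial attention scales the
    activation map by ~1/t before the BiLSTM; the LSTM input weights
    therefore carry a gain of t (variance-preserving w.r.t. the
    attention-scaled input) so that desk-scale training is not stalled by
    a vanishing input signal.
    """
    c = config
    H, h = c.hidden, c.n_kernels
    lstm_in_gain = float(c.pooled_length) if c.use_attention else 1.0
    params: dict[str, np.ndarray] = {
        "F": _he(rng, (h, c.kernel_len, 4), c.kernel_len * 4, dtype),
        "W1": _glorot(rng, (c.flat_dim, c.fc_dim), c.flat_dim, c.fc_dim, dtype),
        "b1": np.zeros(c.fc_dim, dtype=dtype),
        "W2": _glorot(rng, (c.fc_dim, c.n_tasks), c.fc_dim, c.n_tasks, dtype),
        "b2": np.zeros(c.n_tasks, dtype=dtype),
    }
    if c.use_attention:
        params["p"] = _glorot(rng, (h,), h, 1, dtype)
        params["b_att"] = np.zeros((), dtype=dtype)
    for d in ("fwd", "bwd"):
        params[f"Wx_{d}"] = lstm_in_gain * _glorot(rng, (h, GATES * H), h,
                                                   GATES * H, dtype)
        params[f"Wh_{d}"] = _orthogonal_gates(rng, H, dtype)
        b = np.zeros(GATES * H, dtype=dtype)
        b[H : 2 * H] = 1.0  # forget-gate bias
        params[f"b_{d}"] = b
    return params


def n_parameters(params: dict[str, np.ndarray]) -> int:
    return int(sum(v.size for v in params.values()))


def _as_batch(x: np.ndarray) -> tuple[np.ndarray, bool]:
    x = np.asarray(x)
    if x.ndim == 2:
        return x[None], True
    if x.ndim == 3:
        return x, False
    raise ValueError("expected (S, 4) or (n, S, 4) input")


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# convolution + max-pool


def _conv_pool_fw(X: np.ndarray, F: np.ndarray, config: ModelConfig):
    B = X.shape[0]
    l, h, w, t = config.kernel_len, config.n_kernels, config.pool_window, config.pooled_length
    # im2col: (B, P, l*4) windows of the one-hot input
    win = sliding_window_view(X, l, axis=1)            # (B, P, 4, l)
    win = win.transpose(0, 1, 3, 2).reshape(B, -1, l * 4)
    W = F.reshape(h, l * 4).T                          # (l*4, h)
    Z = win @ W                                        # (B, P, h) pre-activation
    A = np.maximum(Z, 0.0)
    Ar = A[:, : t * w].reshape(B, t, w, h)
    idx = Ar.argmax(axis=2)                            # (B, t, h) leftmost max
    C = np.take_along_axis(Ar, idx[:, :, None, :], axis=2)[:, :, 0, :]
    cache = {"win": win, "Z": Z, "idx": idx}
    return C, cache


def _conv_pool_bw(dC: np.ndarray, cache, config: ModelConfig) -> np.ndarray:
    B, t, h = dC.shape
    w, l = config.pool_window, config.kernel_len
    P = cache["Z"].shape[1]
    dAr = np.zeros((B, t, w, h), dtype=dC.dtype)
    np.put_along_axis(dAr, cache["idx"][:, :, None, :], dC[:, :, None, :], axis=2)
    dA = np.zeros((B, P, h), dtype=dC.dtype)
    dA[:, : t * w] = dAr.reshape(B, t * w, h)
    dZ = np.where(cache["Z"] > 0, dA, 0.0)
    win = cache["win"].reshape(B * P, l * 4)
    dW = win.T @ dZ.reshape(B * P, h)                  # (l*4, h)
    return dW.T.reshape(h, l, 4)


def conv_pool_forward(x: np.ndarray, params: dict[str, np.ndarray],
                      config: ModelConfig) -> np.ndarray:
    """Valid cross-correlation with each kernel, ReLU, non-overlapping max-pool.

    Returns the activation map C, shape t x h (or batch n x t x h); the
    trailing ``conv_length mod pool_window`` positions are dropped.
    """
    X, single = _as_batch(x)
    if X.shape[1] != config.seq_length:
        raise ValueError(
            f"sequence length {X.shape[1]} != configured {config.seq_length}")
    C, _ = _conv_pool_fw(X.astype(params["F"].dtype, copy=False), params["F"], config)
    return C[0] if single else C


# ---------------------------------------------------------------------------
# attention


def _attention_fw(C: np.ndarray, p: np.ndarray, b_att: np.ndarray):
    scores = C @ p + b_att                             # (B, t)
    a = _softmax(scores)
    Cs = C * a[:, :, None]
    return a, Cs


def _attention_bw(dCs: np.ndarray, da_extra: np.ndarray | None,
                  C: np.ndarray, a: np.ndarray, p: np.ndarray):
    dC = dCs * a[:, :, None]
    da = np.einsum("bth,bth->bt", dCs, C)
    if da_extra is not None:
        da = da + da_extra
    ds = a * (da - (da * a).sum(axis=1, keepdims=True))  # softmax backward
    dC += ds[:, :, None] * p[None, None, :]
    dp = np.einsum("bt,bth->h", ds, C)
    db = ds.sum()
    return dC, dp, db


def attention_forward(C: np.ndarray, p: np.ndarray,
                      b_att: float | np.ndarray = 0.0
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Positional attention: a = softmax(Cp + b); columns of C scaled by a.

    Returns ``(a, C_scaled)``.  Accepts a single t x h map or a batch.
    The softmax subtracts the row maximum for numerical stability; the
    scalar bias shifts all scores equally and is therefore a no-op for the
    output, but it is part of the trainable parameter count.
    """
    Cb, single = _as_batch(C)
    if not np.isfinite(Cb).all():
        raise ValueError("activation map contains non-finite entries")
    p = np.asarray(p)
    if p.shape != (Cb.shape[2],):
        raise ValueError("key vector length must equal the kernel count")
    a, Cs = _attention_fw(Cb, p, np.asarray(b_att))
    return (a[0], Cs[0]) if single else (a, Cs)


# ---------------------------------------------------------------------------
# LSTM


def _lstm_fw(X: np.ndarray, Wx, Wh, b):
    """Unidirectional LSTM over X (B, t, in) -> outputs (B, t, H) + cache."""
    B, t, _ = X.shape
    H = Wh.shape[0]
    dt = X.dtype
    i_s = np.empty((t, B, H), dt); f_s = np.empty((t, B, H), dt)
    g_s = np.empty((t, B, H), dt); o_s = np.empty((t, B, H), dt)
    c_s = np.empty((t, B, H), dt); tc_s = np.empty((t, B, H), dt)
    h_s = np.empty((t, B, H), dt)
    h_prev = np.zeros((B, H), dt)
    c_prev = np.zeros((B, H), dt)
    for s in range(t):
        z = X[:, s] @ Wx + h_prev @ Wh + b
        i = _sigmoid(z[:, :H]); f = _sigmoid(z[:, H:2 * H])
        g = np.tanh(z[:, 2 * H:3 * H]); o = _sigmoid(z[:, 3 * H:])
        c = f * c_prev + i * g
        tc = np.tanh(c)
        hcur = o * tc
        i_s[s], f_s[s], g_s[s], o_s[s] = i, f, g, o
        c_s[s], tc_s[s], h_s[s] = c, tc, hcur
        h_prev, c_prev = hcur, c
    cache = {"X": X, "i": i_s, "f": f_s, "g": g_s, "o": o_s,
             "c": c_s, "tc": tc_s, "h": h_s}
    return h_s.transpose(1, 0, 2), cache


def _lstm_bw(dH: np.ndarray, cache, Wx, Wh):
    """Backward through one direction.  dH is (B, t, H) in processing order."""
    X = cache["X"]
    B, t, _ = X.shape
    H = Wh.shape[0]
    dt = X.dtype
    dWx = np.zeros_like(Wx); dWh = np.zeros_like(Wh)
    db = np.zeros(GATES * H, dtype=dt)
    dX = np.empty_like(X)
    dh_next = np.zeros((B, H), dt)
    dc_next = np.zeros((B, H), dt)
    dz = np.empty((B, GATES * H), dt)
    for s in range(t - 1, -1, -1):
        i, f, g, o = cache["i"][s], cache["f"][s], cache["g"][s], cache["o"][s]
        tc = cache["tc"][s]
        c_prev = cache["c"][s - 1] if s > 0 else np.zeros((B, H), dt)
        h_prev = cache["h"][s - 1] if s > 0 else np.zeros((B, H), dt)
        dh = dH[:, s] + dh_next
        dc = dc_next + dh * o * (1.0 - tc * tc)
        dz[:, :H] = dc * g * i * (1.0 - i)
        dz[:, H:2 * H] = dc * c_prev * f * (1.0 - f)
        dz[:, 2 * H:3 * H] = dc * i * (1.0 - g * g)
        dz[:, 3 * H:] = dh * tc * o * (1.0 - o)
        dWx += X[:, s].T @ dz
        dWh += h_prev.T @ dz
        db += dz.sum(axis=0)
        dX[:, s] = dz @ Wx.T
        dh_next = dz @ Wh.T
        dc_next = dc * f
    return dX, dWx, dWh, db


def _bilstm_fw(Cs: np.ndarray, params, config: ModelConfig):
    hf, cache_f = _lstm_fw(Cs, params["Wx_fwd"], params["Wh_fwd"], params["b_fwd"])
    hb_rev, cache_b = _lstm_fw(Cs[:, ::-1], params["Wx_bwd"], params["Wh_bwd"],
                               params["b_bwd"])
    L = np.concatenate([hf, hb_rev[:, ::-1]], axis=2)
    return L, (cache_f, cache_b)


def _bilstm_bw(dL: np.ndarray, caches, params, config: ModelConfig):
    H = config.hidden
    cache_f, cache_b = caches
    dXf, dWxf, dWhf, dbf = _lstm_bw(
        np.ascontiguousarray(dL[:, :, :H]), cache_f,
        params["Wx_fwd"], params["Wh_fwd"])
    dXb, dWxb, dWhb, dbb = _lstm_bw(
        np.ascontiguousarray(dL[:, ::-1, H:]), cache_b,
        params["Wx_bwd"], params["Wh_bwd"])
    dCs = dXf + dXb[:, ::-1]
    grads = {"Wx_fwd": dWxf, "Wh_fwd": dWhf, "b_fwd": dbf,
             "Wx_bwd": dWxb, "Wh_bwd": dWhb, "b_bwd": dbb}
    return dCs, grads


def bilstm_forward(C_scaled: np.ndarray, params: dict[str, np.ndarray],
                   config: ModelConfig) -> np.ndarray:
    """Bidirectional LSTM over the t pooled positions.

    Returns L, shape t x 2*hidden (per-position concatenation of the
    forward pass and the backward pass read at the same position).
    Initial states are zero.
    """
    Cb, single = _as_batch(C_scaled)
    L, _ = _bilstm_fw(Cb.astype(params["Wx_fwd"].dtype, copy=False), params, config)
    return L[0] if single else L


def head_forward(L: np.ndarray, params: dict[str, np.ndarray]) -> np.ndarray:
    """Flatten L row-major, ReLU hidden layer, per-task sigmoid outputs."""
    Lb, single = _as_batch(L)
    flat = Lb.reshape(Lb.shape[0], -1)
    y1 = np.maximum(flat @ params["W1"] + params["b1"], 0.0)
    yhat = _sigmoid(y1 @ params["W2"] + params["b2"])
    return yhat[0] if single else yhat


def bce_loss(y_hat: np.ndarray, y: np.ndarray, eps: float = 1e-7) -> float:
    """Mean binary cross-entropy over all sample-task entries.

    Predictions are clipped to [eps, 1 - eps] before the logs.
    """
    y_hat, y = np.asarray(y_hat), np.asarray(y)
    if y_hat.shape != y.shape:
        raise ValueError(f"shape mismatch: {y_hat.shape} vs {y.shape}")
    q = np.clip(y_hat, eps, 1.0 - eps)
    return float(-np.mean(y * np.log(q) + (1.0 - y) * np.log1p(-q)))


# ---------------------------------------------------------------------------
# full network


def forward(X: np.ndarray, params: dict[str, np.ndarray], config: ModelConfig,
            return_cache: bool = False):
    """Full forward pass on a batch (n, S, 4).

    Returns a dict with ``y_hat`` (n, n_tasks), ``attention`` (n, t; None
    when the ablation is active) and ``activation_map`` (n, t, h); with
    ``return_cache=True`` also the cache needed by :func:`backward`.
    """
    X = np.asarray(X, dtype=params["F"].dtype)
    C, conv_cache = _conv_pool_fw(X, params["F"], config)
    if config.use_attention:
        a, Cs = _attention_fw(C, params["p"], params["b_att"])
    else:
        a, Cs = None, C
    L, lstm_caches = _bilstm_fw(Cs, params, config)
    flat = L.reshape(L.shape[0], -1)
    z1 = flat @ params["W1"] + params["b1"]
    y1 = np.maximum(z1, 0.0)
    logits = y1 @ params["W2"] + params["b2"]
    yhat = _sigmoid(logits)
    out = {"y_hat": yhat, "attention": a, "activation_map": C}
    if return_cache:
        out["cache"] = {"conv": conv_cache, "C": C, "a": a, "Cs": Cs,
                        "lstm": lstm_caches, "flat": flat, "z1": z1, "y1": y1,
                        "yhat": yhat}
    return out


def backward(y: np.ndarray, cache: dict[str, Any],
             params: dict[str, np.ndarray], config: ModelConfig
             ) -> dict[str, np.ndarray]:
    """Gradients of the mean BCE loss w.r.t. every trainable parameter."""
    yhat, y1, z1, flat = cache["yhat"], cache["y1"], cache["z1"], cache["flat"]
    B = yhat.shape[0]
    n_total = yhat.size
    dlogits = (yhat - y.astype(yhat.dtype)) / n_total
    grads: dict[str, np.ndarray] = {}
    grads["W2"] = y1.T @ dlogits
    grads["b2"] = dlogits.sum(axis=0)
    dy1 = dlogits @ params["W2"].T
    dz1 = np.where(z1 > 0, dy1, 0.0)
    grads["W1"] = flat.T @ dz1
    grads["b1"] = dz1.sum(axis=0)
    dflat = dz1 @ params["W1"].T
    dL = dflat.reshape(B, config.pooled_length, 2 * config.hidden)
    dCs, lstm_grads = _bilstm_bw(dL, cache["lstm"], params, config)
    grads.update(lstm_grads)
    if config.use_attention:
        dC, dp, db = _attention_bw(dCs, None, cache["C"], cache["a"], params["p"])
        grads["p"] = dp
        grads["b_att"] = np.asarray(db, dtype=params["b_att"].dtype)
    else:
        dC = dCs
    grads["F"] = _conv_pool_bw(dC, cache["conv"], config)
    return grads


def pre_pool_activations(X: np.ndarray, params: dict[str, np.ndarray],
                         config: ModelConfig) -> np.ndarray:
    """Per-position ReLU conv activations (n, S - l + 1, h), before pooling.

    Used by kernel motif harvesting, which needs the position of the
    maximum activation at single-base resolution.
    """
    Xb, single = _as_batch(X)
    win = sliding_window_view(Xb.astype(params["F"].dtype, copy=False),
                              config.kernel_len, axis=1)
    win = win.transpose(0, 1, 3, 2).reshape(Xb.shape[0], -1, config.kernel_len * 4)
    Z = win @ params["F"].reshape(config.n_kernels, -1).T
    A = np.maximum(Z, 0.0)
    return A[0] if single else A


class Adam:
    """Adam optimizer over a parameter dict."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray],
             grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for k, g in grads.items():
            m = self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            v = self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * (g * g)
            params[k] = params[k] - self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
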