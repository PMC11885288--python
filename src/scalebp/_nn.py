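"""Minimal NumPy neural-network kernels with hand-derived gradients.

Just the pieces the signal-quality classifier needs: strided same-padded
1-D convolution, 2x max pooling, a GRU cell unrolled over a short feature
sequence, dense layers, inverted dropout, and Adam.  Shapes are
channels-last: convolution inputs are ``(batch, length, channels)``.

Every backward pass here is checked against central finite differences in
the test suite, which is the contract that keeps this file honest.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "conv1d_forward", "conv1d_backward", "conv1d_out_len", "conv1d_padding",
    "maxpool2_forward", "maxpool2_backward",
    "gru_forward", "gru_backward",
    "dense_forward", "dense_backward",
    "relu", "relu_grad", "sigmoid",
    "AdamState", "adam_step",
]


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def relu_grad(dy: np.ndarray, y: np.ndarray) -> np.ndarray:
    return dy * (y > 0)


# ---------------------------------------------------------------------------
# conv1d, stride s, TF-style "same" padding


def conv1d_out_len(n: int, stride: int) -> int:
    return -(-n // stride)  # ceil


def conv1d_padding(n: int, k: int, stride: int) -> tuple[int, int]:
    out = conv1d_out_len(n, stride)
    pad = max((out - 1) * stride + k - n, 0)
    return pad // 2, pad - pad // 2


def _im2col(xp: np.ndarray, k: int, stride: int, out_len: int) -> np.ndarray:
    b, _, c = xp.shape
    cols = np.empty((b, out_len, k, c), dtype=xp.dtype)
    for o in range(k):
        cols[:, :, o, :] = xp[:, o : o + stride * out_len : stride, :]
    return cols


def conv1d_forward(x: np.ndarray, w: np.ndarray, bias: np.ndarray, stride: int):
    """x (B,L,Cin), w (k,Cin,Cout), bias (Cout) -> y (B,Lout,Cout), cache."""
    b, n, cin = x.shape
    k, _, cout = w.shape
    pl, pr = conv1d_padding(n, k, stride)
    xp = np.pad(x, ((0, 0), (pl, pr), (0, 0)))
    out_len = conv1d_out_len(n, stride)
    cols = _im2col(xp, k, stride, out_len)
    y = cols.reshape(b, out_len, k * cin) @ w.reshape(k * cin, cout) + bias
    return y, (cols, xp.shape, (pl, pr), x.shape)


def conv1d_backward(dy: np.ndarray, w: np.ndarray, stride: int, cache):
    cols, xp_shape, (pl, _pr), x_shape = cache
    b, out_len, cout = dy.shape
    k, cin, _ = w.shape
    flat_cols = cols.reshape(b * out_len, k * cin)
    flat_dy = dy.reshape(b * out_len, cout)
    dw = (flat_cols.T @ flat_dy).reshape(k, cin, cout)
    dbias = flat_dy.sum(axis=0)
    dxp = np.zeros(xp_shape, dtype=dy.dtype)
    for o in range(k):
        # fixed kernel offset: strided, non-overlapping positions
        dxp[:, o : o + stride * out_len : stride, :] += dy @ w[o].T
    dx = dxp[:, pl : pl + x_shape[1], :]
    return dx, dw, dbias


# ---------------------------------------------------------------------------
# max pooling, kernel 2 stride 2 (length must be even)


def maxpool2_forward(x: np.ndarray):
    b, n, c = x.shape
    pairs = x.reshape(b, n // 2, 2, c)
    idx = pairs.argmax(axis=2)
    y = pairs.max(axis=2)
    return y, idx


def maxpool2_backward(dy: np.ndarray, idx: np.ndarray) -> np.ndarray:
    b, m, c = dy.shape
    dpairs = np.zeros((b, m, 2, c), dtype=dy.dtype)
    np.put_along_axis(dpairs, idx[:, :, None, :], dy[:, :, None, :], axis=2)
    return dpairs.reshape(b, 2 * m, c)


# ---------------------------------------------------------------------------
# GRU unrolled over (B, T, D)


def gru_forward(x: np.ndarray, params: dict[str, np.ndarray]):
    """Final hidden state of a single-layer GRU over the feature sequence.

    z_t = sig(x W_z + h U_z + b_z); r_t = sig(x W_r + h U_r + b_r)
    n_t = tanh(x W_n + r_t * (h U_n) + b_n); h_t = (1-z_t) n_t + z_t h
    """
    b, t_steps, _ = x.shape
    h = np.zeros((b, params["Uz"].shape[0]), dtype=x.dtype)
    caches = []
    for t in range(t_steps):
        xt = x[:, t, :]
        z = sigmoid(xt @ params["Wz"] + h @ params["Uz"] + params["bz"])
        r = sigmoid(xt @ params["Wr"] + h @ params["Ur"] + params["br"])
        an_h = h @ params["Un"]
        n = np.tanh(xt @ params["Wn"] + r * an_h + params["bn"])
        h_new = (1.0 - z) * n + z * h
        caches.append((xt, h, z, r, n, an_h))
        h = h_new
    return h, caches


def gru_backward(dh: np.ndarray, params: dict[str, np.ndarray], caches):
    grads = {k: np.zeros_like(v) for k, v in params.items()}
    dx_steps = []
    for xt, h_prev, z, r, n, an_h in reversed(caches):
        dz = dh * (h_prev - n)
        dn = dh * (1.0 - z)
        dh_prev = dh * z

        dn_pre = dn * (1.0 - n * n)
        grads["Wn"] += xt.T @ dn_pre
        grads["bn"] += dn_pre.sum(axis=0)
        dxt = dn_pre @ params["Wn"].T
        dr = dn_pre * an_h
        dan_h = dn_pre * r
        grads["Un"] += h_prev.T @ dan_h
        dh_prev = dh_prev + dan_h @ params["Un"].T

        dz_pre = dz * z * (1.0 - z)
        grads["Wz"] += xt.T @ dz_pre
        grads["Uz"] += h_prev.T @ dz_pre
        grads["bz"] += dz_pre.sum(axis=0)
        dxt += dz_pre @ params["Wz"].T
        dh_prev = dh_prev + dz_pre @ params["Uz"].T

        dr_pre = dr * r * (1.0 - r)
        grads["Wr"] += xt.T @ dr_pre
        grads["Ur"] += h_prev.T @ dr_pre
        grads["br"] += dr_pre.sum(axis=0)
        dxt += dr_pre @ params["Wr"].T
        dh_prev = dh_prev + dr_pre @ params["Ur"].T

        dx_steps.append(dxt)
        dh = dh_prev
    dx = np.stack(dx_steps[::-1], axis=1)
    return dx, grads


# ---------------------------------------------------------------------------
# dense


def dense_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    return x @ w + b, x


def dense_backward(dy: np.ndarray, w: np.ndarray, x: np.ndarray):
    return dy @ w.T, x.T @ dy, dy.sum(axis=0)


# ---------------------------------------------------------------------------
# Adam


class AdamState:
    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}


def adam_step(params: dict[str, np.ndarray], grads: dict[str, np.ndarray],
              state: AdamState) -> None:
    state.t += 1
    b1, b2 = state.beta1, state.beta2
    bias1 = 1.0 - b1**state.t
    bias2 = 1.0 - b2**state.t
    for k, g in grads.items():
        state.m[k] = b1 * state.m[k] + (1 - b1) * g
        state.v[k] = b2 * state.v[k] + (1 - b2) * g * g
        mhat = state.m[k] / bias1
        vhat = state.v[k] / bias2
        params[k] -= state.lr * mhat / (np.sqrt(vhat) + state.eps)
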