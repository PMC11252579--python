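"""NumPy neural-network primitives: initializers, Adam, dense/conv/LSTM
forward-backward passes.  Everything is float64 and driven by explicit
``numpy.random.Generator`` instances, so training is reproducible bit for bit
in single-threaded execution.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Adam", "glorot", "sigmoid", "bce_loss_and_grad",
           "dense_forward", "dense_backward",
           "conv1d_forward", "conv1d_backward",
           "lstm_forward", "lstm_backward"]


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int,
           shape=None) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    shape = (fan_in, fan_out) if shape is None else shape
    return rng.uniform(-limit, limit, size=shape)


def bce_loss_and_grad(p: np.ndarray, y: np.ndarray):
    """Binary cross-entropy summed over classes, averaged over the batch.

    Returns (loss, dlogits) where dlogits is the gradient with respect to the
    pre-sigmoid logits (the sigmoid+BCE composite gradient p − y, scaled by
    1/batch).
    """
    eps = 1e-12
    b = p.shape[0]
    loss = -np.sum(y * np.log(p + eps) + (1.0 - y) * np.log(1.0 - p + eps)) / b
    dlogits = (p - y) / b
    return float(loss), dlogits


class Adam:
    """Adam optimizer over a dict of named parameter arrays."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1.0 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1.0 - self.beta2) * g * g
            m_hat = self.m[k] / b1t
            v_hat = self.v[k] / b2t
            self.params[k] -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def dense_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    return x @ w + b


def dense_backward(dout: np.ndarray, x: np.ndarray, w: np.ndarray):
    return dout @ w.T, x.T @ dout, dout.sum(axis=0)


def conv1d_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    """Valid 1D convolution.

    x: (B, L, D); w: (ks*D, F); b: (F,).  Returns (out (B, P, F), windows
    (B, P, ks*D)) with P = L − ks + 1 output positions.
    """
    bsz, length, dim = x.shape
    ks = w.shape[0] // dim
    p = length - ks + 1
    windows = np.lib.stride_tricks.sliding_window_view(x, (ks, dim), axis=(1, 2))
    windows = windows.reshape(bsz, p, ks * dim)
    return windows @ w + b, windows


def conv1d_backward(dout: np.ndarray, windows: np.ndarray, w: np.ndarray,
                    x_shape):
    """Gradients of conv1d: returns (dx, dw, db)."""
    bsz, length, dim = x_shape
    p = windows.shape[1]
    ks = w.shape[0] // dim
    dw = np.einsum("bpi,bpf->if", windows, dout)
    db = dout.sum(axis=(0, 1))
    dwin = dout @ w.T                     # (B, P, ks*D)
    dwin = dwin.reshape(bsz, p, ks, dim)
    dx = np.zeros(x_shape)
    for j in range(ks):
        dx[:, j:j + p, :] += dwin[:, :, j, :]
    return dx, dw, db


def lstm_forward(x: np.ndarray, mask: np.ndarray, wx: np.ndarray,
                 wh: np.ndarray, b: np.ndarray):
    """Masked LSTM over a batch of sequences.

    x: (B, L, D); mask: (B, L) with 1.0 at valid positions.  At masked
    positions the hidden and cell states carry over unchanged, so the final
    state is the state after the last valid token.  Gate layout in the weight
    matrices: [input, forget, output, candidate] blocks of size H.

    Returns (h_last (B, H), cache) for backprop.
    """
    bsz, length, dim = x.shape
    hidden = wh.shape[0]
    h = np.zeros((bsz, hidden))
    c = np.zeros((bsz, hidden))
    caches = []
    for t in range(length):
        xt = x[:, t, :]
        m = mask[:, t][:, None]
        gates = xt @ wx + h @ wh + b
        i = sigmoid(gates[:, :hidden])
        f = sigmoid(gates[:, hidden:2 * hidden])
        o = sigmoid(gates[:, 2 * hidden:3 * hidden])
        g = np.tanh(gates[:, 3 * hidden:])
        c_new = f * c + i * g
        tanh_c = np.tanh(c_new)
        h_new = o * tanh_c
        h_next = m * h_new + (1.0 - m) * h
        c_next = m * c_new + (1.0 - m) * c
        caches.append((xt, m, h, c, i, f, o, g, c_new, tanh_c))
        h, c = h_next, c_next
    return h, (caches, x.shape, hidden)


def lstm_backward(dh_last: np.ndarray, cache, wx: np.ndarray, wh: np.ndarray):
    """BPTT through :func:`lstm_forward`.  Returns (dx, dwx, dwh, db)."""
    caches, x_shape, hidden = cache
    bsz, length, dim = x_shape
    dx = np.zeros(x_shape)
    dwx = np.zeros_like(wx)
    dwh = np.zeros_like(wh)
    db = np.zeros(wx.shape[1])
    dh = dh_last.copy()
    dc = np.zeros((bsz, hidden))
    for t in range(length - 1, -1, -1):
        xt, m, h_prev, c_prev, i, f, o, g, c_new, tanh_c = caches[t]
        dh_new = m * dh
        dh_carry = (1.0 - m) * dh
        dc_new = m * dc
        dc_carry = (1.0 - m) * dc
        do = dh_new * tanh_c
        dc_total = dc_new + dh_new * o * (1.0 - tanh_c ** 2)
        di = dc_total * g
        df = dc_total * c_prev
        dg = dc_total * i
        dgates = np.concatenate([
            di * i * (1.0 - i),
            df * f * (1.0 - f),
            do * o * (1.0 - o),
            dg * (1.0 - g ** 2),
        ], axis=1)
        dx[:, t, :] = dgates @ wx.T
        dwx += xt.T @ dgates
        dwh += h_prev.T @ dgates
        db += dgates.sum(axis=0)
        dh = dh_carry + dgates @ wh.T
        dc = dc_carry + dc_total * f
    return dx, dwx, dwh, db
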