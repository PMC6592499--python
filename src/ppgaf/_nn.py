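"""Minimal NumPy neural-network engine for the two compact classifiers.

Implements exactly what the classifiers need — 1-D convolution (im2col),
ReLU, global average pooling, a dense head, a single-layer GRU, softmax
cross-entropy and Adam — with explicit backpropagation. Everything is
float32 and seeded, so training is reproducible on a fixed thread
configuration.
"""

from __future__ import annotations

import numpy as np

F32 = np.float32


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(probs: np.ndarray, y: np.ndarray) -> float:
    eps = 1e-12
    return float(-np.mean(np.log(probs[np.arange(len(y)), y] + eps)))


class Conv1d:
    """1-D convolution with 'same' padding and temporal stride (the
    downsampling step of each convolution block)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int, rng):
        scale = np.sqrt(2.0 / (c_in * kernel))
        self.w = (rng.standard_normal((c_out, c_in, kernel)) * scale).astype(F32)
        self.b = np.zeros(c_out, dtype=F32)
        self.stride = stride
        self.kernel = kernel

    @property
    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray):
        k, s = self.kernel, self.stride
        pad = k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
        out_len = (xp.shape[2] - k) // s + 1
        cols = np.lib.stride_tricks.sliding_window_view(xp, k, axis=2)[:, :, ::s, :]
        cols = np.ascontiguousarray(cols[:, :, :out_len, :])
        y = np.tensordot(cols, self.w, axes=([1, 3], [1, 2]))  # (N, L_out, C_out)
        y = y.transpose(0, 2, 1) + self.b[None, :, None]
        self._cache = (cols, x.shape[2])
        return y.astype(F32)

    def backward(self, dy: np.ndarray):
        cols, l_in = self._cache
        k, s = self.kernel, self.stride
        pad = k // 2
        # dy: (N, C_out, L_out)
        dw = np.tensordot(dy, cols, axes=([0, 2], [0, 2]))  # (C_out, C_in, K)
        db = dy.sum(axis=(0, 2))
        contrib = np.tensordot(dy.transpose(0, 2, 1), self.w, axes=([2], [0]))
        # contrib: (N, L_out, C_in, K)
        dxp = np.zeros((dy.shape[0], self.w.shape[1], l_in + 2 * pad), dtype=F32)
        pos = s * np.arange(dy.shape[2])
        for kk in range(k):
            np.add.at(dxp, (slice(None), slice(None), pos + kk), contrib[:, :, :, kk].transpose(0, 2, 1))
        dx = dxp[:, :, pad : pad + l_in]
        self.grads = [dw.astype(F32), db.astype(F32)]
        return dx


class Dense:
    """Classifier head. Zero-initialized so an untrained model outputs the
    uninformative softmax (confidence level 50%); symmetry is broken by the
    first gradient step."""

    def __init__(self, d_in: int, d_out: int, rng):
        self.w = np.zeros((d_in, d_out), dtype=F32)
        self.b = np.zeros(d_out, dtype=F32)

    @property
    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray):
        self._x = x
        return x @ self.w + self.b

    def backward(self, dy: np.ndarray):
        self.grads = [self._x.T @ dy, dy.sum(axis=0)]
        return dy @ self.w.T


class GRU:
    """Single-layer GRU over a token sequence; returns the final hidden state."""

    def __init__(self, d_in: int, hidden: int, rng):
        s_in = np.sqrt(1.0 / d_in)
        s_h = np.sqrt(1.0 / hidden)
        self.wx = (rng.standard_normal((d_in, 3 * hidden)) * s_in).astype(F32)
        self.wh = (rng.standard_normal((hidden, 3 * hidden)) * s_h).astype(F32)
        self.b = np.zeros(3 * hidden, dtype=F32)
        self.hidden = hidden

    @property
    def params(self):
        return [self.wx, self.wh, self.b]

    def forward(self, x: np.ndarray):
        # x: (N, T, D)
        n, t_steps, _ = x.shape
        h = np.zeros((n, self.hidden), dtype=F32)
        hs, zs, rs, cs, hhats = [], [], [], [], []
        gx_all = x @ self.wx + self.b  # (N, T, 3H)
        for t in range(t_steps):
            gh = h @ self.wh
            g = gx_all[:, t, :]
            hdim = self.hidden
            z = _sigmoid(g[:, :hdim] + gh[:, :hdim])
            r = _sigmoid(g[:, hdim : 2 * hdim] + gh[:, hdim : 2 * hdim])
            c = r * h  # gated previous state entering the candidate
            hhat = np.tanh(g[:, 2 * hdim :] + c @ self.wh[:, 2 * hdim :])
            hs.append(h)
            h = (1 - z) * h + z * hhat
            zs.append(z)
            rs.append(r)
            cs.append(c)
            hhats.append(hhat)
        self._cache = (x, hs, zs, rs, cs, hhats)
        return h

    def backward(self, dh: np.ndarray):
        x, hs, zs, rs, cs, hhats = self._cache
        n, t_steps, _ = x.shape
        hdim = self.hidden
        dwx = np.zeros_like(self.wx)
        dwh = np.zeros_like(self.wh)
        db = np.zeros_like(self.b)
        dx = np.zeros_like(x)
        dh = dh.astype(F32).copy()
        for t in range(t_steps - 1, -1, -1):
            h_prev, z, r, c, hhat = hs[t], zs[t], rs[t], cs[t], hhats[t]
            dz = dh * (hhat - h_prev) * z * (1 - z)
            dhhat = dh * z * (1 - hhat**2)
            dc = dhhat @ self.wh[:, 2 * hdim :].T
            dr = dc * h_prev * r * (1 - r)
            dg = np.concatenate([dz, dr, dhhat], axis=1)
            dwx += x[:, t, :].T @ dg
            db += dg.sum(axis=0)
            dwh[:, : 2 * hdim] += h_prev.T @ dg[:, : 2 * hdim]
            dwh[:, 2 * hdim :] += c.T @ dhhat
            dx[:, t, :] = dg @ self.wx.T
            dh = (
                dh * (1 - z)
                + dc * r
                + dg[:, : 2 * hdim] @ self.wh[:, : 2 * hdim].T
            )
        self.grads = [dwx, dwh, db]
        return dx


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return (1.0 / (1.0 + np.exp(-x))).astype(F32)


class Adam:
    def __init__(self, params: list[np.ndarray], lr: float = 1e-3):
        self.params = params
        self.lr = lr
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
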