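"""Numpy building blocks: LSTM/GRU layers, 1-D convolution, max-pool, Adam.

Recurrent layers read a (B, L, d) batch and return the final hidden state;
``backward`` consumes the gradient of that final state and returns the input
gradient plus parameter gradients.  Everything is float64 and fully
deterministic for a fixed seed.
"""

from __future__ import annotations

import numpy as np


def sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))


class Adam:
    def __init__(self, lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self._m: dict[str, np.ndarray] = {}
        self._v: dict[str, np.ndarray] = {}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for key, g in grads.items():
            p = params[key]
            if key not in self._m:
                self._m[key] = np.zeros_like(p)
                self._v[key] = np.zeros_like(p)
            m, v = self._m[key], self._v[key]
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class LSTMLayer:
    """Single-direction LSTM; gate order i, f, g, o; forget-gate bias 1."""

    def __init__(self, d_in: int, hidden: int, rng: np.random.Generator, name: str):
        s = 1.0 / np.sqrt(hidden)
        self.Wx = rng.uniform(-s, s, (d_in, 4 * hidden))
        self.Wh = rng.uniform(-s, s, (hidden, 4 * hidden))
        self.b = np.zeros(4 * hidden)
        self.b[hidden : 2 * hidden] = 1.0
        self.H = hidden
        self.name = name

    def params(self) -> dict[str, np.ndarray]:
        return {f"{self.name}.Wx": self.Wx, f"{self.name}.Wh": self.Wh, f"{self.name}.b": self.b}

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, L, _ = x.shape
        H = self.H
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        self._x = x
        self._cache = []
        for t in range(L):
            z = x[:, t] @ self.Wx + h @ self.Wh + self.b
            i = sigmoid(z[:, :H])
            f = sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = sigmoid(z[:, 3 * H :])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            self._cache.append((h, c, i, f, g, o, tc))
            h = o * tc
            c = c_new
        return h

    def backward(self, dh: np.ndarray) -> tuple[np.ndarray, dict[str, np.ndarray]]:
        x = self._x
        B, L, _ = x.shape
        dWx = np.zeros_like(self.Wx)
        dWh = np.zeros_like(self.Wh)
        db = np.zeros_like(self.b)
        dx = np.zeros_like(x)
        dc = np.zeros((B, self.H))
        for t in range(L - 1, -1, -1):
            h_prev, c_prev, i, f, g, o, tc = self._cache[t]
            dc = dc + dh * o * (1.0 - tc * tc)
            do = dh * tc
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g * g), do * o * (1 - o)], axis=1
            )
            dWx += x[:, t].T @ dz
            dWh += h_prev.T @ dz
            db += dz.sum(axis=0)
            dx[:, t] = dz @ self.Wx.T
            dh = dz @ self.Wh.T
            dc = dc * f
        grads = {f"{self.name}.Wx": dWx, f"{self.name}.Wh": dWh, f"{self.name}.b": db}
        return dx, grads


class GRULayer:
    """Single-direction GRU (reset gate applied after the hidden matmul)."""

    def __init__(self, d_in: int, hidden: int, rng: np.random.Generator, name: str):
        s = 1.0 / np.sqrt(hidden)
        self.Wx = rng.uniform(-s, s, (d_in, 3 * hidden))  # z, r, n blocks
        self.Wh = rng.uniform(-s, s, (hidden, 3 * hidden))
        self.b = np.zeros(3 * hidden)
        self.H = hidden
        self.name = name

    def params(self) -> dict[str, np.ndarray]:
        return {f"{self.name}.Wx": self.Wx, f"{self.name}.Wh": self.Wh, f"{self.name}.b": self.b}

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, L, _ = x.shape
        H = self.H
        h = np.zeros((B, H))
        self._x = x
        self._cache = []
        for t in range(L):
            zx = x[:, t] @ self.Wx + self.b
            zh = h @ self.Wh
            z = sigmoid(zx[:, :H] + zh[:, :H])
            r = sigmoid(zx[:, H : 2 * H] + zh[:, H : 2 * H])
            hh = zh[:, 2 * H :]
            n = np.tanh(zx[:, 2 * H :] + r * hh)
            h_new = (1 - z) * n + z * h
            self._cache.append((h, z, r, n, hh))
            h = h_new
        return h

    def backward(self, dh: np.ndarray) -> tuple[np.ndarray, dict[str, np.ndarray]]:
        x = self._x
        B, L, _ = x.shape
        H = self.H
        dWx = np.zeros_like(self.Wx)
        dWh = np.zeros_like(self.Wh)
        db = np.zeros_like(self.b)
        dx = np.zeros_like(x)
        for t in range(L - 1, -1, -1):
            h_prev, z, r, n, hh = self._cache[t]
            dn = dh * (1 - z)
            dz = dh * (h_prev - n)
            dh_prev = dh * z
            dn_pre = dn * (1 - n * n)
            dr = dn_pre * hh
            dhh = dn_pre * r
            dz_pre = dz * z * (1 - z)
            dr_pre = dr * r * (1 - r)
            dzx = np.concatenate([dz_pre, dr_pre, dn_pre], axis=1)
            dzh = np.concatenate([dz_pre, dr_pre, dhh], axis=1)
            dWx += x[:, t].T @ dzx
            db += dzx.sum(axis=0)
            dWh += h_prev.T @ dzh
            dx[:, t] = dzx @ self.Wx.T
            dh = dh_prev + dzh @ self.Wh.T
        grads = {f"{self.name}.Wx": dWx, f"{self.name}.Wh": dWh, f"{self.name}.b": db}
        return dx, grads


class Conv1D:
    """Valid 1-D convolution over time with ReLU, via an im2col matmul."""

    def __init__(self, d_in: int, filters: int, width: int, rng: np.random.Generator, name: str):
        s = np.sqrt(2.0 / (width * d_in))
        self.W = rng.normal(0.0, s, (width * d_in, filters))
        self.b = np.zeros(filters)
        self.width = width
        self.name = name

    def params(self) -> dict[str, np.ndarray]:
        return {f"{self.name}.W": self.W, f"{self.name}.b": self.b}

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, L, d = x.shape
        k = self.width
        if L < k:
            raise ValueError(f"sequence length {L} shorter than convolution width {k}")
        # windows: (B, T, k, d) -> (B, T, k*d)
        win = np.lib.stride_tricks.sliding_window_view(x, k, axis=1)  # B, T, d, k
        win = win.transpose(0, 1, 3, 2).reshape(B, L - k + 1, k * d)
        z = win @ self.W + self.b
        a = np.maximum(z, 0.0)
        self._win, self._mask, self._shape = win, z > 0, (B, L, d)
        return a

    def backward(self, da: np.ndarray) -> tuple[np.ndarray, dict[str, np.ndarray]]:
        B, L, d = self._shape
        k = self.width
        dz = da * self._mask
        T = dz.shape[1]
        dW = self._win.reshape(B * T, k * d).T @ dz.reshape(B * T, -1)
        db = dz.sum(axis=(0, 1))
        dwin = (dz @ self.W.T).reshape(B, T, k, d)
        dx = np.zeros((B, L, d))
        for j in range(k):
            dx[:, j : j + T] += dwin[:, :, j]
        return dx, {f"{self.name}.W": dW, f"{self.name}.b": db}


class MaxPool1D:
    """Non-overlapping temporal max pooling (trailing remainder dropped)."""

    def __init__(self, pool: int = 2):
        self.pool = pool

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, L, F = x.shape
        T = max(1, L // self.pool) if L >= self.pool else 1
        if L < self.pool:
            self._trivial = True
            self._shape = x.shape
            return x
        self._trivial = False
        trimmed = x[:, : T * self.pool].reshape(B, T, self.pool, F)
        self._arg = trimmed.argmax(axis=2)
        self._shape = x.shape
        return trimmed.max(axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._trivial:
            return dy
        B, L, F = self._shape
        T = dy.shape[1]
        dx = np.zeros((B, L, F))
        b_idx, t_idx, f_idx = np.meshgrid(
            np.arange(B), np.arange(T), np.arange(F), indexing="ij"
        )
        dx[b_idx, t_idx * self.pool + self._arg, f_idx] = dy
        return dx
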