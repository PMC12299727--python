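"""Minimal NumPy implementation of the conv + LSTM window classifier.

The network maps a scaled IMU window (T samples x C channels) to a single
event probability: a stack of valid 1-D convolutions with ReLU, an LSTM
over the remaining time steps, and a sigmoid read-out of the final hidden
state. Training is full backpropagation (through time for the LSTM) with
Adam on a class-weighted binary cross-entropy. Everything is seeded and
single-threaded, so runs are bit-reproducible.

Gradients are verified against central finite differences in the test
suite; keep any change to the backward passes covered by that check.
"""

from __future__ import annotations

import numpy as np


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int,
            fan_out: int) -> np.ndarray:
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, shape)


class Conv1D:
    """Valid 1-D convolution over (batch, time, channels) + ReLU."""

    def __init__(self, rng, c_in: int, c_out: int, kernel: int):
        self.kernel = kernel
        self.W = _glorot(rng, (kernel * c_in, c_out), kernel * c_in, c_out)
        self.b = np.zeros(c_out)

    def _patches(self, x: np.ndarray) -> np.ndarray:
        B, T, C = x.shape
        k = self.kernel
        idx = np.arange(T - k + 1)[:, None] + np.arange(k)[None, :]
        return x[:, idx, :].reshape(B, T - k + 1, k * C)

    def forward(self, x: np.ndarray):
        p = self._patches(x)
        z = p @ self.W + self.b
        y = np.maximum(z, 0.0)
        return y, (x.shape, p, z > 0)

    def backward(self, dy: np.ndarray, cache):
        (B, T, C), p, mask = cache
        dz = dy * mask
        self.dW = np.tensordot(p, dz, axes=([0, 1], [0, 1]))
        self.db = dz.sum(axis=(0, 1))
        dp = dz @ self.W.T  # (B, T-k+1, k*C)
        k = self.kernel
        dx = np.zeros((B, T, C))
        dp = dp.reshape(B, T - k + 1, k, C)
        for j in range(k):  # scatter-add each tap back onto the input grid
            dx[:, j:j + T - k + 1, :] += dp[:, :, j, :]
        return dx

    def params(self):
        return [("W", self), ("b", self)]


class LSTM:
    """Single-layer LSTM; returns the final hidden state."""

    def __init__(self, rng, c_in: int, hidden: int):
        self.hidden = hidden
        H = hidden
        self.Wx = _glorot(rng, (c_in, 4 * H), c_in, 4 * H)
        self.Wh = _glorot(rng, (H, 4 * H), H, 4 * H)
        self.b = np.zeros(4 * H)
        self.b[H:2 * H] = 1.0  # forget-gate bias

    def forward(self, x: np.ndarray):
        B, T, _ = x.shape
        H = self.hidden
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        steps = []
        for t in range(T):
            z = x[:, t, :] @ self.Wx + h @ self.Wh + self.b
            i = sigmoid(z[:, :H])
            f = sigmoid(z[:, H:2 * H])
            g = np.tanh(z[:, 2 * H:3 * H])
            o = sigmoid(z[:, 3 * H:])
            c_new = f * c + i * g
            tanh_c = np.tanh(c_new)
            steps.append((x[:, t, :], h, c, i, f, g, o, tanh_c))
            h, c = o * tanh_c, c_new
        return h, (x.shape, steps)

    def backward(self, dh_last: np.ndarray, cache):
        (B, T, C), steps = cache
        H = self.hidden
        self.dWx = np.zeros_like(self.Wx)
        self.dWh = np.zeros_like(self.Wh)
        self.db = np.zeros_like(self.b)
        dx = np.zeros((B, T, C))
        dh = dh_last
        dc = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            x_t, h_prev, c_prev, i, f, g, o, tanh_c = steps[t]
            do = dh * tanh_c
            dc = dc + dh * o * (1.0 - tanh_c ** 2)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate([
                di * i * (1 - i), df * f * (1 - f),
                dg * (1 - g ** 2), do * o * (1 - o)], axis=1)
            self.dWx += x_t.T @ dz
            self.dWh += h_prev.T @ dz
            self.db += dz.sum(axis=0)
            dx[:, t, :] = dz @ self.Wx.T
            dh = dz @ self.Wh.T
            dc = dc * f
        return dx

    def params(self):
        return [("Wx", self), ("Wh", self), ("b", self)]


class Dense:
    """Linear read-out to a single logit."""

    def __init__(self, rng, c_in: int):
        self.W = _glorot(rng, (c_in, 1), c_in, 1)
        self.b = np.zeros(1)

    def forward(self, x: np.ndarray):
        return (x @ self.W + self.b)[:, 0], x

    def backward(self, dz: np.ndarray, cache):
        x = cache
        dz = dz[:, None]
        self.dW = x.T @ dz
        self.db = dz.sum(axis=0)
        return dz @ self.W.T

    def params(self):
        return [("W", self), ("b", self)]


class ConvLSTMNet:
    """conv blocks -> LSTM -> sigmoid head, for (B, T, C) windows."""

    def __init__(self, n_channels: int, conv_channels=(16, 32), kernel: int = 5,
                 recurrent_units: int = 32, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.convs = []
        c = n_channels
        for width in conv_channels:
            self.convs.append(Conv1D(rng, c, width, kernel))
            c = width
        self.lstm = LSTM(rng, c, recurrent_units)
        self.head = Dense(rng, recurrent_units)
        self.layers = [*self.convs, self.lstm, self.head]

    # -- forward / backward ------------------------------------------------
    def logits(self, X: np.ndarray) -> np.ndarray:
        h = X
        for conv in self.convs:
            h, _ = conv.forward(h)
        h, _ = self.lstm.forward(h)
        z, _ = self.head.forward(h)
        return z

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return sigmoid(self.logits(X))

    def loss_and_grads(self, X: np.ndarray, y: np.ndarray,
                       pos_weight: float = 1.0, dropout: float = 0.0,
                       rng: np.random.Generator | None = None) -> float:
        """Class-weighted BCE; leaves gradients on each layer (d*).

        Inverted dropout (if requested) acts on the LSTM read-out.
        """
        caches = []
        h = X
        for conv in self.convs:
            h, cache = conv.forward(h)
            caches.append(cache)
        h, lstm_cache = self.lstm.forward(h)
        if dropout > 0.0:
            if rng is None:
                raise ValueError("dropout needs an rng")
            mask = (rng.random(h.shape) >= dropout) / (1.0 - dropout)
            h = h * mask
        z, head_cache = self.head.forward(h)
        w = np.where(y > 0.5, pos_weight, 1.0)
        # numerically stable BCE-with-logits
        loss = float(np.mean(w * (np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z))))))
        dz = w * (sigmoid(z) - y) / len(y)
        dh = self.head.backward(dz, head_cache)
        if dropout > 0.0:
            dh = dh * mask
        dh = self.lstm.backward(dh, lstm_cache)
        for conv, cache in zip(reversed(self.convs), reversed(caches)):
            dh = conv.backward(dh, cache)
        return loss

    # -- parameter access --------------------------------------------------
    def parameters(self):
        for layer in self.layers:
            for name, owner in layer.params():
                yield layer, name

    def get_weights(self) -> list[np.ndarray]:
        return [getattr(layer, name).copy() for layer, name in self.parameters()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for (layer, name), w in zip(self.parameters(), weights):
            getattr(layer, name)[...] = w


class Adam:
    def __init__(self, net: ConvLSTMNet, lr: float = 3e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.net, self.lr, self.b1, self.b2, self.eps = net, lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(getattr(l, n)) for l, n in net.parameters()]
        self.v = [np.zeros_like(g) for g in self.m]

    def step(self) -> None:
        self.t += 1
        for k, (layer, name) in enumerate(self.net.parameters()):
            g = getattr(layer, "d" + name)
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            getattr(layer, name)[...] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
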