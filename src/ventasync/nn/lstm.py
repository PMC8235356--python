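"""Two-layer LSTM baseline for per-breath sequence classification.

Consumes length-224, 3-channel resampled/normalized breath sequences and
emits two-class logits from the last time step.  Forward and full
backpropagation through time are implemented in NumPy; the parameter
count per layer follows the standard 4*(u*(u+i)+u) form.
"""

from __future__ import annotations

import numpy as np

from .layers import Layer, Dense


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


class LSTMLayer(Layer):
    """Single LSTM layer, batch-major input (N, T, I) -> (N, T, U)."""

    def __init__(self, input_dim, units, rng=None, name=""):
        rng = rng or np.random.default_rng(0)
        self.input_dim, self.units = input_dim, units
        k = np.sqrt(1.0 / units)
        # gate order: input, forget, cell, output
        self.wx = rng.uniform(-k, k, (input_dim, 4 * units)).astype(np.float32)
        self.wh = rng.uniform(-k, k, (units, 4 * units)).astype(np.float32)
        self.b = np.zeros(4 * units, np.float32)
        self.b[units:2 * units] = 1.0  # forget-gate bias
        self.name = name
        self._grads = {}

    @property
    def params(self):
        return {"wx": self.wx, "wh": self.wh, "b": self.b}

    def forward(self, x, training=False):
        n, t, _ = x.shape
        u = self.units
        dt = np.result_type(x.dtype, self.wx.dtype)
        h = np.zeros((n, u), dt)
        c = np.zeros((n, u), dt)
        hs = np.empty((n, t, u), dt)
        if training:
            cache = []
        for step in range(t):
            z = x[:, step] @ self.wx + h @ self.wh + self.b
            i, f, g, o = (z[:, :u], z[:, u:2 * u], z[:, 2 * u:3 * u], z[:, 3 * u:])
            i, f, o = _sigmoid(i), _sigmoid(f), _sigmoid(o)
            g = np.tanh(g)
            c_prev = c
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h_prev = h
            h = o * tc
            hs[:, step] = h
            if training:
                cache.append((x[:, step], h_prev, c_prev, i, f, g, o, tc))
        if training:
            self._cache = cache
        return hs

    def backward(self, grad):
        """``grad`` is dL/dh over all time steps, shape (N, T, U)."""
        cache = self._cache
        n, t, u = grad.shape
        dwx = np.zeros_like(self.wx)
        dwh = np.zeros_like(self.wh)
        db = np.zeros_like(self.b)
        dx = np.empty((n, t, self.input_dim), grad.dtype)
        dh_next = np.zeros((n, u), grad.dtype)
        dc_next = np.zeros((n, u), grad.dtype)
        for step in reversed(range(t)):
            xt, h_prev, c_prev, i, f, g, o, tc = cache[step]
            dh = grad[:, step] + dh_next
            do = dh * tc * o * (1 - o)
            dc = dh * o * (1 - tc * tc) + dc_next
            di = dc * g * i * (1 - i)
            df = dc * c_prev * f * (1 - f)
            dg = dc * i * (1 - g * g)
            dz = np.concatenate([di, df, dg, do], axis=1)
            dwx += xt.T @ dz
            dwh += h_prev.T @ dz
            db += dz.sum(0)
            dx[:, step] = dz @ self.wx.T
            dh_next = dz @ self.wh.T
            dc_next = dc * f
        self._grads = {"wx": dwx, "wh": dwh, "b": db}
        return dx


class _LastStep(Layer):
    trainable = False

    def forward(self, x, training=False):
        if training:
            self._shape = x.shape
        return x[:, -1]

    def backward(self, grad):
        out = np.zeros(self._shape, grad.dtype)
        out[:, -1] = grad
        return out


class LSTMClassifier:
    """Two stacked LSTM layers plus a dense softmax head."""

    def __init__(self, input_dim=3, units=32, n_classes=2, seed=0):
        rng = np.random.default_rng(seed)
        self.lstm1 = LSTMLayer(input_dim, units, rng=rng, name="lstm1")
        self.lstm2 = LSTMLayer(units, units, rng=rng, name="lstm2")
        self.last = _LastStep()
        self.head = Dense(units, n_classes, rng=rng, name="head")
        self.layers = [self.lstm1, self.lstm2, self.last, self.head]

    @property
    def recurrent_layers(self):
        return [self.lstm1, self.lstm2]

    def forward(self, x, training=False):
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def n_params(self):
        from .network import count_params
        return count_params(self.layers)

    def param_tensors(self, trainable_only=True):
        return [(l, n, a) for l in self.layers if l.trainable
                for n, a in l.params.items()]

    def state(self):
        return [(l, n, a.copy()) for l in self.layers
                for n, a in l.params.items()]

    @staticmethod
    def restore(state):
        for layer, name, arr in state:
            layer.params[name][:] = arr
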