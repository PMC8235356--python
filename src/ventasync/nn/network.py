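"""Containers: Sequential chains and a branching block graph for the
inception-style extractor."""

from __future__ import annotations

import numpy as np

from .layers import Layer, Concat


def count_params(layers) -> int:
    """Total parameter elements (trainable + statistics) over layers."""
    return int(sum(l.n_params() for l in _flatten(layers)))


def _flatten(obj):
    if isinstance(obj, Layer):
        yield obj
    elif isinstance(obj, (list, tuple)):
        for o in obj:
            yield from _flatten(o)
    elif hasattr(obj, "layers"):
        yield from _flatten(obj.layers)
    else:
        raise TypeError(f"cannot flatten {type(obj)!r}")


class Sequential:
    """A chain of layers with full forward/backward support."""

    def __init__(self, layers, name=""):
        self.layers = list(layers)
        self.name = name

    def forward(self, x, training=False):
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def n_params(self):
        return count_params(self.layers)

    def param_tensors(self, trainable_only=True):
        """Flat list of (layer, name, array) for the optimizer."""
        out = []
        for layer in _flatten(self.layers):
            if trainable_only and not layer.trainable:
                continue
            for name, arr in layer.params.items():
                if trainable_only and name in ("moving_mean", "moving_var"):
                    continue
                out.append((layer, name, arr))
        return out

    def state(self):
        """Deep copy of every parameter array (for snapshots/restores)."""
        return [(l, n, a.copy()) for l, n, a in
                ((l, n, a) for l in _flatten(self.layers)
                 for n, a in l.params.items())]

    @staticmethod
    def restore(state):
        for layer, name, arr in state:
            layer.params[name][:] = arr


class Branch:
    """Parallel sub-chains whose outputs are channel-concatenated.

    Forward-only; used by the inception-residual extractor.
    """

    def __init__(self, branches, name=""):
        self.layers = [Sequential(b) if isinstance(b, (list, tuple)) else b
                       for b in branches]
        self.name = name
        self._concat = Concat()

    def forward(self, x, training=False):
        return self._concat.forward(
            [b.forward(x, training=training) for b in self.layers])

    def backward(self, grad):
        raise NotImplementedError("branching blocks are forward-only")

    def n_params(self):
        return count_params(self.layers)


class Residual:
    """x + scale * f(x), with optional output activation (forward-only)."""

    def __init__(self, inner, scale=1.0, activate=True, name=""):
        self.inner = inner
        self.scale = scale
        self.activate = activate
        self.name = name

    @property
    def layers(self):
        return self.inner.layers if hasattr(self.inner, "layers") else [self.inner]

    def forward(self, x, training=False):
        out = x + self.scale * self.inner.forward(x, training=training)
        if self.activate:
            out = np.maximum(out, 0)
        return out

    def backward(self, grad):
        raise NotImplementedError("residual blocks are forward-only")

    def n_params(self):
        return count_params(self.layers)
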