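"""Minimal CNN engine (numpy) for the patch detector and the desk backbone.

Implements exactly the layer vocabulary the pipeline's networks need —
valid-mode 3x3 convolution, ReLU, 2x2 max pooling, dense layers, softmax
cross-entropy — trained with stochastic gradient descent with momentum
("sgdm").  Convolutions run as im2col matrix products; the backward pass for
the input gradient is a full correlation with the flipped kernels, so both
directions are single BLAS calls per layer.

Layers carry an ``lr_scale`` so a freshly attached classification head can
learn faster than pretrained body layers (the usual fine-tuning trick).
Everything is deterministic given the seed of the generator passed in.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Conv2D", "ReLU", "MaxPool2", "Flatten", "Dense", "Net", "sgdm_fit"]


class Layer:
    lr_scale: float = 1.0

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def params_grads(self):
        return []


class Conv2D(Layer):
    """Valid 3x3 (or kxk) convolution, stride 1, NHWC layout."""

    def __init__(self, in_ch: int, out_ch: int, ksize: int = 3, rng=None,
                 dtype=np.float32, lr_scale: float = 1.0):
        rng = rng or np.random.default_rng(0)
        fan_in = ksize * ksize * in_ch
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            size=(ksize, ksize, in_ch, out_ch)).astype(dtype)
        self.b = np.zeros(out_ch, dtype=dtype)
        self.ksize = ksize
        self.lr_scale = lr_scale
        self._vw = np.zeros_like(self.w)
        self._vb = np.zeros_like(self.b)

    def forward(self, x):
        # conv as k*k shifted matrix products: no im2col buffer, and every
        # implicit copy is of contiguous row segments
        self._x = x
        k = self.ksize
        n, h, w_, _c = x.shape
        oh, ow = h - k + 1, w_ - k + 1
        f = self.w.shape[-1]
        c = x.shape[-1]
        out = np.empty((n * oh * ow, f), dtype=x.dtype)
        out[...] = self.b
        for dy in range(k):
            for dx in range(k):
                xs = x[:, dy : dy + oh, dx : dx + ow, :].reshape(-1, c)
                out += xs @ self.w[dy, dx]
        return out.reshape(n, oh, ow, f)

    def backward(self, grad):
        x = self._x
        k = self.ksize
        n, oh, ow, f = grad.shape
        c = x.shape[-1]
        g2 = grad.reshape(-1, f)
        self.dw = np.empty_like(self.w)
        dxp = np.zeros_like(x)
        for dy in range(k):
            for dx in range(k):
                xs = x[:, dy : dy + oh, dx : dx + ow, :].reshape(-1, c)
                self.dw[dy, dx] = xs.T @ g2 / n
                dxp[:, dy : dy + oh, dx : dx + ow, :] += (g2 @ self.w[dy, dx].T
                                                          ).reshape(n, oh, ow, c)
        self.db = g2.sum(axis=0) / n
        return dxp

    def params_grads(self):
        return [(self.w, "dw", self._vw), (self.b, "db", self._vb)]


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class MaxPool2(Layer):
    """2x2 max pooling, stride 2; odd trailing rows/cols are dropped."""

    def forward(self, x):
        n, h, w, c = x.shape
        h2, w2 = h // 2, w // 2
        xc = x[:, : h2 * 2, : w2 * 2]
        self._xr = xc.reshape(n, h2, 2, w2, 2, c)
        out = self._xr.max(axis=(2, 4))
        self._out = out
        self._in_shape = x.shape
        return out

    def backward(self, grad):
        n, h, w, c = self._in_shape
        h2, w2 = h // 2, w // 2
        winners = self._xr == self._out[:, :, None, :, None, :]
        counts = winners.sum(axis=(2, 4), keepdims=True)
        g = winners * (grad[:, :, None, :, None, :] / counts)
        dx = np.zeros(self._in_shape, dtype=grad.dtype)
        dx[:, : h2 * 2, : w2 * 2] = g.reshape(n, h2 * 2, w2 * 2, c)
        return dx


class Flatten(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng=None, dtype=np.float32,
                 lr_scale: float = 1.0):
        rng = rng or np.random.default_rng(0)
        self.w = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out)).astype(dtype)
        self.b = np.zeros(n_out, dtype=dtype)
        self.lr_scale = lr_scale
        self._vw = np.zeros_like(self.w)
        self._vb = np.zeros_like(self.b)

    def forward(self, x):
        self._x = x
        return x @ self.w + self.b

    def backward(self, grad):
        n = grad.shape[0]
        self.dw = self._x.T @ grad / n
        self.db = grad.sum(axis=0) / n
        return grad @ self.w.T

    def params_grads(self):
        return [(self.w, "dw", self._vw), (self.b, "db", self._vb)]


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class Net:
    """A plain layer stack with softmax cross-entropy training."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def predict_proba(self, x: np.ndarray, batch_size: int = 512) -> np.ndarray:
        out = []
        for i in range(0, len(x), batch_size):
            out.append(_softmax(self.forward(x[i : i + batch_size])))
        return np.concatenate(out, axis=0)

    def loss_and_backward(self, x: np.ndarray, y: np.ndarray) -> float:
        """Mean cross-entropy on a batch; leaves gradients on the layers."""
        logits = self.forward(x)
        p = _softmax(logits)
        n = x.shape[0]
        loss = -np.log(np.clip(p[np.arange(n), y], 1e-12, None)).mean()
        grad = p.astype(logits.dtype)
        grad[np.arange(n), y] -= 1.0
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return float(loss)

    def penultimate(self, x: np.ndarray, n_tail: int, batch_size: int = 256) -> np.ndarray:
        """Activations just before the last ``n_tail`` layers."""
        out = []
        for i in range(0, len(x), batch_size):
            h = x[i : i + batch_size]
            for layer in self.layers[: len(self.layers) - n_tail]:
                h = layer.forward(h)
            out.append(h)
        return np.concatenate(out, axis=0)

    # --- persistence -----------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        arrays = {}
        for i, layer in enumerate(self.layers):
            for name in ("w", "b"):
                if hasattr(layer, name):
                    arrays[f"layer{i}_{name}"] = getattr(layer, name)
        return arrays

    def load_state_arrays(self, arrays) -> None:
        for i, layer in enumerate(self.layers):
            for name in ("w", "b"):
                key = f"layer{i}_{name}"
                if key in arrays:
                    getattr(layer, name)[...] = arrays[key]


def sgdm_fit(
    net: Net,
    x: np.ndarray,
    y: np.ndarray,
    schedule: list[tuple[float, int]],
    batch_size: int,
    rng: np.random.Generator,
    momentum: float = 0.9,
    verbose: bool = False,
) -> list[float]:
    """SGD-with-momentum training over a ``[(lr, epochs), ...]`` schedule.

    Returns the per-epoch mean losses.  Layer ``lr_scale`` multiplies the
    phase learning rate (used to boost a new classification head).
    """
    n = len(x)
    losses = []
    for lr, epochs in schedule:
        for _epoch in range(epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            nb = 0
            for i in range(0, n, batch_size):
                idx = order[i : i + batch_size]
                epoch_loss += net.loss_and_backward(x[idx], y[idx])
                nb += 1
                for layer in net.layers:
                    for w, gname, v in layer.params_grads():
                        g = getattr(layer, gname)
                        v *= momentum
                        v -= (lr * layer.lr_scale) * g
                        w += v
            losses.append(epoch_loss / max(nb, 1))
            if verbose:
                print(f"epoch {len(losses)}: loss {losses[-1]:.4f}")
    return losses
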