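"""Two small convolutional networks for 16x36 perfusion matrices, in NumPy.

CNN 1: conv(64 filters, 5x5, ReLU) -> global average pooling ->
dense(256, ReLU) -> dense(2, softmax); ~19k trainable parameters,
independent of the convolution padding.

CNN 2: conv(64, 5x5, ReLU) -> 2x2 max-pool -> conv(128, 3x3, ReLU) ->
2x2 max-pool -> flatten -> dense(256, ReLU) -> dense(2, softmax);
~535k trainable parameters with unpadded ("valid") convolutions.

Training uses the Adam optimizer, categorical cross-entropy, and a combined
L1+L2 penalty on the kernels.  The networks and input images are small
enough that a plain NumPy implementation (im2col convolutions,
explicit backprop) trains in seconds per epoch; everything is seeded for
bit-reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import ConfigurationError, TrainingError

INPUT_SHAPE = (16, 36, 1)


@dataclass
class CnnSpec:
    """Architecture + training hyperparameters of one CNN run."""

    architecture: str = "cnn1"  # "cnn1" | "cnn2"
    epochs: int = 50
    learning_rate: float = 1e-3
    batch_size: int = 32
    l1: float = 1e-5
    l2: float = 1e-5
    padding: str = "valid"  # "valid" | "same" (CNN1 only; CNN2 is unpadded)
    seed: int = 0

    def __post_init__(self):
        if self.architecture not in ("cnn1", "cnn2"):
            raise ConfigurationError(f"unknown architecture {self.architecture!r}")
        if self.padding not in ("valid", "same"):
            raise ConfigurationError(f"unknown padding {self.padding!r}")
        if self.epochs <= 0 or self.batch_size <= 0 or self.learning_rate <= 0:
            raise ConfigurationError("epochs, batch_size and learning_rate must be positive")


# --------------------------------------------------------------------------
# layers


class _Layer:
    params: list
    grads: list

    def __init__(self):
        self.params, self.grads = [], []

    def forward(self, x, train=False):
        raise NotImplementedError

    def backward(self, dy):
        raise NotImplementedError


class Conv2D(_Layer):
    def __init__(self, in_ch, filters, kernel, padding, rng):
        super().__init__()
        kh, kw = kernel
        fan_in, fan_out = kh * kw * in_ch, kh * kw * filters
        limit = np.sqrt(6.0 / (fan_in + fan_out))  # Glorot uniform
        self.w = rng.uniform(-limit, limit, size=(kh * kw * in_ch, filters))
        self.b = np.zeros(filters)
        self.kernel = kernel
        self.in_ch = in_ch
        self.padding = padding
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]
        self.regularized = [True, False]

    def _pad(self, x):
        if self.padding == "valid":
            return x, (0, 0)
        kh, kw = self.kernel
        ph, pw = (kh - 1) // 2, (kw - 1) // 2
        ph2, pw2 = kh - 1 - ph, kw - 1 - pw
        return np.pad(x, ((0, 0), (ph, ph2), (pw, pw2), (0, 0))), (ph, pw)

    def forward(self, x, train=False):
        xp, _ = self._pad(x)
        kh, kw = self.kernel
        win = sliding_window_view(xp, (kh, kw), axis=(1, 2))  # (N,H',W',C,kh,kw)
        patches = np.moveaxis(win, 3, 5)  # (N,H',W',kh,kw,C)
        self._cache = (patches, x.shape, xp.shape)
        n, ho, wo = patches.shape[:3]
        flat = patches.reshape(n * ho * wo, -1)
        out = flat @ self.w + self.b
        return out.reshape(n, ho, wo, -1)

    def backward(self, dy):
        patches, x_shape, xp_shape = self._cache
        n, ho, wo = patches.shape[:3]
        kh, kw = self.kernel
        dy_flat = dy.reshape(n * ho * wo, -1)
        self.grads[0][...] = patches.reshape(n * ho * wo, -1).T @ dy_flat
        self.grads[1][...] = dy_flat.sum(axis=0)
        dpatch = (dy_flat @ self.w.T).reshape(n, ho, wo, kh, kw, self.in_ch)
        dxp = np.zeros(xp_shape)
        for i in range(kh):
            for j in range(kw):
                dxp[:, i : i + ho, j : j + wo, :] += dpatch[:, :, :, i, j, :]
        if self.padding == "valid":
            return dxp
        ph = (kh - 1) // 2
        pw = (kw - 1) // 2
        return dxp[:, ph : ph + x_shape[1], pw : pw + x_shape[2], :]


class ReLU(_Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class MaxPool2x2(_Layer):
    def forward(self, x, train=False):
        n, h, w, c = x.shape
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c)
        out = xr.max(axis=(2, 4))
        winners = xr == out[:, :, None, :, None, :]
        # split gradient equally among tied maxima
        self._dist = winners / winners.sum(axis=(2, 4), keepdims=True)
        self._shape = x.shape
        return out

    def backward(self, dy):
        dyr = dy[:, :, None, :, None, :] * self._dist
        return dyr.reshape(self._shape)


class GlobalAvgPool(_Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dy):
        n, h, w, c = self._shape
        return np.broadcast_to(dy[:, None, None, :], self._shape) / (h * w)


class Flatten(_Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Dense(_Layer):
    def __init__(self, n_in, n_out, rng):
        super().__init__()
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.w = rng.uniform(-limit, limit, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]
        self.regularized = [True, False]

    def forward(self, x, train=False):
        self._x = x
        return x @ self.w + self.b

    def backward(self, dy):
        self.grads[0][...] = self._x.T @ dy
        self.grads[1][...] = dy.sum(axis=0)
        return dy @ self.w.T


def _softmax(z):
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


# --------------------------------------------------------------------------
# network


class NumpyCNN:
    """Sequential conv-net with softmax head and Adam training."""

    def __init__(self, spec: CnnSpec):
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        h, w, c = INPUT_SHAPE
        layers: list[_Layer] = []
        if spec.architecture == "cnn1":
            layers += [Conv2D(c, 64, (5, 5), spec.padding, rng), ReLU(), GlobalAvgPool()]
            flat = 64
        else:
            layers += [Conv2D(c, 64, (5, 5), "valid", rng), ReLU(), MaxPool2x2()]
            layers += [Conv2D(64, 128, (3, 3), "valid", rng), ReLU(), MaxPool2x2(), Flatten()]
            h1, w1 = (h - 4) // 2, (w - 4) // 2  # after conv5x5 valid + pool
            h2, w2 = (h1 - 2) // 2, (w1 - 2) // 2  # after conv3x3 valid + pool
            flat = h2 * w2 * 128
        layers += [Dense(flat, 256, rng), ReLU(), Dense(256, 2, rng)]
        self.layers = layers
        self._rng = rng
        self.loss_history_: list[float] = []

    # -- inference ---------------------------------------------------------
    def _logits(self, x, train=False):
        out = np.asarray(x, dtype=float)
        if out.ndim == 3:
            out = out[..., None]
        for layer in self.layers:
            out = layer.forward(out, train=train)
        return out

    def predict_proba(self, x) -> np.ndarray:
        """Softmax class probabilities, shape (n, 2); column 1 is the event class."""
        return _softmax(self._logits(x))

    # -- training ----------------------------------------------------------
    def _param_list(self):
        out = []
        for layer in self.layers:
            for p, g, reg in zip(
                layer.params, layer.grads, getattr(layer, "regularized", [False] * len(layer.params))
            ):
                out.append((p, g, reg))
        return out

    def fit(self, x, y, *, epochs: int | None = None, verbose: bool = False) -> "NumpyCNN":
        """Train with Adam on categorical cross-entropy + L1/L2 kernel penalty.

        ``y`` is a vector of 0/1 class labels.  All randomness (batch
        shuffling) comes from the spec seed, so identical calls reproduce
        identical weights.
        """
        spec = self.spec
        epochs = spec.epochs if epochs is None else epochs
        x = np.asarray(x, dtype=float)
        if x.ndim == 3:
            x = x[..., None]
        y = np.asarray(y, dtype=int)
        n = len(x)
        onehot = np.eye(2)[y]

        params = self._param_list()
        m = [np.zeros_like(p) for p, _, _ in params]
        v = [np.zeros_like(p) for p, _, _ in params]
        beta1, beta2, eps = 0.9, 0.999, 1e-7
        t = 0

        for epoch in range(epochs):
            order = self._rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, spec.batch_size):
                idx = order[start : start + spec.batch_size]
                xb, yb = x[idx], onehot[idx]
                logits = self._logits(xb, train=True)
                probs = _softmax(logits)
                data_loss = float(-(yb * np.log(probs + 1e-12)).sum() / len(idx))
                if not np.isfinite(data_loss):
                    raise TrainingError(f"non-finite loss at epoch {epoch + 1}")
                epoch_loss += data_loss * len(idx)

                dlogits = (probs - yb) / len(idx)
                grad = dlogits
                for layer in reversed(self.layers):
                    grad = layer.backward(grad)

                t += 1
                for k, (p, g, reg) in enumerate(params):
                    gk = g.copy()
                    if reg:
                        gk += spec.l2 * 2.0 * p + spec.l1 * np.sign(p)
                    m[k] = beta1 * m[k] + (1 - beta1) * gk
                    v[k] = beta2 * v[k] + (1 - beta2) * gk**2
                    mhat = m[k] / (1 - beta1**t)
                    vhat = v[k] / (1 - beta2**t)
                    p -= spec.learning_rate * mhat / (np.sqrt(vhat) + eps)
            self.loss_history_.append(epoch_loss / n)
            if verbose:
                print(f"epoch {epoch + 1}/{epochs}: loss {self.loss_history_[-1]:.4f}")
        return self


def build_cnn(spec: CnnSpec) -> NumpyCNN:
    """Instantiate the network described by ``spec`` (weights seeded)."""
    return NumpyCNN(spec)


def count_trainable_parameters(net: NumpyCNN) -> int:
    """Total number of trainable weights and biases."""
    return int(sum(p.size for p, _, _ in net._param_list()))


def train_cnn(net: NumpyCNN, matrices, labels, *, epochs: int | None = None) -> NumpyCNN:
    """Train on a (typically augmented) list of matrices with 0/1 labels."""
    x = np.stack([m.values if hasattr(m, "values") else np.asarray(m, float) for m in matrices])
    return net.fit(x, labels, epochs=epochs)
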