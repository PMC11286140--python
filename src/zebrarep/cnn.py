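"""A compact convolutional network for spectrogram classification.

Implemented directly on numpy: two convolution + ReLU + max-pooling
blocks, one dense hidden layer with dropout, and a softmax output, trained
with Adam on the cross-entropy loss with early stopping on a validation
split. The footprint (a few thousand parameters on a 32 x 32 input) is
sized for call-type classification of prepared mel-spectrograms, where the
classes differ in coarse time-frequency structure rather than fine detail.

Runs are deterministic for a fixed seed: parameter initialization, batch
order and dropout masks all come from one :class:`numpy.random.Generator`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class CNNConfig:
    n_classes: int = 4
    input_shape: tuple[int, int] = (32, 32)
    filters: tuple[int, int] = (8, 16)
    kernel: int = 3
    dense_width: int = 32
    dropout: float = 0.25
    learning_rate: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 60
    patience: int = 8
    seed: int = 0


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(n, c, h, w) -> (n, h_out*w_out, c*k*k) patches, valid padding."""
    n, c, h, w = x.shape
    ho, wo = h - k + 1, w - k + 1
    s = x.strides
    patches = np.lib.stride_tricks.as_strided(
        x, shape=(n, c, ho, wo, k, k),
        strides=(s[0], s[1], s[2], s[3], s[2], s[3]), writeable=False)
    return patches.transpose(0, 2, 3, 1, 4, 5).reshape(n, ho * wo, c * k * k)


class _ConvLayer:
    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * k * k))
        self.W = rng.normal(0, scale, size=(c_out, c_in * k * k))
        self.b = np.zeros(c_out)
        self.k, self.c_in, self.c_out = k, c_in, c_out

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        ho, wo = h - self.k + 1, w - self.k + 1
        self._x_shape = x.shape
        self._cols = _im2col(x, self.k)                       # (n, P, ckk)
        out = self._cols @ self.W.T + self.b                  # (n, P, c_out)
        return out.transpose(0, 2, 1).reshape(n, self.c_out, ho, wo)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c_out, ho, wo = grad.shape
        g = grad.reshape(n, c_out, ho * wo).transpose(0, 2, 1)  # (n, P, c_out)
        self.dW = np.einsum("npo,npk->ok", g, self._cols)
        self.db = g.sum(axis=(0, 1))
        dcols = g @ self.W                                    # (n, P, ckk)
        # col2im (accumulate overlapping patches)
        _, c_in, h, w = self._x_shape
        k = self.k
        dx = np.zeros(self._x_shape)
        dcols = dcols.reshape(n, ho, wo, c_in, k, k)
        for di in range(k):
            for dj in range(k):
                dx[:, :, di:di + ho, dj:dj + wo] += dcols[:, :, :, :, di, dj].transpose(0, 3, 1, 2)
        return dx


def _maxpool(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n, c, h, w = x.shape
    h2, w2 = h // 2, w // 2
    xv = x[:, :, : h2 * 2, : w2 * 2].reshape(n, c, h2, 2, w2, 2)
    flat = xv.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h2, w2, 4)
    idx = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
    return out, idx


def _maxpool_backward(grad: np.ndarray, idx: np.ndarray,
                      in_shape: tuple[int, ...]) -> np.ndarray:
    n, c, h, w = in_shape
    h2, w2 = grad.shape[2], grad.shape[3]
    flat = np.zeros((n, c, h2, w2, 4))
    np.put_along_axis(flat, idx[..., None], grad[..., None], axis=-1)
    dx = np.zeros(in_shape)
    dx[:, :, : h2 * 2, : w2 * 2] = (
        flat.reshape(n, c, h2, w2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        .reshape(n, c, h2 * 2, w2 * 2))
    return dx


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    best_epoch: int = 0


class SmallCNN:
    """Two conv+pool blocks, one dense hidden layer, softmax output."""

    def __init__(self, config: CNNConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        c = config
        self.conv1 = _ConvLayer(1, c.filters[0], c.kernel, rng)
        self.conv2 = _ConvLayer(c.filters[0], c.filters[1], c.kernel, rng)
        h, w = c.input_shape
        h1, w1 = (h - c.kernel + 1) // 2, (w - c.kernel + 1) // 2
        h2, w2 = (h1 - c.kernel + 1) // 2, (w1 - c.kernel + 1) // 2
        self._flat = c.filters[1] * h2 * w2
        self.W1 = rng.normal(0, np.sqrt(2.0 / self._flat), size=(self._flat, c.dense_width))
        self.b1 = np.zeros(c.dense_width)
        self.W2 = rng.normal(0, np.sqrt(2.0 / c.dense_width), size=(c.dense_width, c.n_classes))
        self.b2 = np.zeros(c.n_classes)
        self._rng = rng
        self._adam: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        self._adam_t = 0

    # -- forward / backward ------------------------------------------------
    def _forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        z1 = self.conv1.forward(x)
        a1 = np.maximum(z1, 0)
        p1, self._i1 = _maxpool(a1)
        z2 = self.conv2.forward(p1)
        a2 = np.maximum(z2, 0)
        p2, self._i2 = _maxpool(a2)
        self._shapes = (z1.shape, a1.shape, z2.shape, a2.shape, p1.shape, p2.shape)
        self._masks = (z1 > 0, z2 > 0)
        flat = p2.reshape(len(x), -1)
        h = np.maximum(flat @ self.W1 + self.b1, 0)
        if train and self.config.dropout > 0:
            keep = 1.0 - self.config.dropout
            self._drop = (self._rng.random(h.shape) < keep) / keep
            h = h * self._drop
        else:
            self._drop = None
        logits = h @ self.W2 + self.b2
        self._cache = (flat, h)
        logits = logits - logits.max(axis=1, keepdims=True)
        p = np.exp(logits)
        return p / p.sum(axis=1, keepdims=True)

    def _backward(self, x: np.ndarray, probs: np.ndarray, y: np.ndarray) -> dict:
        n = len(x)
        flat, h = self._cache
        dlogits = probs.copy()
        dlogits[np.arange(n), y] -= 1.0
        dlogits /= n
        grads = {}
        grads["W2"] = h.T @ dlogits
        grads["b2"] = dlogits.sum(axis=0)
        dh = dlogits @ self.W2.T
        if self._drop is not None:
            dh = dh * self._drop
        dh = dh * (h > 0)
        grads["W1"] = flat.T @ dh
        grads["b1"] = dh.sum(axis=0)
        dflat = dh @ self.W1.T
        z1s, a1s, z2s, a2s, p1s, p2s = self._shapes
        dp2 = dflat.reshape(p2s)
        da2 = _maxpool_backward(dp2, self._i2, a2s)
        dz2 = da2 * self._masks[1]
        dp1 = self.conv2.backward(dz2)
        da1 = _maxpool_backward(dp1, self._i1, a1s)
        dz1 = da1 * self._masks[0]
        self.conv1.backward(dz1)
        grads["conv1.W"], grads["conv1.b"] = self.conv1.dW, self.conv1.db
        grads["conv2.W"], grads["conv2.b"] = self.conv2.dW, self.conv2.db
        return grads

    def _params(self) -> dict[str, np.ndarray]:
        return {"W1": self.W1, "b1": self.b1, "W2": self.W2, "b2": self.b2,
                "conv1.W": self.conv1.W, "conv1.b": self.conv1.b,
                "conv2.W": self.conv2.W, "conv2.b": self.conv2.b}

    def _adam_step(self, grads: dict[str, np.ndarray]) -> None:
        lr, b1, b2, eps = self.config.learning_rate, 0.9, 0.999, 1e-8
        self._adam_t += 1
        t = self._adam_t
        for name, p in self._params().items():
            g = grads[name]
            m, v = self._adam.get(name, (np.zeros_like(p), np.zeros_like(p)))
            m = b1 * m + (1 - b1) * g
            v = b2 * v + (1 - b2) * g * g
            self._adam[name] = (m, v)
            mhat = m / (1 - b1**t)
            vhat = v / (1 - b2**t)
            p -= lr * mhat / (np.sqrt(vhat) + eps)

    # -- public API --------------------------------------------------------
    def fit(self, X_train: np.ndarray, y_train: np.ndarray,
            X_val: np.ndarray, y_val: np.ndarray) -> TrainHistory:
        """Train with Adam and early stopping on validation loss.

        X arrays are (n, h, w) in [0, 1]; labels are integer classes.
        """
        c = self.config
        Xt = X_train[:, None, :, :]
        Xv = X_val[:, None, :, :]
        hist = TrainHistory()
        best_loss, best_state, patience_left = np.inf, None, c.patience
        for epoch in range(c.max_epochs):
            order = self._rng.permutation(len(Xt))
            losses = []
            for i0 in range(0, len(Xt), c.batch_size):
                sel = order[i0:i0 + c.batch_size]
                probs = self._forward(Xt[sel], train=True)
                loss = -np.mean(np.log(probs[np.arange(len(sel)), y_train[sel]] + 1e-12))
                losses.append(loss)
                grads = self._backward(Xt[sel], probs, y_train[sel])
                self._adam_step(grads)
            pv = self._forward(Xv, train=False)
            val_loss = -np.mean(np.log(pv[np.arange(len(Xv)), y_val] + 1e-12))
            val_acc = float(np.mean(pv.argmax(axis=1) == y_val))
            hist.train_loss.append(float(np.mean(losses)))
            hist.val_loss.append(float(val_loss))
            hist.val_accuracy.append(val_acc)
            if val_loss < best_loss - 1e-5:
                best_loss = val_loss
                best_state = {k: v.copy() for k, v in self._params().items()}
                hist.best_epoch = epoch
                patience_left = c.patience
            else:
                patience_left -= 1
                if patience_left <= 0:
                    break
        if best_state is not None:
            for k, v in self._params().items():
                v[...] = best_state[k]
        return hist

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        out = []
        for i0 in range(0, len(X), 256):
            out.append(self._forward(X[i0:i0 + 256, None, :, :], train=False))
        return np.concatenate(out)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)
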