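"""A small convolutional-network engine for spectral-information matrices.

The architecture is fixed by design: three same-padded stride-1 convolution
layers (one kernel size throughout, chosen from 3/5/7), each followed by
ReLU and 2x2 max pooling, with dropout after the first two pooling stages,
then two fully connected layers ending in one output unit per class.
Training minimises the mean squared error between the raw 5-way outputs and
one-hot targets with the Adam optimiser; the softmax is applied only at
prediction time to turn outputs into class scores.

Everything runs on numpy: convolutions are lowered to matrix products via
im2col (``sliding_window_view``), and every layer implements an explicit
backward pass.  Tensors are laid out NHWC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

N_CLASSES = 5


def relu(x: np.ndarray) -> np.ndarray:
    """Rectified linear unit, elementwise max(x, 0)."""
    return np.maximum(x, 0.0)


def softmax(z: np.ndarray) -> np.ndarray:
    """Row-wise softmax with the usual max-shift for stability."""
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def conv2d_same(x: np.ndarray, weights: np.ndarray, offsets: np.ndarray) -> np.ndarray:
    """Same-padded stride-1 2-D convolution (cross-correlation convention).

    ``x`` is NHWC, ``weights`` has shape (k, k, C_in, C_out) and ``offsets``
    (C_out,).  Output channel k is the sum over input channels of the
    kernel response plus its offset.
    """
    x = np.asarray(x, dtype=float)
    k = weights.shape[0]
    if weights.shape[0] != weights.shape[1] or k % 2 == 0 or k < 1:
        raise ValueError("kernel must be square with odd positive size")
    if weights.shape[2] != x.shape[3]:
        raise ValueError(f"weights expect {weights.shape[2]} input channels, "
                         f"input has {x.shape[3]}")
    p = k // 2
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
    patches = sliding_window_view(xp, (k, k), axis=(1, 2))  # N,H,W,C,k,k
    n, h, w = x.shape[:3]
    cols = patches.transpose(0, 1, 2, 4, 5, 3).reshape(n, h, w, -1)
    wmat = weights.reshape(-1, weights.shape[3])
    return cols @ wmat + offsets


def max_pool(x: np.ndarray, size: int = 2, stride: int = 2) -> np.ndarray:
    """Blockwise max pooling; trailing rows/columns beyond a full block drop."""
    x = np.asarray(x, dtype=float)
    n, h, w, c = x.shape
    ho, wo = h // size, w // size
    if ho < 1 or wo < 1:
        raise ValueError("spatial dimensions smaller than the pooling window")
    v = x[:, :ho * size, :wo * size, :]
    v = v.reshape(n, ho, size, wo, size, c)
    return v.max(axis=(2, 4))


# ---------------------------------------------------------------------------
# Layers with explicit backward passes


class _Conv:
    def __init__(self, k, c_in, c_out, rng):
        fan_in = k * k * c_in
        scale = np.sqrt(2.0 / fan_in)  # He init for ReLU stacks
        self.W = rng.normal(0.0, scale, size=(k, k, c_in, c_out))
        self.b = np.zeros(c_out)
        self.k, self.c_in, self.c_out = k, c_in, c_out

    def forward(self, x, train):
        self._shape = x.shape
        k, p = self.k, self.k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        patches = sliding_window_view(xp, (k, k), axis=(1, 2))
        n, h, w = x.shape[:3]
        self._cols = patches.transpose(0, 1, 2, 4, 5, 3).reshape(n * h * w, -1)
        wmat = self.W.reshape(-1, self.c_out)
        y = self._cols @ wmat + self.b
        return y.reshape(n, h, w, self.c_out)

    def backward(self, dy):
        n, h, w, c_in = self._shape
        k, p = self.k, self.k // 2
        dyf = dy.reshape(n * h * w, self.c_out)
        self.dW = (self._cols.T @ dyf).reshape(self.W.shape)
        self.db = dyf.sum(axis=0)
        wmat = self.W.reshape(-1, self.c_out)
        dcols = (dyf @ wmat.T).reshape(n, h, w, k, k, c_in)
        dxp = np.zeros((n, h + 2 * p, w + 2 * p, c_in))
        for i in range(k):
            for j in range(k):
                dxp[:, i:i + h, j:j + w, :] += dcols[:, :, :, i, j, :]
        return dxp[:, p:p + h, p:p + w, :]

    def params(self):
        return [("W", self.W, self.dW), ("b", self.b, self.db)]


class _ReLU:
    def forward(self, x, train):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy):
        return dy * self._mask

    def params(self):
        return []


class _MaxPool:
    def __init__(self, size=2):
        self.size = size

    def forward(self, x, train):
        s = self.size
        n, h, w, c = x.shape
        ho, wo = h // s, w // s
        self._in_shape = x.shape
        v = x[:, :ho * s, :wo * s, :].reshape(n, ho, s, wo, s, c)
        v = v.transpose(0, 1, 3, 5, 2, 4).reshape(n, ho, wo, c, s * s)
        self._arg = v.argmax(axis=-1)
        return np.take_along_axis(v, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, dy):
        s = self.size
        n, h, w, c = self._in_shape
        ho, wo = h // s, w // s
        dv = np.zeros((n, ho, wo, c, s * s))
        np.put_along_axis(dv, self._arg[..., None], dy[..., None], axis=-1)
        dv = dv.reshape(n, ho, wo, c, s, s).transpose(0, 1, 4, 2, 5, 3)
        dx = np.zeros(self._in_shape)
        dx[:, :ho * s, :wo * s, :] = dv.reshape(n, ho * s, wo * s, c)
        return dx

    def params(self):
        return []


class _Dropout:
    def __init__(self, rate, rng):
        self.rate = rate
        self.rng = rng

    def forward(self, x, train):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask

    def params(self):
        return []


class _Flatten:
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)

    def params(self):
        return []


class _Dense:
    def __init__(self, d_in, d_out, rng):
        scale = np.sqrt(2.0 / d_in)
        self.W = rng.normal(0.0, scale, size=(d_in, d_out))
        self.b = np.zeros(d_out)

    def forward(self, x, train):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        self.dW = self._x.T @ dy
        self.db = dy.sum(axis=0)
        return dy @ self.W.T

    def params(self):
        return [("W", self.W, self.dW), ("b", self.b, self.db)]


class _Adam:
    def __init__(self, lr=0.001, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.state: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        self.t = 0

    def step(self, params):
        self.t += 1
        for key, (p, g) in enumerate(params):
            m, v = self.state.get(key, (np.zeros_like(p), np.zeros_like(p)))
            m = self.b1 * m + (1 - self.b1) * g
            v = self.b2 * v + (1 - self.b2) * g * g
            self.state[key] = (m, v)
            mh = m / (1 - self.b1 ** self.t)
            vh = v / (1 - self.b2 ** self.t)
            p -= self.lr * mh / (np.sqrt(vh) + self.eps)


# ---------------------------------------------------------------------------
# Architecture description and trained model


@dataclass(frozen=True)
class CNNSpec:
    """Architecture and training hyperparameters of the feature extractor.

    ``input_size`` is the side length C of the C x C single-channel input;
    one odd ``kernel_size`` (3, 5 or 7) is used in all three convolution
    layers; ``filter_counts`` sets the channel pyramid; ``fc_hidden`` is the
    width of the penultimate fully connected layer whose post-ReLU
    activations serve as features for external classifier heads.
    """

    input_size: int = 230
    kernel_size: int = 7
    filter_counts: tuple[int, int, int] = (16, 32, 64)
    fc_hidden: int = 128
    n_classes: int = N_CLASSES
    dropout_rate: float = 0.3
    learning_rate: float = 0.001
    epochs: int = 500
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self):
        if self.kernel_size % 2 == 0 or self.kernel_size < 1:
            raise ValueError("kernel size must be odd and positive")
        if len(self.filter_counts) != 3:
            raise ValueError("exactly three convolution layers are required")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")
        if self.input_size // 8 < 1:
            raise ValueError("input too small for three 2x2 pooling stages")

    @property
    def flattened_size(self) -> int:
        d = self.input_size
        for _ in range(3):
            d //= 2
        return d * d * self.filter_counts[2]


class CNN:
    """The convolutional feature extractor with its training loop.

    Layer graph: [conv -> relu -> pool -> dropout] x 2 -> conv -> relu ->
    pool -> flatten -> dense(hidden) -> relu -> dense(classes).
    Initialisation and dropout are driven by a single seeded generator, so
    two builds from the same spec are identical.
    """

    def __init__(self, spec: CNNSpec):
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        self._dropout_rng = np.random.default_rng(
            np.random.SeedSequence(spec.seed).spawn(1)[0])
        f1, f2, f3 = spec.filter_counts
        k = spec.kernel_size
        self.layers = [
            _Conv(k, 1, f1, rng), _ReLU(), _MaxPool(),
            _Dropout(spec.dropout_rate, self._dropout_rng),
            _Conv(k, f1, f2, rng), _ReLU(), _MaxPool(),
            _Dropout(spec.dropout_rate, self._dropout_rng),
            _Conv(k, f2, f3, rng), _ReLU(), _MaxPool(),
            _Flatten(),
            _Dense(spec.flattened_size, spec.fc_hidden, rng), _ReLU(),
            _Dense(spec.fc_hidden, spec.n_classes, rng),
        ]
        self._feature_layer = len(self.layers) - 1  # up to post-ReLU hidden
        self.history: dict[str, list[float]] = {"loss": [], "accuracy": []}

    # -- forward paths ------------------------------------------------------

    def _as_nhwc(self, matrices: np.ndarray) -> np.ndarray:
        m = np.asarray(matrices, dtype=float)
        if m.ndim == 3:
            m = m[..., None]
        if m.shape[1] != self.spec.input_size or m.shape[2] != self.spec.input_size:
            raise ValueError(f"expected {self.spec.input_size}x"
                             f"{self.spec.input_size} matrices, got "
                             f"{m.shape[1]}x{m.shape[2]}")
        return m

    def forward(self, matrices: np.ndarray, train: bool = False,
                upto: int | None = None) -> np.ndarray:
        x = self._as_nhwc(matrices)
        for layer in self.layers[:upto]:
            x = layer.forward(x, train)
        return x

    def extract_features(self, matrices: np.ndarray,
                         batch_size: int = 64) -> np.ndarray:
        """Post-ReLU activations of the hidden dense layer, dropout off."""
        m = self._as_nhwc(matrices)
        out = [self.forward(m[i:i + batch_size], train=False,
                            upto=self._feature_layer)
               for i in range(0, len(m), batch_size)]
        return np.concatenate(out, axis=0)

    def predict_softmax(self, matrices: np.ndarray,
                        batch_size: int = 64) -> tuple[np.ndarray, np.ndarray]:
        """Class indices and softmax scores over the outputs.

        Ties in the scores resolve to the lowest class index.
        """
        m = self._as_nhwc(matrices)
        logits = np.concatenate(
            [self.forward(m[i:i + batch_size]) for i in range(0, len(m), batch_size)])
        scores = softmax(logits)
        return scores.argmax(axis=1), scores

    # -- training -----------------------------------------------------------

    def train(self, matrices: np.ndarray, one_hot: np.ndarray,
              epochs: int | None = None, batch_size: int | None = None,
              verbose: bool = False) -> "CNN":
        """Fit by Adam on the mean-squared error to one-hot targets.

        Records per-epoch training loss and accuracy in ``self.history``.
        """
        import warnings as _w

        m = self._as_nhwc(matrices)
        t = np.asarray(one_hot, dtype=float)
        if t.ndim != 2 or t.shape[1] != self.spec.n_classes:
            raise ValueError(f"targets must be one-hot over "
                             f"{self.spec.n_classes} classes")
        if len(m) != len(t):
            raise ValueError("matrices and targets misaligned")
        if (t.sum(axis=0) == 0).any():
            _w.warn("some classes absent from the training labels", stacklevel=2)
        epochs = self.spec.epochs if epochs is None else epochs
        batch_size = self.spec.batch_size if batch_size is None else batch_size
        opt = _Adam(lr=self.spec.learning_rate)
        shuffle_rng = np.random.default_rng(
            np.random.SeedSequence(self.spec.seed).spawn(2)[1])
        n = len(m)
        for epoch in range(epochs):
            order = shuffle_rng.permutation(n)
            losses = []
            correct = 0
            for i in range(0, n, batch_size):
                idx = order[i:i + batch_size]
                x = m[idx]
                for layer in self.layers:
                    x = layer.forward(x, True)
                diff = x - t[idx]
                losses.append(float((diff ** 2).mean()))
                correct += int((x.argmax(1) == t[idx].argmax(1)).sum())
                dy = 2.0 * diff / diff.size
                for layer in reversed(self.layers):
                    dy = layer.backward(dy)
                params = [pg[1:] for layer in self.layers for pg in layer.params()]
                opt.step(params)
            self.history["loss"].append(float(np.mean(losses)))
            self.history["accuracy"].append(correct / n)
            if verbose:
                print(f"epoch {epoch + 1}/{epochs}  loss "
                      f"{self.history['loss'][-1]:.5f}  acc "
                      f"{self.history['accuracy'][-1]:.3f}")
        return self

    # -- audit and persistence ---------------------------------------------

    def layer_summary(self) -> list[str]:
        return [type(layer).__name__.lstrip("_") for layer in self.layers]

    def get_weights(self) -> list[np.ndarray]:
        return [p for layer in self.layers for _, p, _ in _iter_params(layer)]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        flat = [(layer, name) for layer in self.layers
                for name, _, _ in _iter_params(layer)]
        if len(flat) != len(weights):
            raise ValueError("weight list does not match architecture")
        for (layer, name), w in zip(flat, weights):
            getattr(layer, name)[...] = w


def _iter_params(layer):
    if isinstance(layer, (_Conv, _Dense)):
        yield ("W", layer.W, None)
        yield ("b", layer.b, None)


def build(spec: CNNSpec) -> CNN:
    """Construct an initialised network from its architecture description."""
    return CNN(spec)


def one_hot(labels: np.ndarray, n_classes: int = N_CLASSES) -> np.ndarray:
    """Integer class codes to one-hot rows."""
    labels = np.asarray(labels, dtype=int)
    if labels.min() < 0 or labels.max() >= n_classes:
        raise ValueError("label codes out of range")
    return np.eye(n_classes)[labels]
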