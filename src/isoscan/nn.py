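"""Minimal numpy backend for small 3D convolutional classifiers.

No deep-learning framework is assumed: layers implement their own forward
and backward passes (im2col convolutions, ceil-mode max pooling, inverted
dropout) and training uses Adam on the softmax cross-entropy. The grids
involved are small (tens of thousands of voxels), so BLAS-backed matrix
multiplication is entirely adequate on one CPU.

Conventions
-----------
* arrays are channels-first: a batch is ``(N, C, X, Y, Z)``;
* "same" padding splits ``k - 1`` as ``(k - 1) // 2`` before / ``k // 2``
  after, so even kernels also preserve the spatial shape;
* 2x2x2 max pooling is ceil-mode: odd extents are right-padded with -inf so
  the output extent is ``ceil(n / 2)``;
* weights are He-uniform, biases zero, all randomness from one seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from isoscan.errors import TrainingError


@dataclass
class Hyperparams:
    """Training recipe for the CNN classifiers.

    Defaults are conventional for small 3D CNNs: Adam at 1e-4 on softmax
    cross-entropy, batches of 16, early stopping on held-out accuracy with
    patience 10, at most 100 epochs. Every field can be overridden.
    """

    learning_rate: float = 1e-4
    batch_size: int = 16
    max_epochs: int = 100
    patience: int | None = 10
    val_fraction: float = 0.15


def _he_uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


def _same_pads(ksize: tuple[int, int, int]) -> list[tuple[int, int]]:
    return [((k - 1) // 2, k // 2) for k in ksize]


def _im2col(x: np.ndarray, ksize: tuple[int, int, int], pads: list[tuple[int, int]]) -> np.ndarray:
    """(N, C, X, Y, Z) -> (N * X'Y'Z', C * prod(k)) patch matrix."""
    xp = np.pad(x, [(0, 0), (0, 0), *pads])
    win = np.lib.stride_tricks.sliding_window_view(xp, ksize, axis=(2, 3, 4))
    # win: (N, C, X', Y', Z', kx, ky, kz)
    n, c = win.shape[0], win.shape[1]
    spatial = win.shape[2:5]
    cols = win.transpose(0, 2, 3, 4, 1, 5, 6, 7).reshape(
        n * int(np.prod(spatial)), c * int(np.prod(ksize))
    )
    return np.ascontiguousarray(cols), spatial


class Layer:
    """Base layer: stateless unless it owns parameters."""

    params: dict[str, np.ndarray]
    grads: dict[str, np.ndarray]

    def __init__(self) -> None:
        self.params = {}
        self.grads = {}

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv3D(Layer):
    """Same-padded, stride-1 3D convolution, fully connected across channels."""

    def __init__(self, in_channels: int, n_kernels: int,
                 kernel_size: tuple[int, int, int], rng: np.random.Generator) -> None:
        super().__init__()
        self.in_channels = in_channels
        self.n_kernels = n_kernels
        self.kernel_size = tuple(int(k) for k in kernel_size)
        fan_in = in_channels * int(np.prod(self.kernel_size))
        self.params = {
            "W": _he_uniform(rng, (n_kernels, in_channels, *self.kernel_size), fan_in),
            "b": np.zeros(n_kernels, dtype=np.float32),
        }
        self._pads = _same_pads(self.kernel_size)
        self._cache: tuple | None = None

    def forward(self, x, train=False, rng=None):
        n = x.shape[0]
        cols, spatial = _im2col(x, self.kernel_size, self._pads)
        w2 = self.params["W"].reshape(self.n_kernels, -1)
        out = cols @ w2.T + self.params["b"]
        y = out.reshape(n, *spatial, self.n_kernels).transpose(0, 4, 1, 2, 3)
        self._cache = (cols, x.shape)
        return np.ascontiguousarray(y)

    def backward(self, dy):
        cols, x_shape = self._cache
        n = dy.shape[0]
        do = dy.transpose(0, 2, 3, 4, 1).reshape(-1, self.n_kernels)
        self.grads["W"] = (do.T @ cols).reshape(self.params["W"].shape)
        self.grads["b"] = do.sum(axis=0)
        # dX is a correlation of dY with the flipped kernels, channels swapped
        w_flip = np.flip(self.params["W"], axis=(2, 3, 4)).transpose(1, 0, 2, 3, 4)
        back_pads = [(k - 1 - pl, k - 1 - pr)
                     for k, (pl, pr) in zip(self.kernel_size, self._pads)]
        cols_b, spatial = _im2col(dy, self.kernel_size, back_pads)
        wb = w_flip.reshape(self.in_channels, -1)
        dx = (cols_b @ wb.T).reshape(n, *spatial, self.in_channels)
        return np.ascontiguousarray(dx.transpose(0, 4, 1, 2, 3)).reshape(x_shape)


class MaxPool3D(Layer):
    """2x2x2 ceil-mode max pooling (odd extents right-padded with -inf)."""

    def __init__(self) -> None:
        super().__init__()
        self._cache: tuple | None = None

    def forward(self, x, train=False, rng=None):
        n, c, sx, sy, sz = x.shape
        px, py, pz = sx % 2, sy % 2, sz % 2
        xp = np.pad(x, [(0, 0), (0, 0), (0, px), (0, py), (0, pz)],
                    constant_values=-np.inf)
        w6 = xp.reshape(n, c, xp.shape[2] // 2, 2, xp.shape[3] // 2, 2,
                        xp.shape[4] // 2, 2)
        out = w6.max(axis=(3, 5, 7))
        self._cache = (w6, out, (sx, sy, sz))
        return out

    def backward(self, dy):
        w6, out, (sx, sy, sz) = self._cache
        expanded = out[:, :, :, None, :, None, :, None]
        mask = w6 == expanded
        cnt = mask.sum(axis=(3, 5, 7), keepdims=True)
        dxp = mask * (dy[:, :, :, None, :, None, :, None] / cnt)
        n, c = dy.shape[:2]
        dxp = dxp.reshape(n, c, w6.shape[2] * 2, w6.shape[4] * 2, w6.shape[6] * 2)
        return np.ascontiguousarray(dxp[:, :, :sx, :sy, :sz])


class ReLU(Layer):
    def __init__(self) -> None:
        super().__init__()
        self._mask: np.ndarray | None = None

    def forward(self, x, train=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class Flatten(Layer):
    def __init__(self) -> None:
        super().__init__()
        self._shape: tuple | None = None

    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_dim: int, units: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.params = {
            "W": _he_uniform(rng, (units, in_dim), in_dim),
            "b": np.zeros(units, dtype=np.float32),
        }
        self._x: np.ndarray | None = None

    def forward(self, x, train=False, rng=None):
        self._x = x
        return x @ self.params["W"].T + self.params["b"]

    def backward(self, dy):
        self.grads["W"] = dy.T @ self._x
        self.grads["b"] = dy.sum(axis=0)
        return dy @ self.params["W"]


class Dropout(Layer):
    """Inverted dropout: identity at evaluation time."""

    def __init__(self, rate: float) -> None:
        super().__init__()
        if not (0.0 <= rate < 1.0):
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self._mask: np.ndarray | None = None

    def forward(self, x, train=False, rng=None):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        assert rng is not None, "training-mode dropout needs an RNG"
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dy):
        if self._mask is None:
            return dy
        return dy * self._mask


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class Sequential:
    """Ordered layer stack ending in logits (softmax applied by the caller)."""

    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train, rng=rng)
        return x

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        dy = dlogits
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def parameters(self) -> list[tuple[Layer, str]]:
        return [(layer, name) for layer in self.layers for name in layer.params]

    def num_params(self) -> int:
        return sum(layer.params[name].size for layer, name in self.parameters())

    def get_state(self) -> list[np.ndarray]:
        return [layer.params[name].copy() for layer, name in self.parameters()]

    def set_state(self, state: list[np.ndarray]) -> None:
        for (layer, name), value in zip(self.parameters(), state):
            layer.params[name] = value.copy()


class Adam:
    def __init__(self, net: Sequential, learning_rate: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.net = net
        self.lr = learning_rate
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(layer.params[name]) for layer, name in net.parameters()]
        self.v = [np.zeros_like(layer.params[name]) for layer, name in net.parameters()]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for i, (layer, name) in enumerate(self.net.parameters()):
            g = layer.grads[name]
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            layer.params[name] = (
                layer.params[name] - self.lr * mhat / (np.sqrt(vhat) + self.eps)
            ).astype(np.float32)


class NeuralNetClassifier:
    """Two-class 3D CNN with softmax output and gradient access.

    ``predict_proba`` returns ``(N, 2)`` class probabilities;
    ``input_gradient`` returns the gradient of a pre-softmax class score
    with respect to one input stack (the quantity saliency maps use).
    """

    def __init__(self, net: Sequential, n_input_channels: int,
                 input_shape: tuple[int, int, int], seed: int) -> None:
        self.net = net
        self.n_input_channels = n_input_channels
        self.input_shape = tuple(input_shape)
        self.seed = seed

    # -- plumbing ---------------------------------------------------------
    def _check_batch(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 4:
            x = x[None]
        expected = (self.n_input_channels, *self.input_shape)
        if x.shape[1:] != expected:
            raise ValueError(f"input shape {x.shape[1:]} != model input {expected}")
        return x

    @property
    def num_params(self) -> int:
        return self.net.num_params()

    def layer_param_sizes(self) -> list[int]:
        """Realized trainable-parameter count per parameterized layer."""
        sizes: list[int] = []
        for layer in self.net.layers:
            if layer.params:
                sizes.append(sum(p.size for p in layer.params.values()))
        return sizes

    # -- inference --------------------------------------------------------
    def predict_proba(self, x: np.ndarray, batch_size: int = 32) -> np.ndarray:
        x = self._check_batch(x)
        out = [softmax(self.net.forward(x[i:i + batch_size]))
               for i in range(0, len(x), batch_size)]
        return np.concatenate(out, axis=0)

    def input_gradient(self, x: np.ndarray, class_index: int) -> np.ndarray:
        """d(logit[class_index]) / d(input) for a single stack."""
        if not (0 <= class_index < 2):
            raise ValueError(f"class_index must be 0 or 1, got {class_index}")
        x = self._check_batch(x)
        logits = self.net.forward(x, train=False)
        dlogits = np.zeros_like(logits)
        dlogits[:, class_index] = 1.0
        return self.net.backward(dlogits)

    # -- training ---------------------------------------------------------
    def fit(self, x: np.ndarray, y: np.ndarray,
            hyperparams: Hyperparams | None = None,
            seed: int | None = None) -> dict:
        """Train with Adam on softmax cross-entropy.

        When ``patience`` is set and both classes allow it, a stratified
        fraction of the training set is held out and the parameters with
        the best held-out accuracy are restored at the end.
        """
        hp = hyperparams or Hyperparams()
        rng = np.random.default_rng(self.seed if seed is None else seed)
        x = self._check_batch(x)
        y = np.asarray(y, dtype=np.int64)
        if len(np.unique(y)) < 2:
            raise TrainingError("training set contains a single class")

        # stratified early-stopping holdout
        val_x = val_y = None
        if hp.patience is not None and hp.val_fraction > 0:
            idx_by_class = [np.flatnonzero(y == c) for c in (0, 1)]
            n_val = [max(1, int(round(len(ix) * hp.val_fraction))) for ix in idx_by_class]
            if all(len(ix) - nv >= 1 for ix, nv in zip(idx_by_class, n_val)):
                val_idx = np.concatenate(
                    [rng.permutation(ix)[:nv] for ix, nv in zip(idx_by_class, n_val)]
                )
                train_mask = np.ones(len(y), dtype=bool)
                train_mask[val_idx] = False
                val_x, val_y = x[val_idx], y[val_idx]
                x, y = x[train_mask], y[train_mask]

        opt = Adam(self.net, learning_rate=hp.learning_rate)
        best_state = None
        best_metric = -np.inf
        stale = 0
        history = {"loss": [], "val_accuracy": []}
        n = len(x)
        for _epoch in range(hp.max_epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, hp.batch_size):
                batch = order[start:start + hp.batch_size]
                xb, yb = x[batch], y[batch]
                logits = self.net.forward(xb, train=True, rng=rng)
                probs = softmax(logits)
                eps = 1e-12
                epoch_loss -= float(
                    np.log(probs[np.arange(len(yb)), yb] + eps).sum()
                )
                dlogits = probs.copy()
                dlogits[np.arange(len(yb)), yb] -= 1.0
                self.net.backward((dlogits / len(yb)).astype(np.float32))
                opt.step()
            history["loss"].append(epoch_loss / n)

            if val_x is not None:
                val_pred = self.predict_proba(val_x).argmax(axis=1)
                metric = float((val_pred == val_y).mean())
            else:
                metric = -history["loss"][-1]
            history["val_accuracy"].append(metric if val_x is not None else np.nan)
            if metric > best_metric + 1e-12:
                best_metric = metric
                best_state = self.net.get_state()
                stale = 0
            else:
                stale += 1
                if hp.patience is not None and stale >= hp.patience:
                    break
        if best_state is not None:
            self.net.set_state(best_state)
        return history
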