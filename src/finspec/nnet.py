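"""Compact feed-forward network trainer on numpy.

Implements exactly the pieces the two classifier families need: dense and
strided 1-D convolution layers, the ReLU/SELU/ELU/Swish activations, inverted
dropout, L2 weight decay, softmax + (class-weighted) categorical
cross-entropy with the combined stable gradient, and the Adam optimizer.
Everything is seeded through a single ``numpy.random.Generator``, so training
is bit-reproducible.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Dense", "Conv1D", "Activation", "Dropout", "Network", "train_network", "conv1d_output_length"]

_SELU_LAMBDA = 1.0507009873554805
_SELU_ALPHA = 1.6732632423543772


def conv1d_output_length(n_in: int, kernel: int, stride: int) -> int:
    """Output length of an unpadded strided 1-D convolution."""
    if n_in < kernel:
        raise ValueError(f"input length {n_in} shorter than kernel {kernel}")
    return (n_in - kernel) // stride + 1


class Activation:
    """Elementwise nonlinearity; softmax is handled by the loss, not here."""

    def __init__(self, kind: str):
        if kind not in ("relu", "selu", "elu", "swish"):
            raise ValueError(f"unknown activation {kind!r}")
        self.kind = kind
        self.params: list[np.ndarray] = []
        self.grads: list[np.ndarray] = []

    def forward(self, x, train=False, rng=None):
        self._x = x
        if self.kind == "relu":
            return np.maximum(x, 0.0)
        if self.kind == "selu":
            return _SELU_LAMBDA * np.where(x > 0, x, _SELU_ALPHA * np.expm1(x))
        if self.kind == "elu":
            return np.where(x > 0, x, np.expm1(x))
        s = 1.0 / (1.0 + np.exp(-x))
        self._sig = s
        return x * s

    def backward(self, g):
        x = self._x
        if self.kind == "relu":
            return g * (x > 0)
        if self.kind == "selu":
            return g * _SELU_LAMBDA * np.where(x > 0, 1.0, _SELU_ALPHA * np.exp(x))
        if self.kind == "elu":
            return g * np.where(x > 0, 1.0, np.exp(x))
        s = self._sig
        return g * (s + x * s * (1.0 - s))


class Dropout:
    """Inverted dropout: active only during training passes."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.params: list[np.ndarray] = []
        self.grads: list[np.ndarray] = []

    def forward(self, x, train=False, rng=None):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, g):
        return g if self._mask is None else g * self._mask


class Dense:
    """Fully connected layer with optional L2 weight decay on the kernel."""

    def __init__(self, n_in: int, n_out: int, l2: float = 0.0, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        # He-style initialization, suitable for the rectifier-family activations
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.l2 = l2
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train=False, rng=None):
        self._x = x
        return x @ self.W + self.b

    def backward(self, g):
        self.grads[0][:] = self._x.T @ g
        if self.l2:
            self.grads[0] += self.l2 * self.W
        self.grads[1][:] = g.sum(axis=0)
        return g @ self.W.T


class Conv1D:
    """Unpadded strided 1-D convolution over single-channel spectra.

    Input ``(N, B)``; output is flattened to ``(N, L * n_filters)`` with
    ``L = (B - kernel)//stride + 1`` so a dense layer can follow directly.
    """

    def __init__(self, n_in: int, n_filters: int, kernel: int, stride: int,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.kernel, self.stride = kernel, stride
        self.L = conv1d_output_length(n_in, kernel, stride)
        self.n_filters = n_filters
        self.W = rng.normal(0.0, np.sqrt(2.0 / kernel), size=(n_filters, kernel))
        self.b = np.zeros(n_filters)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]
        self._pos = stride * np.arange(self.L)

    def forward(self, x, train=False, rng=None):
        n = x.shape[0]
        patches = np.empty((n, self.L, self.kernel))
        for t in range(self.kernel):
            patches[:, :, t] = x[:, self._pos + t]
        self._patches, self._n_in = patches, x.shape[1]
        out = np.einsum("nlk,fk->nlf", patches, self.W) + self.b
        return out.reshape(n, self.L * self.n_filters)

    def backward(self, g):
        n = g.shape[0]
        g = g.reshape(n, self.L, self.n_filters)
        self.grads[0][:] = np.einsum("nlk,nlf->fk", self._patches, g)
        self.grads[1][:] = g.sum(axis=(0, 1))
        dx = np.zeros((n, self._n_in))
        for t in range(self.kernel):
            dx[:, self._pos + t] += g @ self.W[:, t]
        return dx

    @property
    def output_dim(self) -> int:
        return self.L * self.n_filters


class Network:
    """A plain layer stack ending in logits; softmax lives in the loss."""

    def __init__(self, layers: list):
        self.layers = layers

    def forward(self, x, train=False, rng=None):
        for layer in self.layers:
            x = layer.forward(x, train=train, rng=rng)
        return x

    def backward(self, g):
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    def predict_proba(self, x, batch: int = 4096) -> np.ndarray:
        out = []
        for i in range(0, x.shape[0], batch):
            logits = self.forward(x[i : i + batch], train=False)
            logits = logits - logits.max(axis=1, keepdims=True)
            e = np.exp(logits)
            out.append(e / e.sum(axis=1, keepdims=True))
        return np.vstack(out) if out else np.empty((0, self.layers[-1].b.size))

    def get_params(self) -> list[np.ndarray]:
        return [p.copy() for layer in self.layers for p in layer.params]

    def set_params(self, flat: list[np.ndarray]) -> None:
        i = 0
        for layer in self.layers:
            for p in layer.params:
                p[:] = flat[i]
                i += 1


class _Adam:
    def __init__(self, params, lr=1e-3, b1=0.9, b2=0.999, eps=1e-8):
        self.params, self.lr, self.b1, self.b2, self.eps = params, lr, b1, b2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[:] = self.b1 * m + (1 - self.b1) * g
            v[:] = self.b2 * v + (1 - self.b2) * g * g
            mh = m / (1 - self.b1**self.t)
            vh = v / (1 - self.b2**self.t)
            p -= self.lr * mh / (np.sqrt(vh) + self.eps)


def _weighted_ce_grad(logits, y, w):
    """Stable softmax-CE loss and dlogits for integer labels and row weights."""
    n = logits.shape[0]
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)
    loss = -(w * (z[np.arange(n), y] - np.log(e.sum(axis=1)))).sum() / w.sum()
    g = p * w[:, None]
    g[np.arange(n), y] -= w
    return loss, g / w.sum()


def train_network(
    net: Network,
    X: np.ndarray,
    y: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    class_weights: np.ndarray,
    epochs: int = 200,
    patience: int = 20,
    batch_size: int = 64,
    lr: float = 1e-3,
    seed: int = 0,
) -> dict:
    """Train with class-weighted cross-entropy; select the epoch minimizing
    the complement of class-weighted mean recall on the validation slice.

    Returns a history dict; ``net`` is left holding the selected parameters.
    """
    rng = np.random.default_rng(seed)
    params = [p for layer in net.layers for p in layer.params]
    grads = [g for layer in net.layers for g in layer.grads]
    opt = _Adam(params, lr=lr)
    n = X.shape[0]
    row_w = class_weights[y]
    best_metric, best_params, best_epoch, since = (np.inf, np.inf), net.get_params(), -1, 0
    history = {"loss": [], "val_metric": []}
    for epoch in range(epochs):
        order = rng.permutation(n)
        ep_loss = 0.0
        for i in range(0, n, batch_size):
            idx = order[i : i + batch_size]
            logits = net.forward(X[idx], train=True, rng=rng)
            loss, g = _weighted_ce_grad(logits, y[idx], row_w[idx])
            net.backward(g)
            opt.step(grads)
            ep_loss += loss * idx.size
        history["loss"].append(ep_loss / n)
        metric = _selection_metric(net, X_val, y_val, class_weights)
        history["val_metric"].append(metric)
        if metric[0] < best_metric[0] - 1e-9:
            since = 0  # recall improved: reset patience
        else:
            since += 1
        if metric < best_metric:
            best_metric, best_params, best_epoch = metric, net.get_params(), epoch
        if since >= patience:
            break
    net.set_params(best_params)
    history.update(best_epoch=best_epoch, best_metric=best_metric)
    return history


def _selection_metric(net: Network, X_val, y_val, class_weights) -> tuple[float, float]:
    """(1 − class-weighted mean recall, weighted log loss) on the validation slice.

    The recall complement is the selection criterion proper; the log loss
    breaks its coarse ties so that among equally accurate epochs the better
    calibrated one is kept.
    """
    if X_val.shape[0] == 0:
        return (np.inf, np.inf)
    p = net.predict_proba(X_val)
    pred = p.argmax(axis=1)
    classes = np.unique(y_val)
    recalls = np.array([(pred[y_val == c] == c).mean() for c in classes])
    w = class_weights[classes]
    row_w = class_weights[y_val]
    eps = 1e-12
    ll = float(-(row_w * np.log(p[np.arange(len(y_val)), y_val] + eps)).sum() / row_w.sum())
    return (1.0 - float((recalls * w).sum() / w.sum()), ll)
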