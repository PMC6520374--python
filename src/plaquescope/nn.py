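"""Minimal deterministic CNN engine on numpy.

Implements exactly the layer set needed by the tile classifier: 3x3
convolutions (stride 1, padding 1), rectifier units, inverted dropout,
2x2 max pooling, dense layers, the Adam optimizer and a multi-label
soft-margin loss.  Everything runs in float32 on BLAS matmuls with
channels-last (NHWC) activations, so im2col reduces to contiguous slice
copies.

Design constraint: batched evaluation must be bit-identical to
evaluating samples one at a time (sliding-window maps and occlusion
maps are validated against naive per-window loops).  BLAS gemm results
depend on the row count, so convolutions and dense layers loop over the
batch dimension internally and issue one fixed-shape gemm per sample;
elementwise ops are batch-invariant anyway.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv3x3",
    "ReLU",
    "Dropout",
    "MaxPool2",
    "Flatten",
    "Dense",
    "Net",
    "Adam",
    "multilabel_soft_margin",
    "multilabel_soft_margin_grad",
    "sigmoid",
]


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def he_uniform(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class Layer:
    """Base layer: stateful single-use forward/backward caches."""

    params: list  # list of [name, value, grad]

    def __init__(self):
        self.params = []

    def forward(self, x, train=False, rng=None):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout, guided=False):  # pragma: no cover - interface
        raise NotImplementedError


class Conv3x3(Layer):
    """3x3 convolution, stride 1, zero padding 1 (shape preserving).

    Weights are stored (3, 3, cin, cout); the im2col row order (di, dj,
    cin) makes the gemm view a zero-copy reshape.  The batch loop is
    deliberate — see module docstring.
    """

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        super().__init__()
        self.cin, self.cout = cin, cout
        w = he_uniform(rng, (3, 3, cin, cout), fan_in=cin * 9)
        b = np.zeros(cout, dtype=np.float32)
        self.params = [["W", w, None], ["b", b, None]]
        self._x = None

    @staticmethod
    def _pad(xi: np.ndarray) -> np.ndarray:
        h, w, c = xi.shape
        xp = np.zeros((h + 2, w + 2, c), dtype=np.float32)
        xp[1:h + 1, 1:w + 1] = xi
        return xp

    def forward(self, x, train=False, rng=None):
        n, h, w, c = x.shape
        # one row-shifted stacked matmul per kernel row: each window row
        # of 3 taps is contiguous in the padded sample, so no im2col
        # copy is needed on the forward path
        wr = self.params[0][1].reshape(3, 3 * c, self.cout)
        b = self.params[1][1]
        out = np.empty((n, h, w, self.cout), dtype=np.float32)
        for i in range(n):
            xp = self._pad(x[i])
            acc = np.zeros((h, w, self.cout), dtype=np.float32)
            for di in range(3):
                rows = np.lib.stride_tricks.as_strided(
                    xp[di:], shape=(h, w, 3 * c), strides=xp.strides)
                acc += rows @ wr[di]
            acc += b
            out[i] = acc
        self._x = x
        return out

    def backward(self, dout, guided=False):
        x = self._x
        n, h, w, c = x.shape
        weight = self.params[0][1]  # (3, 3, cin, cout)
        # data gradient = convolution of dout with the flipped kernel,
        # channels transposed; computed with the same row-shifted trick
        wb = np.ascontiguousarray(weight[::-1, ::-1].transpose(0, 1, 3, 2))
        wbr = wb.reshape(3, 3 * self.cout, c)
        dw = np.zeros((3, 3 * c, self.cout), dtype=np.float64)
        db = np.zeros(self.cout, dtype=np.float64)
        dx = np.empty_like(x)
        strided = np.lib.stride_tricks.as_strided
        for i in range(n):
            do = dout[i]
            xp = self._pad(x[i])
            dop = self._pad(do)
            acc = np.zeros((h, w, c), dtype=np.float32)
            for di in range(3):
                rows = strided(xp[di:], shape=(h, w, 3 * c), strides=xp.strides)
                dw[di] += np.matmul(rows.transpose(0, 2, 1), do).sum(axis=0)
                drows = strided(dop[di:], shape=(h, w, 3 * self.cout), strides=dop.strides)
                acc += drows @ wbr[di]
            db += do.sum(axis=(0, 1), dtype=np.float64)
            dx[i] = acc
        self.params[0][2] = dw.reshape(3, 3, c, self.cout).astype(np.float32)
        self.params[1][2] = db.astype(np.float32)
        self._x = None
        return dx


class ReLU(Layer):
    def __init__(self):
        super().__init__()
        self._in = None

    def forward(self, x, train=False, rng=None):
        self._in = x
        return np.maximum(x, np.float32(0))

    def backward(self, dout, guided=False):
        g = np.where(self._in > 0, dout, np.float32(0))
        if guided:
            # guided backprop: additionally block negative gradients
            g = np.where(g > 0, g, np.float32(0))
        return g


class Dropout(Layer):
    """Inverted dropout; identity when not training."""

    def __init__(self, p: float):
        super().__init__()
        self.p = float(p)
        self._mask = None

    def forward(self, x, train=False, rng=None):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        keep = np.float32(1.0 - self.p)
        self._mask = (rng.random(x.shape, dtype=np.float32) < keep).astype(np.float32)
        self._mask /= keep
        return x * self._mask

    def backward(self, dout, guided=False):
        if self._mask is None:
            return dout
        return dout * self._mask


class MaxPool2(Layer):
    """2x2 max pooling, stride 2.  Gradient is routed to every argmax
    on exact ties (ties are measure-zero for real activations)."""

    def __init__(self):
        super().__init__()
        self._x = None
        self._out = None

    def forward(self, x, train=False, rng=None):
        out = np.maximum(np.maximum(x[:, ::2, ::2], x[:, ::2, 1::2]),
                         np.maximum(x[:, 1::2, ::2], x[:, 1::2, 1::2]))
        self._x, self._out = x, out
        return out

    def backward(self, dout, guided=False):
        dx = np.empty_like(self._x)
        for a in (0, 1):
            for b in (0, 1):
                q = self._x[:, a::2, b::2]
                dx[:, a::2, b::2] = np.where(q == self._out, dout, np.float32(0))
        self._x = self._out = None
        return dx


class Flatten(Layer):
    def __init__(self):
        super().__init__()
        self._shape = None

    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout, guided=False):
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, nin: int, nout: int, rng: np.random.Generator):
        super().__init__()
        w = he_uniform(rng, (nin, nout), fan_in=nin)
        b = np.zeros(nout, dtype=np.float32)
        self.params = [["W", w, None], ["b", b, None]]
        self._x = None

    def forward(self, x, train=False, rng=None):
        w, b = self.params[0][1], self.params[1][1]
        n = x.shape[0]
        out = np.empty((n, w.shape[1]), dtype=np.float32)
        for i in range(n):  # per-sample gemv for batch invariance
            out[i] = x[i] @ w + b
        self._x = x
        return out

    def backward(self, dout, guided=False):
        w = self.params[0][1]
        x = self._x
        self.params[0][2] = (x.T @ dout).astype(np.float32)
        self.params[1][2] = dout.sum(axis=0).astype(np.float32)
        self._x = None
        return dout @ w.T


class Net:
    """A plain sequential network with introspection hooks."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def parameters(self):
        out = []
        for li, layer in enumerate(self.layers):
            for p in layer.params:
                out.append((li, p))
        return out

    def n_parameters(self) -> int:
        return sum(int(p[1].size) for _, p in self.parameters())

    def forward(self, x, train=False, rng=None):
        for layer in self.layers:
            x = layer.forward(x, train=train, rng=rng)
        return x

    def forward_from(self, x, start: int, train=False, rng=None):
        """Run the tail of the network beginning at layer index ``start``."""
        for layer in self.layers[start:]:
            x = layer.forward(x, train=train, rng=rng)
        return x

    def backward(self, dout, guided=False, upto: int = 0):
        """Backpropagate to the *input* of layer index ``upto``.

        Returns the gradient flowing into that layer (``upto=0`` gives the
        gradient with respect to the network input).
        """
        for layer in reversed(self.layers[upto:]):
            dout = layer.backward(dout, guided=guided)
        return dout

    def state_dict(self) -> dict:
        state = {}
        for li, layer in enumerate(self.layers):
            for p in layer.params:
                state[f"{li}.{p[0]}"] = p[1]
        return state

    def load_state_dict(self, state: dict):
        for li, layer in enumerate(self.layers):
            for p in layer.params:
                key = f"{li}.{p[0]}"
                arr = np.asarray(state[key], dtype=np.float32)
                if arr.shape != p[1].shape:
                    raise ValueError(f"shape mismatch for {key}: {arr.shape} vs {p[1].shape}")
                p[1] = arr


class Adam:
    """Adam with an L2 penalty added to the gradient (coupled weight decay)."""

    def __init__(self, net: Net, lr: float, weight_decay: float = 0.0,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.net = net
        self.lr = float(lr)
        self.wd = float(weight_decay)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p[1]) for _, p in net.parameters()]
        self.v = [np.zeros_like(p[1]) for _, p in net.parameters()]

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, (_, p) in enumerate(self.net.parameters()):
            g = p[2]
            if g is None:
                continue
            if self.wd and p[0] == "W":
                g = g + self.wd * p[1]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            p[1] = p[1] - np.float32(self.lr) * mhat / (np.sqrt(vhat) + self.eps)
            p[2] = None


def multilabel_soft_margin(logits: np.ndarray, labels: np.ndarray) -> float:
    """Mean over samples and tasks of -[y log s(x) + (1-y) log(1-s(x))].

    Computed with log1p-exp stabilisation in float64.
    """
    x = np.asarray(logits, dtype=np.float64)
    y = np.asarray(labels, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("logits and labels must have the same shape")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("labels must be binary (0/1)")
    z = np.where(y == 1.0, -x, x)
    return float(np.mean(np.logaddexp(0.0, z)))


def multilabel_soft_margin_grad(logits: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Gradient of :func:`multilabel_soft_margin` with respect to the logits."""
    x = np.asarray(logits, dtype=np.float64)
    y = np.asarray(labels, dtype=np.float64)
    return ((sigmoid(x) - y) / x.size).astype(np.float32)
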