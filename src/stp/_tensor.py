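"""Minimal reverse-mode automatic differentiation over numpy arrays.

This is the numerical core used by the spatiotemporal blocks and the BPTT
trainer.  It records a tape of operations when gradients are enabled and
replays it backwards on :meth:`Tensor.backward`.  The forward kernels
(`conv2d_forward`, `linear_forward`, ...) are plain numpy functions shared
with the stateful-graph runtime so that graph execution and direct execution
produce bitwise-identical results.

Only the operations needed by the package are implemented: elementwise
arithmetic with broadcasting, matmul, 2-D convolution (via im2col), simple
reductions, relu, the spike step with a rectangular surrogate derivative,
and a fused softmax cross-entropy.
"""

from __future__ import annotations

import contextlib

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable tape recording inside the context (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def grad_enabled() -> bool:
    return _GRAD_ENABLED


# ---------------------------------------------------------------------------
# shared numpy kernels


def same_padding(h: int, w: int, i: int, j: int, sh: int, sw: int):
    """Asymmetric 'same' padding (TensorFlow convention): output ceil(H/s)."""
    ho = -(-h // sh)
    wo = -(-w // sw)
    ph = max((ho - 1) * sh + i - h, 0)
    pw = max((wo - 1) * sw + j - w, 0)
    return (ph // 2, ph - ph // 2), (pw // 2, pw - pw // 2)


def conv2d_forward(x, w, b, stride=(1, 1), padding="same"):
    """2-D convolution, x [B,K,H,W], w [C,K,I,J], b [C] -> [B,C,Ho,Wo].

    Returns (out, cols) where cols is the im2col matrix kept for backward.
    """
    bsz, k, h, wd = x.shape
    c, k2, i, j = w.shape
    if k != k2:
        raise ValueError(f"conv2d: input channels {k} != kernel channels {k2}")
    sh, sw = stride
    if padding == "same":
        (pt, pb), (pl, pr) = same_padding(h, wd, i, j, sh, sw)
    elif padding == "valid":
        (pt, pb), (pl, pr) = (0, 0), (0, 0)
    else:
        (pt, pb), (pl, pr) = padding
    xp = np.pad(x, ((0, 0), (0, 0), (pt, pb), (pl, pr)))
    win = sliding_window_view(xp, (i, j), axis=(2, 3))[:, :, ::sh, ::sw]
    # win: [B,K,Ho,Wo,I,J] -> cols [B,Ho,Wo,K*I*J]
    ho, wo = win.shape[2], win.shape[3]
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        bsz, ho, wo, k * i * j
    )
    out = cols @ w.reshape(c, -1).T + b
    return np.ascontiguousarray(out.transpose(0, 3, 1, 2)), cols


def conv2d_backward(gout, x_shape, w, cols, stride=(1, 1), padding="same"):
    """Gradients of conv2d_forward w.r.t. x, w, b."""
    bsz, k, h, wd = x_shape
    c, _, i, j = w.shape
    sh, sw = stride
    if padding == "same":
        (pt, pb), (pl, pr) = same_padding(h, wd, i, j, sh, sw)
    elif padding == "valid":
        (pt, pb), (pl, pr) = (0, 0), (0, 0)
    else:
        (pt, pb), (pl, pr) = padding
    ho, wo = gout.shape[2], gout.shape[3]
    g = gout.transpose(0, 2, 3, 1)  # [B,Ho,Wo,C]
    gw = np.tensordot(g, cols, axes=([0, 1, 2], [0, 1, 2])).reshape(w.shape)
    gb = g.sum(axis=(0, 1, 2))
    dxp = np.zeros((bsz, k, h + pt + pb, wd + pl + pr), dtype=gout.dtype)
    wk = w.reshape(c, k, i, j)
    for di in range(i):
        for dj in range(j):
            # [B,Ho,Wo,C] x [C,K] -> [B,Ho,Wo,K]
            contrib = g @ wk[:, :, di, dj]
            dxp[:, :, di : di + sh * ho : sh, dj : dj + sw * wo : sw] += (
                contrib.transpose(0, 3, 1, 2)
            )
    gx = dxp[:, :, pt : pt + h, pl : pl + wd]
    return gx, gw, gb


def linear_forward(x, w, b):
    """x [..., S_in], w [S_out, S_in], b [S_out]."""
    return x @ w.T + b


# ---------------------------------------------------------------------------


def _unbroadcast(grad, shape):
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == tuple(shape):
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(a for a, s in enumerate(shape) if s == 1 and grad.shape[a] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A numpy array plus an optional gradient tape node."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_bw")

    # keep numpy from absorbing Tensor operands into object arrays; reflected
    # operators then dispatch back to Tensor.__r*__
    __array_ufunc__ = None

    def __init__(self, data, requires_grad=False):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data, dtype=np.float64) if not isinstance(
            data, np.ndarray
        ) else data
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = ()
        self._bw = None

    # -- construction helpers ------------------------------------------------
    @staticmethod
    def as_tensor(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def copy(self) -> "Tensor":
        return Tensor(self.data.copy(), requires_grad=self.requires_grad)

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def zero_grad(self):
        self.grad = None

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- tape ----------------------------------------------------------------
    def _attach(self, parents, bw):
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            self.requires_grad = True
            self._parents = tuple(parents)
            self._bw = bw
        return self

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._bw is None or node.grad is None:
                continue
            for parent, g in zip(node._parents, node._bw(node.grad)):
                if g is None or not parent.requires_grad:
                    continue
                if parent.grad is None:
                    parent.grad = g
                else:
                    parent.grad = parent.grad + g

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        o = Tensor.as_tensor(other)
        out = Tensor(self.data + o.data)
        return out._attach(
            (self, o),
            lambda g: (_unbroadcast(g, self.shape), _unbroadcast(g, o.shape)),
        )

    __radd__ = __add__

    def __sub__(self, other):
        o = Tensor.as_tensor(other)
        out = Tensor(self.data - o.data)
        return out._attach(
            (self, o),
            lambda g: (_unbroadcast(g, self.shape), _unbroadcast(-g, o.shape)),
        )

    def __rsub__(self, other):
        return Tensor.as_tensor(other) - self

    def __mul__(self, other):
        o = Tensor.as_tensor(other)
        out = Tensor(self.data * o.data)
        return out._attach(
            (self, o),
            lambda g: (
                _unbroadcast(g * o.data, self.shape),
                _unbroadcast(g * self.data, o.shape),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        o = Tensor.as_tensor(other)
        out = Tensor(self.data / o.data)
        return out._attach(
            (self, o),
            lambda g: (
                _unbroadcast(g / o.data, self.shape),
                _unbroadcast(-g * self.data / (o.data * o.data), o.shape),
            ),
        )

    def __neg__(self):
        out = Tensor(-self.data)
        return out._attach((self,), lambda g: (-g,))

    def __pow__(self, p):
        out = Tensor(self.data**p)
        return out._attach((self,), lambda g: (g * p * self.data ** (p - 1),))

    def __matmul__(self, other):
        o = Tensor.as_tensor(other)
        out = Tensor(self.data @ o.data)

        def bw(g):
            ga = g @ np.swapaxes(o.data, -1, -2)
            gb = np.swapaxes(self.data, -1, -2) @ g
            return _unbroadcast(ga, self.shape), _unbroadcast(gb, o.shape)

        return out._attach((self, o), bw)

    def __getitem__(self, idx):
        out = Tensor(self.data[idx])

        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            return (full,)

        return out._attach((self,), bw)

    # -- shape ---------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape))
        return out._attach((self,), lambda g: (g.reshape(self.shape),))

    def transpose(self, *axes):
        out = Tensor(self.data.transpose(axes))
        inv = np.argsort(axes)
        return out._attach((self,), lambda g: (g.transpose(inv),))

    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims))

        def bw(g):
            if axis is None:
                return (np.broadcast_to(g, self.shape).astype(self.data.dtype),)
            ax = axis if isinstance(axis, tuple) else (axis,)
            if not keepdims:
                g = np.expand_dims(g, ax)
            return (np.broadcast_to(g, self.shape).astype(self.data.dtype),)

        return out._attach((self,), bw)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    # -- nonlinearities --------------------------------------------------------
    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0))
        mask = self.data > 0
        return out._attach((self,), lambda g: (g * mask,))


def relu(x: Tensor) -> Tensor:
    return Tensor.as_tensor(x).relu()


def spike(v_m: Tensor, v_th, width: float = 1.0) -> Tensor:
    """Heaviside spike `F = (v_m >= v_th)` with a rectangular surrogate.

    Forward is the exact step of the fire condition (inclusive at threshold);
    backward substitutes a rectangular window of area 1 centred on the
    threshold: dF/dv = 1/width for |v_m - v_th| <= width/2, else 0.
    """
    v_m = Tensor.as_tensor(v_m)
    vth = v_th.data if isinstance(v_th, Tensor) else np.asarray(v_th)
    out = Tensor(np.greater_equal(v_m.data, vth).astype(v_m.data.dtype))
    if width <= 0:
        raise ValueError("surrogate width must be > 0")
    sg = (np.abs(v_m.data - vth) <= width / 2.0) / width
    return out._attach((v_m,), lambda g: (g * sg,))


def conv2d(x: Tensor, w: Tensor, b: Tensor, stride=(1, 1), padding="same") -> Tensor:
    x, w, b = map(Tensor.as_tensor, (x, w, b))
    out_data, cols = conv2d_forward(x.data, w.data, b.data, stride, padding)
    out = Tensor(out_data)

    def bw(g):
        gx, gw, gb = conv2d_backward(g, x.shape, w.data, cols, stride, padding)
        return gx, gw, gb

    return out._attach((x, w, b), bw)


def linear(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    x, w, b = map(Tensor.as_tensor, (x, w, b))
    out = Tensor(linear_forward(x.data, w.data, b.data))

    def bw(g):
        gx = g @ w.data
        gw = np.tensordot(g, x.data, axes=(tuple(range(g.ndim - 1)),) * 2)
        gb = g.sum(axis=tuple(range(g.ndim - 1)))
        return gx, gw, gb

    return out._attach((x, w, b), bw)


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy; labels are integer class indices."""
    logits = Tensor.as_tensor(logits)
    z = logits.data
    if z.ndim != 2:
        raise ValueError("cross_entropy expects [B, n_classes] logits")
    n = z.shape[0]
    zmax = z.max(axis=1, keepdims=True)
    lse = zmax[:, 0] + np.log(np.exp(z - zmax).sum(axis=1))
    nll = lse - z[np.arange(n), labels]
    out = Tensor(np.array(nll.mean()))

    def bw(g):
        p = np.exp(z - zmax)
        p /= p.sum(axis=1, keepdims=True)
        p[np.arange(n), labels] -= 1.0
        return (g * p / n,)

    return out._attach((logits,), bw)


def stack_time(steps: list[Tensor]) -> Tensor:
    """Stack per-timestep tensors [B, ...] into [B, T, ...]."""
    out = Tensor(np.stack([s.data for s in steps], axis=1))

    def bw(g):
        return tuple(g[:, t] for t in range(len(steps)))

    return out._attach(tuple(steps), bw)
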