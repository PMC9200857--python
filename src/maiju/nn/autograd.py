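"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the package's networks need: broadcasted
arithmetic, matmul, 1-D (dilated, strided) convolution via im2col,
elementwise nonlinearities, reductions, indexing/stack/concat, and a fused
softmax cross-entropy with soft targets and per-row weights. Gradients are
dense numpy arrays; the graph is built eagerly and freed after backward.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "_parents", "_backward")

    def __init__(self, data, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    # ---- graph mechanics -------------------------------------------------

    def backward(self, grad=None):
        topo, seen = [], set()

        def visit(node):
            if id(node) in seen:
                return
            seen.add(id(node))
            for p in node._parents:
                visit(p)
            topo.append(node)

        visit(self)
        self.grad = np.ones_like(self.data) if grad is None else np.asarray(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
        # free graph references
        for node in topo:
            node._parents = ()
            node._backward = None

    def _accum(self, grad):
        self.grad = grad if self.grad is None else self.grad + grad

    # ---- operators -------------------------------------------------------

    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data + other.data, (self, other))

        def bw(g):
            self._accum(_unbroadcast(g, self.data.shape))
            other._accum(_unbroadcast(g, other.data.shape))
        out._backward = bw
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data * other.data, (self, other))

        def bw(g):
            self._accum(_unbroadcast(g * other.data, self.data.shape))
            other._accum(_unbroadcast(g * self.data, other.data.shape))
        out._backward = bw
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def matmul(self, other: "Tensor") -> "Tensor":
        out = Tensor(self.data @ other.data, (self, other))

        def bw(g):
            self._accum(g @ other.data.T)
            other._accum(self.data.T @ g)
        out._backward = bw
        return out

    def __matmul__(self, other):
        return self.matmul(other)

    def reshape(self, *shape) -> "Tensor":
        out = Tensor(self.data.reshape(*shape), (self,))

        def bw(g):
            self._accum(g.reshape(self.data.shape))
        out._backward = bw
        return out

    def take(self, idx) -> "Tensor":
        """Row gather along axis 0 (scatter-add on backward)."""
        idx = np.asarray(idx)
        out = Tensor(self.data[idx], (self,))

        def bw(g):
            acc = np.zeros_like(self.data)
            np.add.at(acc, idx, g)
            self._accum(acc)
        out._backward = bw
        return out

    def sum(self, axis=None, keepdims=False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def bw(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())
        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)


# --------------------------------------------------------------------------
# Elementwise nonlinearities
# --------------------------------------------------------------------------

def leaky_relu(x: Tensor, slope: float = 0.1) -> Tensor:
    mask = x.data > 0
    out = Tensor(np.where(mask, x.data, slope * x.data), (x,))

    def bw(g):
        x._accum(np.where(mask, g, slope * g))
    out._backward = bw
    return out


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-np.clip(x.data, -60, 60)))
    out = Tensor(s, (x,))

    def bw(g):
        x._accum(g * s * (1.0 - s))
    out._backward = bw
    return out


def tanh(x: Tensor) -> Tensor:
    t = np.tanh(x.data)
    out = Tensor(t, (x,))

    def bw(g):
        x._accum(g * (1.0 - t * t))
    out._backward = bw
    return out


# --------------------------------------------------------------------------
# Structure ops
# --------------------------------------------------------------------------

def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    out = Tensor(np.stack([t.data for t in tensors], axis=axis), tuple(tensors))

    def bw(g):
        for i, t in enumerate(tensors):
            t._accum(np.take(g, i, axis=axis))
    out._backward = bw
    return out


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]

    def bw(g):
        ofs = 0
        for t, s in zip(tensors, sizes):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(ofs, ofs + s)
            t._accum(g[tuple(sl)])
            ofs += s
    out._backward = bw
    return out


# --------------------------------------------------------------------------
# Convolution (1-D over time, channels-last)
# --------------------------------------------------------------------------

def conv1d(x: Tensor, w: Tensor, b: Tensor, stride: int = 1, pad: int = 0,
           dilation: int = 1) -> Tensor:
    """x: [N, T, Cin], w: [fw, Cin, Cout], b: [Cout] -> [N, T_out, Cout]."""
    fw, cin, cout = w.data.shape
    xp = np.pad(x.data, ((0, 0), (pad, pad), (0, 0))) if pad else x.data
    n, tp, _ = xp.shape
    eff = (fw - 1) * dilation + 1
    t_out = (tp - eff) // stride + 1
    if t_out < 1:
        raise ValueError("input too short for convolution")
    sw = np.lib.stride_tricks.sliding_window_view(xp, eff, axis=1)
    # [N, T_out, Cin, fw] -> [N, T_out, fw, Cin]
    cols = sw[:, ::stride][:, :t_out][..., ::dilation].transpose(0, 1, 3, 2)
    cols2 = np.ascontiguousarray(cols).reshape(n * t_out, fw * cin)
    w2 = w.data.reshape(fw * cin, cout)
    y = (cols2 @ w2 + b.data).reshape(n, t_out, cout)
    out = Tensor(y, (x, w, b))

    def bw(g):
        g2 = g.reshape(n * t_out, cout)
        w._accum((cols2.T @ g2).reshape(fw, cin, cout))
        b._accum(g2.sum(axis=0))
        dcols = (g2 @ w2.T).reshape(n, t_out, fw, cin)
        dxp = np.zeros((n, tp, cin))
        for j in range(fw):
            lo = j * dilation
            dxp[:, lo:lo + stride * t_out:stride, :] += dcols[:, :, j, :]
        x._accum(dxp[:, pad:tp - pad, :] if pad else dxp)
    out._backward = bw
    return out


# --------------------------------------------------------------------------
# Losses
# --------------------------------------------------------------------------

def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: Tensor, targets: np.ndarray,
                          weights: np.ndarray | None = None) -> Tensor:
    """Mean weighted cross-entropy between row softmax and soft targets.

    logits: [N, K]; targets: [N, K] rows summing to 1; weights: [N].
    """
    t = np.asarray(targets, float)
    w = np.ones(t.shape[0]) if weights is None else np.asarray(weights, float)
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=1))
    ce = (t * (lse[:, None] - z)).sum(axis=1)
    denom = max(w.sum(), 1e-12)
    out = Tensor((w * ce).sum() / denom, (logits,))
    p = softmax(logits.data)

    def bw(g):
        logits._accum(g * (w[:, None] * (p - t)) / denom)
    out._backward = bw
    return out


# --------------------------------------------------------------------------
# Optimizer
# --------------------------------------------------------------------------

class Adam:
    """ADAM with the standard bias-corrected moment estimates."""

    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
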