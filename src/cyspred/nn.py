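"""Minimal reverse-mode automatic differentiation on NumPy arrays.

This module provides the numeric substrate for the sequence classifier: a
``Tensor`` wrapper around :class:`numpy.ndarray` that records the computation
graph, the differentiable operations needed by a 1-D CNN, a bidirectional
LSTM, additive attention and fully connected layers, and an Adam optimizer.

All arrays are float64. Every operation's gradient is exercised against
central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "add",
    "mul",
    "matmul",
    "tanh",
    "sigmoid",
    "relu",
    "concat",
    "stack",
    "select",
    "reshape",
    "sum_",
    "mean_",
    "softmax",
    "softmax_cross_entropy",
    "dropout",
    "conv1d",
    "maxpool1d",
    "Adam",
]


class Tensor:
    """Node in the computation graph.

    Parameters
    ----------
    data : array-like
        Value of the node; coerced to a float64 ndarray.
    parents : tuple of Tensor
        Graph predecessors.
    backward_fn : callable or None
        Maps the gradient flowing into this node to a tuple of gradients
        aligned with ``parents``.
    requires_grad : bool
        Leaf flag; interior nodes inherit it from their parents.
    """

    __slots__ = ("data", "grad", "parents", "backward_fn", "requires_grad")

    def __init__(self, data, parents=(), backward_fn=None, requires_grad=False):
        self.data = np.asarray(data, dtype=np.float64)
        self.parents = tuple(parents)
        self.backward_fn = backward_fn
        self.requires_grad = bool(
            requires_grad or any(p.requires_grad for p in self.parents)
        )
        self.grad = None

    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    def backward(self) -> None:
        """Backpropagate from this (scalar) node through the graph."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [self]
        while stack:  # iterative DFS; graphs from BPTT can be deep
            node = stack[-1]
            if id(node) in seen:
                stack.pop()
                continue
            unvisited = [p for p in node.parents if id(p) not in seen and p.requires_grad]
            if unvisited:
                stack.extend(unvisited)
            else:
                seen.add(id(node))
                topo.append(node)
                stack.pop()
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node.backward_fn is None or node.grad is None:
                continue
            grads = node.backward_fn(node.grad)
            for parent, g in zip(node.parents, grads):
                if g is None or not parent.requires_grad:
                    continue
                if parent.grad is None:
                    parent.grad = g.copy() if isinstance(g, np.ndarray) else np.asarray(g)
                else:
                    parent.grad = parent.grad + g


def _reduce_to(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    grad = np.asarray(grad)
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data + b.data

    def backward(g):
        return _reduce_to(g, a.data.shape), _reduce_to(g, b.data.shape)

    return Tensor(out_data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data * b.data

    def backward(g):
        return _reduce_to(g * b.data, a.data.shape), _reduce_to(g * a.data, b.data.shape)

    return Tensor(out_data, (a, b), backward)


def matmul(a, b) -> Tensor:
    """Matrix product supporting batched left operands (e.g. (N,T,D) @ (D,A))."""
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data @ b.data

    def backward(g):
        ga = g @ np.swapaxes(b.data, -1, -2)
        gb = np.swapaxes(a.data, -1, -2) @ g
        return _reduce_to(ga, a.data.shape), _reduce_to(gb, b.data.shape)

    return Tensor(out_data, (a, b), backward)


def tanh(x) -> Tensor:
    x = _as_tensor(x)
    y = np.tanh(x.data)
    return Tensor(y, (x,), lambda g: (g * (1.0 - y * y),))


def sigmoid(x) -> Tensor:
    x = _as_tensor(x)
    y = 1.0 / (1.0 + np.exp(-x.data))
    return Tensor(y, (x,), lambda g: (g * y * (1.0 - y),))


def relu(x) -> Tensor:
    x = _as_tensor(x)
    mask = x.data > 0

    def backward(g):
        return (g * mask,)

    return Tensor(x.data * mask, (x,), backward)


def concat(tensors, axis: int = -1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor(out_data, tuple(tensors), backward)


def stack(tensors, axis: int = 1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out_data = np.stack([t.data for t in tensors], axis=axis)

    def backward(g):
        pieces = np.split(g, len(tensors), axis=axis)
        return tuple(np.squeeze(p, axis=axis) for p in pieces)

    return Tensor(out_data, tuple(tensors), backward)


def select(x, index: int) -> Tensor:
    """Select timestep ``index`` along axis 1 of a (N, T, D) tensor."""
    x = _as_tensor(x)
    out_data = x.data[:, index, :]

    def backward(g):
        gx = np.zeros_like(x.data)
        gx[:, index, :] = g
        return (gx,)

    return Tensor(out_data, (x,), backward)


def reshape(x, shape) -> Tensor:
    x = _as_tensor(x)
    old = x.data.shape
    return Tensor(x.data.reshape(shape), (x,), lambda g: (g.reshape(old),))


def sum_(x, axis=None, keepdims: bool = False) -> Tensor:
    x = _as_tensor(x)
    out_data = x.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if axis is None:
            return (np.broadcast_to(g, x.data.shape).copy(),)
        g2 = g if keepdims else np.expand_dims(g, axis)
        return (np.broadcast_to(g2, x.data.shape).copy(),)

    return Tensor(out_data, (x,), backward)


def mean_(x, axis=None, keepdims: bool = False) -> Tensor:
    x = _as_tensor(x)
    n = x.data.size if axis is None else x.data.shape[axis]
    return mul(sum_(x, axis=axis, keepdims=keepdims), 1.0 / n)


def softmax(x, axis: int = -1) -> Tensor:
    x = _as_tensor(x)
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * p).sum(axis=axis, keepdims=True)
        return (p * (g - dot),)

    return Tensor(p, (x,), backward)


def softmax_cross_entropy(logits, labels) -> Tensor:
    """Mean cross-entropy of integer ``labels`` under softmax of ``logits``."""
    logits = _as_tensor(logits)
    labels = np.asarray(labels, dtype=np.int64)
    n = logits.data.shape[0]
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    logsumexp = np.log(np.exp(z).sum(axis=1, keepdims=True))
    logp = z - logsumexp
    loss = -logp[np.arange(n), labels].mean()
    p = np.exp(logp)

    def backward(g):
        grad = p.copy()
        grad[np.arange(n), labels] -= 1.0
        return (g * grad / n,)

    return Tensor(loss, (logits,), backward)


def dropout(x, rate: float, rng: np.random.Generator, train: bool) -> Tensor:
    """Inverted dropout; identity when ``train`` is False or rate == 0."""
    x = _as_tensor(x)
    if not train or rate <= 0.0:
        return x
    mask = (rng.random(x.data.shape) >= rate) / (1.0 - rate)
    return mul(x, Tensor(mask))


def conv1d(x, w, b) -> Tensor:
    """Valid-mode 1-D convolution.

    x: (N, L, C_in); w: (k, C_in, C_out); b: (C_out,). Output (N, L-k+1, C_out).
    """
    x, w, b = _as_tensor(x), _as_tensor(w), _as_tensor(b)
    k, c_in, c_out = w.data.shape
    n, length, _ = x.data.shape
    t = length - k + 1
    if t < 1:
        raise ValueError(f"input length {length} shorter than kernel {k}")
    # (N, T, C_in, k) -> (N, T, k, C_in) -> (N, T, k*C_in)
    cols = np.lib.stride_tricks.sliding_window_view(x.data, k, axis=1)
    cols = np.ascontiguousarray(cols.transpose(0, 1, 3, 2)).reshape(n, t, k * c_in)
    w2 = w.data.reshape(k * c_in, c_out)
    out_data = cols @ w2 + b.data

    def backward(g):
        gw2 = cols.reshape(n * t, k * c_in).T @ g.reshape(n * t, c_out)
        gb = g.sum(axis=(0, 1))
        gcols = (g @ w2.T).reshape(n, t, k, c_in)
        gx = np.zeros_like(x.data)
        for j in range(k):
            gx[:, j : j + t, :] += gcols[:, :, j, :]
        return gx, gw2.reshape(k, c_in, c_out), gb

    return Tensor(out_data, (x, w, b), backward)


def maxpool1d(x, size: int) -> Tensor:
    """Non-overlapping max pooling along axis 1; trailing remainder dropped."""
    x = _as_tensor(x)
    n, length, c = x.data.shape
    t2 = length // size
    if t2 < 1:
        raise ValueError(f"input length {length} shorter than pool size {size}")
    blocks = x.data[:, : t2 * size, :].reshape(n, t2, size, c)
    idx = blocks.argmax(axis=2)
    out_data = np.take_along_axis(blocks, idx[:, :, None, :], axis=2).squeeze(axis=2)

    def backward(g):
        gb = np.zeros_like(blocks)
        np.put_along_axis(gb, idx[:, :, None, :], g[:, :, None, :], axis=2)
        gx = np.zeros_like(x.data)
        gx[:, : t2 * size, :] = gb.reshape(n, t2 * size, c)
        return (gx,)

    return Tensor(out_data, (x,), backward)


class Adam:
    """Adam optimizer over a name -> Tensor parameter mapping."""

    def __init__(self, params: dict, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.v = {k: np.zeros_like(v.data) for k, v in params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
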