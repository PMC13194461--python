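"""Minimal vectorized reverse-mode automatic differentiation on numpy.

Supports exactly the operations the segmentation network needs: broadcasted
arithmetic, (batched) matrix products, 1D convolution along a point axis,
ReLU/sigmoid, reductions, max pooling, concatenation, point gathering by
index, and a numerically stable log-softmax.  Tensors carry arbitrary
leading batch dimensions so whole mini-batches run as single numpy ops.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """Array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        data = np.asarray(data)
        if data.dtype not in (np.float32, np.float64):
            data = data.astype(np.float64)
        self.data = data
        self.grad = None
        self.requires_grad = requires_grad
        self._parents = ()
        self._backward = None

    # -- graph bookkeeping ------------------------------------------------
    @staticmethod
    def _node(data, parents, backward):
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() expects a scalar loss")
        topo, seen = [], set()

        def visit(node):
            if id(node) in seen or not node.requires_grad:
                return
            seen.add(id(node))
            for p in node._parents:
                visit(p)
            topo.append(node)

        visit(self)
        for node in topo:
            node.grad = np.zeros_like(node.data)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # -- arithmetic -------------------------------------------------------
    @staticmethod
    def _coerce(x, like=None):
        if isinstance(x, Tensor):
            return x
        arr = np.asarray(x)
        if like is not None and arr.ndim == 0:
            arr = arr.astype(like.dtype)   # keep scalars from upcasting float32
        return Tensor(arr)

    def __add__(self, other):
        other = self._coerce(other, like=self.data)

        def bwd(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g, self.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(g, other.shape)

        return self._node(self.data + other.data, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            if self.requires_grad:
                self.grad += -g

        return self._node(-self.data, (self,), bwd)

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __mul__(self, other):
        other = self._coerce(other, like=self.data)

        def bwd(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g * other.data, self.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(g * self.data, other.shape)

        return self._node(self.data * other.data, (self, other), bwd)

    __rmul__ = __mul__

    def matmul(self, other):
        other = self._coerce(other)

        def bwd(g):
            if self.requires_grad:
                self.grad += _unbroadcast(
                    g @ np.swapaxes(other.data, -1, -2), self.shape
                )
            if other.requires_grad:
                other.grad += _unbroadcast(
                    np.swapaxes(self.data, -1, -2) @ g, other.shape
                )

        return self._node(self.data @ other.data, (self, other), bwd)

    __matmul__ = matmul

    # -- activations -------------------------------------------------------
    def relu(self):
        mask = self.data > 0

        def bwd(g):
            if self.requires_grad:
                self.grad += g * mask

        return self._node(self.data * mask, (self,), bwd)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-np.clip(self.data, -500, 500)))

        def bwd(g):
            if self.requires_grad:
                self.grad += g * out_data * (1.0 - out_data)

        return self._node(out_data, (self,), bwd)

    # -- reductions ---------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def bwd(g):
            if not self.requires_grad:
                return
            gg = g
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            self.grad += np.broadcast_to(gg, self.shape)

        return self._node(self.data.sum(axis=axis, keepdims=keepdims), (self,), bwd)

    def mean(self, axis=None, keepdims=False):
        count = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(count))

    def max(self, axis: int, keepdims: bool = False):
        """Max pooling along one axis; gradient routed to the arg-max."""
        idx = np.argmax(self.data, axis=axis)
        out_data = np.take_along_axis(
            self.data, np.expand_dims(idx, axis), axis=axis
        )

        def bwd(g):
            if not self.requires_grad:
                return
            gg = g if keepdims else np.expand_dims(g, axis)
            scatter = np.zeros_like(self.data)
            np.put_along_axis(scatter, np.expand_dims(idx, axis), gg, axis=axis)
            self.grad += scatter

        data = out_data if keepdims else np.squeeze(out_data, axis=axis)
        return self._node(data, (self,), bwd)

    # -- shaping -------------------------------------------------------------
    def reshape(self, *shape):
        old = self.shape

        def bwd(g):
            if self.requires_grad:
                self.grad += g.reshape(old)

        return self._node(self.data.reshape(*shape), (self,), bwd)

    def log_softmax(self):
        """Stable log-softmax over the last axis."""
        shifted = self.data - self.data.max(axis=-1, keepdims=True)
        lse = np.log(np.exp(shifted).sum(axis=-1, keepdims=True))
        out_data = shifted - lse
        soft = np.exp(out_data)

        def bwd(g):
            if self.requires_grad:
                self.grad += g - soft * g.sum(axis=-1, keepdims=True)

        return self._node(out_data, (self,), bwd)


def concat(tensors, axis: int = -1) -> Tensor:
    tensors = [Tensor._coerce(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t.grad += piece

    return Tensor._node(
        np.concatenate([t.data for t in tensors], axis=axis), tensors, bwd
    )


def gather_points(t: Tensor, idx: np.ndarray) -> Tensor:
    """Select point rows: ``t`` is (..., N, C) and ``idx`` (..., M) or
    (..., M, K); result is (..., M, C) or (..., M, K, C)."""
    idx = np.asarray(idx)
    batch = t.data.shape[:-2]
    n, c = t.data.shape[-2:]
    flat = t.data.reshape(-1, n, c)
    fidx = idx.reshape(len(flat), -1)
    out = np.stack([flat[b][fidx[b]] for b in range(len(flat))])
    out = out.reshape(*batch, *idx.shape[len(batch):], c)

    def bwd(g):
        if not t.requires_grad:
            return
        gflat = g.reshape(len(flat), -1, c)
        acc = np.zeros_like(flat)
        for b in range(len(flat)):
            np.add.at(acc[b], fidx[b], gflat[b])
        t.grad += acc.reshape(t.shape)

    return Tensor._node(out, (t,), bwd)


def conv1d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """1D convolution along the point axis with same-length zero padding.

    ``x`` is (..., M, Cin), ``w`` is (k, Cin, Cout) for odd kernel size k,
    ``b`` is (Cout,).  When M < k, the effective padding still yields M
    output positions (taps falling outside are zero).
    """
    k = w.data.shape[0]
    if k % 2 != 1:
        raise ValueError("kernel size must be odd")
    half = k // 2
    m = x.data.shape[-2]
    pad_width = [(0, 0)] * (x.data.ndim - 2) + [(half, half), (0, 0)]
    xp = np.pad(x.data, pad_width)
    out = None
    for t in range(k):
        piece = xp[..., t : t + m, :] @ w.data[t]
        out = piece if out is None else out + piece
    if b is not None:
        out = out + b.data

    def bwd(g):
        if x.requires_grad:
            gx = np.zeros_like(xp)
            for t in range(k):
                gx[..., t : t + m, :] += g @ w.data[t].T
            x.grad += gx[..., half : half + m, :] if half else gx
        if w.requires_grad:
            for t in range(k):
                xt = xp[..., t : t + m, :]
                cin, cout = w.data.shape[1], w.data.shape[2]
                w.grad[t] += xt.reshape(-1, cin).T @ g.reshape(-1, cout)
        if b is not None and b.requires_grad:
            b.grad += g.reshape(-1, g.shape[-1]).sum(axis=0)

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._node(out, parents, bwd)


class Adam:
    """Adam with classic L2 weight decay and a step-decay learning rate."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8,
                 weight_decay=0.0):
        self.params = list(params)
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = np.zeros_like(p.data)

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for p, m, v in zip(self.params, self._m, self._v):
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
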