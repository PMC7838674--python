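"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The networks in this package are small (three-electrode spectrogram inputs,
a few dozen convolutions) so a full deep-learning framework is unnecessary;
this module provides exactly the operations the backbone needs, in NHWC
layout, with float64 arithmetic so that oracle comparisons against
brute-force reference implementations are tight.

Every op builds a node in a tape; :meth:`Tensor.backward` walks the tape in
reverse topological order.  Convolutions use a kernel-offset accumulation
scheme (one ``tensordot`` per kernel tap) which is exact and fast at the
feature-map sizes that arise here.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "add",
    "conv2d",
    "relu",
    "max_pool2d",
    "avg_pool2d",
    "global_max_pool",
    "global_avg_pool",
    "concat_channels",
    "slice_channels",
    "permute_channels",
    "flatten",
    "dense",
    "softmax",
    "softmax_cross_entropy",
]


class Tensor:
    """A NumPy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad=None) -> None:
        """Accumulate gradients of a scalar (or given seed) into the tape."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a seed requires a scalar")
            grad = np.ones_like(self.data)
        # reverse topological order over the tape
        order: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, grad) -> None:
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def _node(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad or p._parents for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def add(a: Tensor, b: Tensor) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    if a.data.shape != b.data.shape:
        raise ValueError(f"add: shape mismatch {a.data.shape} vs {b.data.shape}")
    out_data = a.data + b.data

    def backward(g):
        a._accumulate(g)
        b._accumulate(g)

    return _node(out_data, (a, b), backward)


def relu(x: Tensor) -> Tensor:
    x = as_tensor(x)
    mask = x.data > 0
    out_data = np.where(mask, x.data, 0.0)

    def backward(g):
        x._accumulate(g * mask)

    return _node(out_data, (x,), backward)


def _same_padding(size: int, kernel: int, stride: int) -> tuple[int, int, int]:
    """TF-style SAME padding: output ceil(size/stride), pad split low/high."""
    out = -(-size // stride)
    pad = max((out - 1) * stride + kernel - size, 0)
    return out, pad // 2, pad - pad // 2


def conv2d(x: Tensor, w: Tensor, b: Tensor, stride: int = 1) -> Tensor:
    """2-D convolution (cross-correlation), NHWC input, SAME padding.

    ``x``: (N, H, W, Cin); ``w``: (kh, kw, Cin, Cout); ``b``: (Cout,).
    """
    x, w, b = as_tensor(x), as_tensor(w), as_tensor(b)
    n, h, wd, cin = x.data.shape
    kh, kw, wcin, cout = w.data.shape
    if wcin != cin:
        raise ValueError(f"conv2d: input has {cin} channels, kernel expects {wcin}")
    ho, pt, pb = _same_padding(h, kh, stride)
    wo, pl, pr = _same_padding(wd, kw, stride)
    xp = np.pad(x.data, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
    y = np.empty((n, ho, wo, cout))
    y[:] = b.data
    for di in range(kh):
        for dj in range(kw):
            xv = xp[:, di : di + (ho - 1) * stride + 1 : stride,
                    dj : dj + (wo - 1) * stride + 1 : stride, :]
            y += np.tensordot(xv, w.data[di, dj], axes=([3], [0]))

    def backward(g):
        gxp = np.zeros_like(xp)
        gw = np.zeros_like(w.data)
        for di in range(kh):
            for dj in range(kw):
                sl = (slice(None),
                      slice(di, di + (ho - 1) * stride + 1, stride),
                      slice(dj, dj + (wo - 1) * stride + 1, stride),
                      slice(None))
                gw[di, dj] = np.tensordot(xp[sl], g, axes=([0, 1, 2], [0, 1, 2]))
                gxp[sl] += np.tensordot(g, w.data[di, dj], axes=([3], [1]))
        x._accumulate(gxp[:, pt : pt + h, pl : pl + wd, :])
        w._accumulate(gw)
        b._accumulate(g.sum(axis=(0, 1, 2)))

    return _node(y, (x, w, b), backward)


def _pool2d(x: Tensor, reduce_max: bool) -> Tensor:
    """2x2 stride-2 pooling; a trailing odd row/column is dropped."""
    x = as_tensor(x)
    n, h, w, c = x.data.shape
    ho, wo = h // 2, w // 2
    if ho < 1 or wo < 1:
        raise ValueError(f"pool2d: spatial dims {h}x{w} too small for 2x2 pooling")
    xc = x.data[:, : ho * 2, : wo * 2, :]
    v = xc.reshape(n, ho, 2, wo, 2, c).transpose(0, 1, 3, 5, 2, 4).reshape(
        n, ho, wo, c, 4)
    if reduce_max:
        idx = np.argmax(v, axis=-1)
        out_data = np.take_along_axis(v, idx[..., None], axis=-1)[..., 0]
    else:
        out_data = v.mean(axis=-1)

    def backward(g):
        gv = np.zeros((n, ho, wo, c, 4))
        if reduce_max:
            np.put_along_axis(gv, idx[..., None], g[..., None], axis=-1)
        else:
            gv[:] = g[..., None] / 4.0
        gx = np.zeros_like(x.data)
        gx[:, : ho * 2, : wo * 2, :] = (
            gv.reshape(n, ho, wo, c, 2, 2)
            .transpose(0, 1, 4, 2, 5, 3)
            .reshape(n, ho * 2, wo * 2, c)
        )
        x._accumulate(gx)

    return _node(out_data, (x,), backward)


def max_pool2d(x: Tensor) -> Tensor:
    return _pool2d(x, reduce_max=True)


def avg_pool2d(x: Tensor) -> Tensor:
    return _pool2d(x, reduce_max=False)


def global_max_pool(x: Tensor) -> Tensor:
    """(N, H, W, C) -> (N, C), max over the spatial grid."""
    x = as_tensor(x)
    n, h, w, c = x.data.shape
    flat = x.data.reshape(n, h * w, c)
    idx = np.argmax(flat, axis=1)
    out_data = np.take_along_axis(flat, idx[:, None, :], axis=1)[:, 0, :]

    def backward(g):
        gf = np.zeros_like(flat)
        np.put_along_axis(gf, idx[:, None, :], g[:, None, :], axis=1)
        x._accumulate(gf.reshape(x.data.shape))

    return _node(out_data, (x,), backward)


def global_avg_pool(x: Tensor) -> Tensor:
    x = as_tensor(x)
    n, h, w, c = x.data.shape
    out_data = x.data.mean(axis=(1, 2))

    def backward(g):
        x._accumulate(np.broadcast_to(g[:, None, None, :] / (h * w), x.data.shape).copy())

    return _node(out_data, (x,), backward)


def concat_channels(parts: list[Tensor]) -> Tensor:
    parts = [as_tensor(p) for p in parts]
    sizes = [p.data.shape[-1] for p in parts]
    out_data = np.concatenate([p.data for p in parts], axis=-1)
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for p, lo, hi in zip(parts, offsets[:-1], offsets[1:]):
            p._accumulate(g[..., lo:hi])

    return _node(out_data, tuple(parts), backward)


def slice_channels(x: Tensor, lo: int, hi: int) -> Tensor:
    x = as_tensor(x)
    out_data = x.data[..., lo:hi].copy()

    def backward(g):
        gx = np.zeros_like(x.data)
        gx[..., lo:hi] = g
        x._accumulate(gx)

    return _node(out_data, (x,), backward)


def permute_channels(x: Tensor, perm: np.ndarray) -> Tensor:
    """Reorder the channel axis; ``perm`` must be a permutation."""
    x = as_tensor(x)
    perm = np.asarray(perm)
    out_data = x.data[..., perm].copy()
    inv = np.empty_like(perm)
    inv[perm] = np.arange(perm.size)

    def backward(g):
        x._accumulate(g[..., inv])

    return _node(out_data, (x,), backward)


def flatten(x: Tensor) -> Tensor:
    x = as_tensor(x)
    n = x.data.shape[0]
    out_data = x.data.reshape(n, -1)

    def backward(g):
        x._accumulate(g.reshape(x.data.shape))

    return _node(out_data, (x,), backward)


def dense(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Affine map: (N, D) @ (D, K) + (K,)."""
    x, w, b = as_tensor(x), as_tensor(w), as_tensor(b)
    out_data = x.data @ w.data + b.data

    def backward(g):
        x._accumulate(g @ w.data.T)
        w._accumulate(x.data.T @ g)
        b._accumulate(g.sum(axis=0))

    return _node(out_data, (x, w, b), backward)


def softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax on a plain array (no tape)."""
    z = np.asarray(logits, dtype=np.float64)
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> tuple[Tensor, np.ndarray]:
    """Mean categorical cross-entropy fused with softmax.

    Returns the scalar loss node and the probability matrix (plain array).
    """
    logits = as_tensor(logits)
    labels = np.asarray(labels, dtype=np.intp)
    probs = softmax(logits.data)
    n = probs.shape[0]
    eps = 1e-12  # guards log of an exactly-zero probability
    loss_val = -np.log(probs[np.arange(n), labels] + eps).mean()

    def backward(g):
        grad = probs.copy()
        grad[np.arange(n), labels] -= 1.0
        logits._accumulate(g * grad / n)

    out = _node(np.asarray(loss_val), (logits,), backward)
    return out, probs
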