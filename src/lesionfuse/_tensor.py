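"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The engine provides exactly the operations the encoders, fusion operators and
attribution methods need: broadcasting arithmetic, (batched) matrix products,
2-D convolution and max-pooling via im2col, reductions, shape manipulation,
the usual activations, a numerically stable softmax and cross-entropy.

All data is kept in float32.  Gradients are accumulated on every node of the
graph (not just leaves), which is what Grad-CAM needs: the gradient of a class
score with respect to an intermediate convolutional activation is read straight
off the activation tensor after ``backward``.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "concat", "conv2d", "max_pool2d", "cross_entropy"]

_DTYPE = np.float32


def _as_array(data) -> np.ndarray:
    arr = np.asarray(data, dtype=_DTYPE)
    return arr


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (the reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over prepended axes
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over axes that were 1 in the original shape
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A NumPy array with a gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False,
                 _parents: Sequence["Tensor"] = (),
                 _backward: Callable[[np.ndarray], None] | None = None):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(_parents)
        self._backward = _backward

    # ------------------------------------------------------------------ infra
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def size(self) -> int:
        return self.data.size

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(_DTYPE, copy=True)
        else:
            self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Reverse-mode sweep from this node.  ``grad`` defaults to ones."""
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=_DTYPE))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ------------------------------------------------------------- arithmetic
    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data,
                     requires_grad=self.requires_grad or other.requires_grad,
                     _parents=(self, other))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = _bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, requires_grad=self.requires_grad, _parents=(self,))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(-g)

        out._backward = _bw
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data,
                     requires_grad=self.requires_grad or other.requires_grad,
                     _parents=(self, other))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = _bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out = Tensor(self.data / other.data,
                     requires_grad=self.requires_grad or other.requires_grad,
                     _parents=(self, other))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(
                    -g * self.data / (other.data ** 2), other.data.shape))

        out._backward = _bw
        return out

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, exponent: float):
        out = Tensor(self.data ** exponent, requires_grad=self.requires_grad,
                     _parents=(self,))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(g * exponent * self.data ** (exponent - 1))

        out._backward = _bw
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(np.matmul(self.data, other.data),
                     requires_grad=self.requires_grad or other.requires_grad,
                     _parents=(self, other))

        def _bw(g):
            a, b = self.data, other.data
            if self.requires_grad:
                if b.ndim == 1:
                    ga = np.multiply.outer(g, b) if a.ndim > 1 else g * b
                    if a.ndim == 1 and g.ndim == 0:
                        ga = g * b
                else:
                    gb = np.swapaxes(b, -1, -2)
                    ga = np.matmul(g[..., None, :] if a.ndim == 1 else g, gb)
                    if a.ndim == 1:
                        ga = ga[..., 0, :]
                self._accumulate(_unbroadcast(np.asarray(ga, dtype=_DTYPE),
                                              a.shape))
            if other.requires_grad:
                if a.ndim == 1:
                    gb = np.multiply.outer(a, g) if b.ndim > 1 else a * g
                else:
                    at = np.swapaxes(a, -1, -2)
                    gb = np.matmul(at, g[..., :, None] if b.ndim == 1 else g)
                    if b.ndim == 1:
                        gb = gb[..., 0]
                other._accumulate(_unbroadcast(np.asarray(gb, dtype=_DTYPE),
                                               b.shape))

        out._backward = _bw
        return out

    # ------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     requires_grad=self.requires_grad, _parents=(self,))

        def _bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                grad = np.broadcast_to(g, self.data.shape)
            else:
                g2 = g if keepdims else np.expand_dims(g, axis)
                grad = np.broadcast_to(g2, self.data.shape)
            self._accumulate(np.ascontiguousarray(grad))

        out._backward = _bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ------------------------------------------------------------------ shape
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), requires_grad=self.requires_grad,
                     _parents=(self,))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(g.reshape(self.data.shape))

        out._backward = _bw
        return out

    def flatten_batch(self):
        """Flatten all but the first (batch) axis."""
        return self.reshape(self.data.shape[0], -1)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        out = Tensor(self.data.transpose(axes), requires_grad=self.requires_grad,
                     _parents=(self,))
        inv = np.argsort(axes)

        def _bw(g):
            if self.requires_grad:
                self._accumulate(g.transpose(inv))

        out._backward = _bw
        return out

    def swapaxes(self, a: int, b: int):
        out = Tensor(np.swapaxes(self.data, a, b),
                     requires_grad=self.requires_grad, _parents=(self,))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(np.swapaxes(g, a, b))

        out._backward = _bw
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], requires_grad=self.requires_grad,
                     _parents=(self,))

        def _bw(g):
            if self.requires_grad:
                grad = np.zeros_like(self.data)
                np.add.at(grad, idx, g)
                self._accumulate(grad)

        out._backward = _bw
        return out

    # ------------------------------------------------------------ activations
    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, requires_grad=self.requires_grad,
                     _parents=(self,))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        out._backward = _bw
        return out

    def leaky_relu(self, slope: float = 0.01):
        factor = np.where(self.data > 0, 1.0, slope).astype(_DTYPE)
        out = Tensor(self.data * factor, requires_grad=self.requires_grad,
                     _parents=(self,))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(g * factor)

        out._backward = _bw
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, requires_grad=self.requires_grad, _parents=(self,))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(g * s * (1.0 - s))

        out._backward = _bw
        return out

    def exp(self):
        e = np.exp(self.data)
        out = Tensor(e, requires_grad=self.requires_grad, _parents=(self,))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(g * e)

        out._backward = _bw
        return out

    def log(self):
        out = Tensor(np.log(self.data), requires_grad=self.requires_grad,
                     _parents=(self,))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(g / self.data)

        out._backward = _bw
        return out

    def sqrt(self):
        return self ** 0.5

    def softmax(self, axis: int = -1):
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        s = e / e.sum(axis=axis, keepdims=True)
        out = Tensor(s, requires_grad=self.requires_grad, _parents=(self,))

        def _bw(g):
            if self.requires_grad:
                dot = (g * s).sum(axis=axis, keepdims=True)
                self._accumulate(s * (g - dot))

        out._backward = _bw
        return out


# ----------------------------------------------------------------- functions
def concat(tensors: Iterable[Tensor], axis: int = -1) -> Tensor:
    ts = list(tensors)
    out = Tensor(np.concatenate([t.data for t in ts], axis=axis),
                 requires_grad=any(t.requires_grad for t in ts),
                 _parents=tuple(ts))
    sizes = [t.data.shape[axis] for t in ts]
    offsets = np.cumsum([0] + sizes)

    def _bw(g):
        for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis if axis >= 0 else g.ndim + axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    out._backward = _bw
    return out


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, padding: int):
    b, c, h, w = x.shape
    if padding:
        x = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    oh = (x.shape[2] - kh) // stride + 1
    ow = (x.shape[3] - kw) // stride + 1
    windows = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    windows = windows[:, :, ::stride, ::stride]  # (B, C, OH, OW, kh, kw)
    cols = windows.transpose(0, 2, 3, 1, 4, 5).reshape(b * oh * ow, c * kh * kw)
    return np.ascontiguousarray(cols), oh, ow


def _col2im(dcols: np.ndarray, x_shape, kh, kw, stride, padding, oh, ow):
    b, c, h, w = x_shape
    hp, wp = h + 2 * padding, w + 2 * padding
    dxp = np.zeros((b, c, hp, wp), dtype=_DTYPE)
    d6 = dcols.reshape(b, oh, ow, c, kh, kw).transpose(0, 3, 1, 2, 4, 5)
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i:i + stride * oh:stride, j:j + stride * ow:stride] += \
                d6[:, :, :, :, i, j]
    if padding:
        return dxp[:, :, padding:-padding, padding:-padding]
    return dxp


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """2-D convolution (cross-correlation) of NCHW input with OIHW weights."""
    o, c, kh, kw = weight.data.shape
    b = x.data.shape[0]
    cols, oh, ow = _im2col(x.data, kh, kw, stride, padding)
    wmat = weight.data.reshape(o, -1)
    out_mat = cols @ wmat.T
    if bias is not None:
        out_mat = out_mat + bias.data
    out_data = out_mat.reshape(b, oh, ow, o).transpose(0, 3, 1, 2)
    parents = (x, weight) if bias is None else (x, weight, bias)
    out = Tensor(out_data,
                 requires_grad=any(p.requires_grad for p in parents),
                 _parents=parents)

    def _bw(g):
        gmat = g.transpose(0, 2, 3, 1).reshape(b * oh * ow, o)
        if weight.requires_grad:
            weight._accumulate((gmat.T @ cols).reshape(weight.data.shape))
        if bias is not None and bias.requires_grad:
            bias._accumulate(gmat.sum(axis=0))
        if x.requires_grad:
            dcols = gmat @ wmat
            x._accumulate(_col2im(dcols, x.data.shape, kh, kw, stride,
                                  padding, oh, ow))

    out._backward = _bw
    return out


def max_pool2d(x: Tensor, kernel: int = 3, stride: int = 2,
               padding: int = 1) -> Tensor:
    b, c, h, w = x.data.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)),
                constant_values=-np.inf) if padding else x.data
    oh = (xp.shape[2] - kernel) // stride + 1
    ow = (xp.shape[3] - kernel) // stride + 1
    windows = np.lib.stride_tricks.sliding_window_view(xp, (kernel, kernel),
                                                       axis=(2, 3))
    windows = windows[:, :, ::stride, ::stride]  # (B, C, OH, OW, k, k)
    flat = windows.reshape(b, c, oh, ow, kernel * kernel)
    idx = flat.argmax(axis=-1)
    out_data = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
    out = Tensor(out_data, requires_grad=x.requires_grad, _parents=(x,))

    def _bw(g):
        if not x.requires_grad:
            return
        hp, wp = xp.shape[2], xp.shape[3]
        dxp = np.zeros((b, c, hp, wp), dtype=_DTYPE)
        for k in range(kernel * kernel):
            i, j = divmod(k, kernel)
            mask = idx == k
            dxp[:, :, i:i + stride * oh:stride, j:j + stride * ow:stride] += \
                g * mask
        if padding:
            dxp = dxp[:, :, padding:-padding, padding:-padding]
        x._accumulate(dxp)

    out._backward = _bw
    return out


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of unnormalized class scores against integer labels."""
    labels = np.asarray(labels)
    z = logits.data
    zmax = z.max(axis=1, keepdims=True)
    e = np.exp(z - zmax)
    probs = e / e.sum(axis=1, keepdims=True)
    n = z.shape[0]
    nll = -np.log(probs[np.arange(n), labels] + 1e-12)
    out = Tensor(nll.mean(), requires_grad=logits.requires_grad,
                 _parents=(logits,))

    def _bw(g):
        if logits.requires_grad:
            grad = probs.copy()
            grad[np.arange(n), labels] -= 1.0
            logits._accumulate(grad * (float(g) / n))

    out._backward = _bw
    return out
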