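"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The engine records a tape of operations on :class:`Tensor` objects and
replays it in reverse topological order when :meth:`Tensor.backward` is
called.  Only the primitives needed by the segmentation network are
implemented: broadcasting arithmetic, matmul, reshaping, slicing,
concatenation, reductions, ReLU/GELU/exp/log/sqrt and 2-D zero padding.
Gradients accumulate into ``Tensor.grad`` as plain ``numpy`` arrays.
"""

from __future__ import annotations

import contextlib

import numpy as np

__all__ = ["Tensor", "Parameter", "concat", "no_grad"]

_grad_enabled = True


@contextlib.contextmanager
def no_grad():
    """Disable tape recording (inference mode); ops return constants."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast to reach its shape."""
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
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(np.asarray(other))

    @classmethod
    def _from_op(cls, data, parents, backward) -> "Tensor":
        out = cls(data)
        if _grad_enabled and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._set_backward(backward)
        return out

    def _set_backward(self, fn):
        # drop the closure when not recording, so inference holds no graph
        if self._parents:
            self._backward = fn

    # -- basic introspection --------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    @property
    def size(self):
        return self.data.size

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)
        out = Tensor._from_op(self.data + other.data, (self, other), None)

        def backward(g):
            return _unbroadcast(g, self.shape), _unbroadcast(g, other.shape)

        out._set_backward(backward)
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor._from_op(-self.data, (self,), lambda g: (-g,))
        return out

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out = Tensor._from_op(self.data * other.data, (self, other), None)

        def backward(g):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )

        out._set_backward(backward)
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        out = Tensor._from_op(self.data / other.data, (self, other), None)

        def backward(g):
            return (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            )

        out._set_backward(backward)
        return out

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __pow__(self, exponent: float):
        out = Tensor._from_op(self.data**exponent, (self,), None)
        out._set_backward(lambda g: (g * exponent * self.data ** (exponent - 1),))
        return out

    def __matmul__(self, other):
        other = self._wrap(other)
        out = Tensor._from_op(self.data @ other.data, (self, other), None)

        def backward(g):
            a, b = self.data, other.data
            if b.ndim == 1:
                ga = np.outer(g, b) if a.ndim > 1 else g * b
                gb = a.T @ g if a.ndim > 1 else a * g
                return _unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape)
            ga = g @ np.swapaxes(b, -1, -2)
            gb = np.swapaxes(a, -1, -2) @ g
            return _unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape)

        out._set_backward(backward)
        return out

    # -- shape manipulation ---------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape
        out = Tensor._from_op(self.data.reshape(shape), (self,), None)
        out._set_backward(lambda g: (g.reshape(old),))
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = Tensor._from_op(self.data.transpose(axes), (self,), None)
        out._set_backward(lambda g: (g.transpose(inv),))
        return out

    def __getitem__(self, key):
        out = Tensor._from_op(self.data[key], (self,), None)

        def backward(g):
            # basic (slice/int) indexing only, so no duplicate positions
            full = np.zeros_like(self.data)
            full[key] += g
            return (full,)

        out._set_backward(backward)
        return out

    def pad2d(self, p: int):
        """Zero-pad the two spatial axes of an NHWC tensor by ``p``."""
        widths = ((0, 0), (p, p), (p, p), (0, 0))
        out = Tensor._from_op(np.pad(self.data, widths), (self,), None)
        out._set_backward(lambda g: (g[:, p:-p, p:-p, :],))
        return out

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor._from_op(self.data.sum(axis=axis, keepdims=keepdims), (self,), None)

        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            ax = axis if isinstance(axis, tuple) else (axis,)
            if not keepdims:
                g = np.expand_dims(g, ax)
            return (np.broadcast_to(g, self.shape).copy(),)

        out._set_backward(backward)
        return out

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.size
        else:
            ax = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[a] for a in ax]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False):
        idx = np.argmax(self.data, axis=axis)
        val = np.take_along_axis(self.data, np.expand_dims(idx, axis), axis=axis)
        out_data = val if keepdims else np.squeeze(val, axis=axis)
        out = Tensor._from_op(out_data, (self,), None)

        def backward(g):
            if not keepdims:
                g = np.expand_dims(g, axis)
            full = np.zeros_like(self.data)
            np.put_along_axis(full, np.expand_dims(idx, axis), g, axis=axis)
            return (full,)

        out._set_backward(backward)
        return out

    # -- elementwise nonlinearities -------------------------------------------
    def relu(self):
        mask = self.data > 0
        out = Tensor._from_op(self.data * mask, (self,), None)
        out._set_backward(lambda g: (g * mask,))
        return out

    def exp(self):
        out = Tensor._from_op(np.exp(self.data), (self,), None)
        out._set_backward(lambda g: (g * out.data,))
        return out

    def log(self):
        out = Tensor._from_op(np.log(self.data), (self,), None)
        out._set_backward(lambda g: (g / self.data,))
        return out

    def sqrt(self):
        out = Tensor._from_op(np.sqrt(self.data), (self,), None)
        out._set_backward(lambda g: (g * 0.5 / out.data,))
        return out

    def tanh(self):
        out = Tensor._from_op(np.tanh(self.data), (self,), None)
        out._set_backward(lambda g: (g * (1.0 - out.data**2),))
        return out

    def gelu(self):
        """Gaussian error linear unit (tanh approximation)."""
        c = 0.7978845608028654  # sqrt(2/pi)
        inner = (c * (self + 0.044715 * self * self * self)).tanh()
        return 0.5 * self * (1.0 + inner)

    def softmax(self, axis: int = -1):
        shifted = self - np.max(self.data, axis=axis, keepdims=True)
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)

    # -- backward pass --------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None):
        if grad is None:
            if self.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)

        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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

        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=self.dtype)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:
                if node.grad is None:
                    node.grad = g.copy()
                else:
                    node.grad += g
                continue
            parent_grads = node._backward(g)
            for p, pg in zip(node._parents, parent_grads):
                if not p.requires_grad or pg is None:
                    continue
                if p._backward is None and not p._parents:  # leaf
                    if p.grad is None:
                        p.grad = pg.astype(p.dtype, copy=True)
                    else:
                        p.grad += pg
                else:
                    if id(p) in grads:
                        grads[id(p)] += pg
                    else:
                        grads[id(p)] = pg.astype(node.dtype, copy=False)


class Parameter(Tensor):
    """A trainable leaf tensor.

    ``penalized`` marks weights included in the L2 term of the training
    loss (convolution/attention/feed-forward kernels); biases and
    normalization parameters are created with ``penalized=False``.
    """

    __slots__ = ("penalized",)

    def __init__(self, data, penalized: bool = True):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)
        self.penalized = penalized


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor._from_op(np.concatenate(datas, axis=axis), tensors, None)
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    out._set_backward(backward)
    return out
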