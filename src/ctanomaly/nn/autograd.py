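"""Minimal reverse-mode automatic differentiation on NumPy arrays.

A small tape-based engine in the micrograd tradition, extended with the 2-D
convolution, pooling and normalization primitives needed for convolutional
generative networks.  Every op builds a node holding a closure that propagates
the upstream gradient to its inputs; ``Tensor.backward`` runs a topological
sort and calls the closures in reverse order.

All arithmetic is float32.  The engine is deliberately eager and
single-threaded: determinism under a fixed seed is part of the package
contract.
"""

from __future__ import annotations

import numpy as np

_DTYPE = np.float32


def _as_array(x) -> np.ndarray:
    a = np.asarray(x, dtype=_DTYPE)
    return a


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A NumPy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev: tuple = ()):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _prev)
        self._backward = None
        self._prev = _prev

    # -- graph mechanics -------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(_DTYPE, copy=True)
        else:
            self.grad += g

    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=_DTYPE))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- arithmetic ------------------------------------------------------

    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = _bw
        return out

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = _bw
        return out

    def __neg__(self):
        return self * Tensor(np.float32(-1.0))

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self * other.pow(-1.0)

    def pow(self, p: float) -> "Tensor":
        out = Tensor(self.data ** p, _prev=(self,))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(g * (p * self.data ** (p - 1.0)))

        out._backward = _bw
        return out

    def sqrt(self) -> "Tensor":
        return self.pow(0.5)

    def matmul(self, other: "Tensor") -> "Tensor":
        out = Tensor(self.data @ other.data, _prev=(self, other))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(g @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ g)

        out._backward = _bw
        return out

    def reshape(self, *shape) -> "Tensor":
        out = Tensor(self.data.reshape(*shape), _prev=(self,))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(g.reshape(self.data.shape))

        out._backward = _bw
        return out

    # -- reductions ------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _prev=(self,))

        def _bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())
            else:
                gg = g
                if not keepdims:
                    gg = np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(gg, self.data.shape).copy())

        out._backward = _bw
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * Tensor(np.float32(1.0 / n))

    # -- nonlinearities --------------------------------------------------

    def relu(self) -> "Tensor":
        out = Tensor(np.maximum(self.data, 0.0), _prev=(self,))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(g * (self.data > 0.0))

        out._backward = _bw
        return out

    def leaky_relu(self, alpha: float = 0.2) -> "Tensor":
        out = Tensor(np.where(self.data > 0.0, self.data, alpha * self.data),
                     _prev=(self,))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(g * np.where(self.data > 0.0, 1.0, alpha).astype(_DTYPE))

        out._backward = _bw
        return out

    def tanh(self) -> "Tensor":
        t = np.tanh(self.data)
        out = Tensor(t, _prev=(self,))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(g * (1.0 - t * t))

        out._backward = _bw
        return out

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, _prev=(self,))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(g * (s * (1.0 - s)))

        out._backward = _bw
        return out

    def abs(self) -> "Tensor":
        out = Tensor(np.abs(self.data), _prev=(self,))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(g * np.sign(self.data))

        out._backward = _bw
        return out

    # -- spatial ops -----------------------------------------------------

    def glu(self) -> "Tensor":
        """Gated linear unit over the channel axis of a (B, 2C, H, W) tensor."""
        c2 = self.data.shape[1]
        if c2 % 2:
            raise ValueError("GLU needs an even channel count")
        c = c2 // 2
        a = self.data[:, :c]
        b = self.data[:, c:]
        sb = 1.0 / (1.0 + np.exp(-b))
        out = Tensor(a * sb, _prev=(self,))

        def _bw(g):
            if not self.requires_grad:
                return
            gx = np.empty_like(self.data)
            gx[:, :c] = g * sb
            gx[:, c:] = g * a * sb * (1.0 - sb)
            self._accumulate(gx)

        out._backward = _bw
        return out

    def upsample2x(self) -> "Tensor":
        """Nearest-neighbour 2x upsampling of a (B, C, H, W) tensor."""
        out = Tensor(self.data.repeat(2, axis=2).repeat(2, axis=3), _prev=(self,))

        def _bw(g):
            if self.requires_grad:
                b, c, h2, w2 = g.shape
                self._accumulate(
                    g.reshape(b, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5))
                )

        out._backward = _bw
        return out

    def avg_pool(self, factor: int) -> "Tensor":
        """Average pooling of a (B, C, H, W) tensor by an integer factor."""
        b, c, h, w = self.data.shape
        if h % factor or w % factor:
            raise ValueError("avg_pool needs sizes divisible by the factor")
        pooled = self.data.reshape(b, c, h // factor, factor, w // factor, factor)
        out = Tensor(pooled.mean(axis=(3, 5)), _prev=(self,))

        def _bw(g):
            if self.requires_grad:
                gg = g[:, :, :, None, :, None] / (factor * factor)
                self._accumulate(
                    np.broadcast_to(
                        gg, (b, c, h // factor, factor, w // factor, factor)
                    ).reshape(b, c, h, w).astype(_DTYPE)
                )

        out._backward = _bw
        return out


def conv2d(x: Tensor, w: Tensor, b: Tensor | None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """2-D convolution (cross-correlation) via im2col + GEMM.

    x: (B, C, H, W); w: (O, C, k, k); b: (O,) or None.
    """
    B, C, H, W = x.data.shape
    O, Cw, k, _ = w.data.shape
    if C != Cw:
        raise ValueError(f"channel mismatch: input {C}, weight {Cw}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding))) \
        if padding else x.data
    Hp, Wp = xp.shape[2], xp.shape[3]
    Ho = (Hp - k) // stride + 1
    Wo = (Wp - k) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]            # (B, C, Ho, Wo, k, k)
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)) \
        .reshape(B * Ho * Wo, C * k * k)
    wmat = w.data.reshape(O, C * k * k)
    y = cols @ wmat.T                               # (B*Ho*Wo, O)
    if b is not None:
        y = y + b.data
    out_data = y.reshape(B, Ho, Wo, O).transpose(0, 3, 1, 2)
    prev = (x, w) if b is None else (x, w, b)
    out = Tensor(out_data, _prev=prev)

    def _bw(g):
        gmat = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(B * Ho * Wo, O)
        if w.requires_grad:
            w._accumulate((gmat.T @ cols).reshape(O, C, k, k))
        if b is not None and b.requires_grad:
            b._accumulate(gmat.sum(axis=0))
        if x.requires_grad:
            dcols = (gmat @ wmat).reshape(B, Ho, Wo, C, k, k).transpose(0, 3, 1, 2, 4, 5)
            dxp = np.zeros((B, C, Hp, Wp), dtype=_DTYPE)
            for ki in range(k):
                for kj in range(k):
                    dxp[:, :, ki:ki + stride * Ho:stride,
                        kj:kj + stride * Wo:stride] += dcols[:, :, :, :, ki, kj]
            if padding:
                dxp = dxp[:, :, padding:-padding, padding:-padding]
            x._accumulate(dxp)

    out._backward = _bw
    return out
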