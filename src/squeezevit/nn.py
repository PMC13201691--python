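"""Reverse-mode automatic differentiation over numpy arrays.

A small tape-based engine providing exactly the operations the network
needs: 2-D convolution (im2col + BLAS matmul), max pooling, ReLU, batched
matrix products, layer normalisation, softmax, concatenation, reshapes and
a numerically stable binary cross-entropy on logits, plus the Adam
optimizer.  Forward activations needed for the backward pass are kept on
the tape; the im2col matrix of a convolution is recomputed in backward to
bound peak memory.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable, Iterator, Sequence

import numpy as np

from .errors import ShapeError

__all__ = [
    "Tensor",
    "Parameter",
    "Module",
    "Adam",
    "no_grad",
    "add",
    "matmul",
    "relu",
    "reshape",
    "transpose",
    "concat",
    "mean",
    "pad2d_br",
    "crop2d",
    "conv2d",
    "maxpool2d",
    "layer_norm",
    "softmax",
    "bce_with_logits",
    "sigmoid",
]

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad() -> Iterator[None]:
    """Disable graph construction (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


class Tensor:
    """An n-d array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], None] | None = None

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def size(self) -> int:
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- autograd ------------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        """Run reverse-mode accumulation from this tensor."""
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs can be deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = grad
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                if node._parents:
                    # free intermediate grads; leaves keep theirs
                    node.grad = None
                    node._backward = None
                    node._parents = ()

    # -- operator sugar ------------------------------------------------------
    def __add__(self, other: "Tensor") -> "Tensor":
        return add(self, other)

    def __mul__(self, other) -> "Tensor":
        if isinstance(other, Tensor):
            return _ewise_mul(self, other)
        return _scale(self, float(other))

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        return _scale(self, 1.0 / float(other))

    def __neg__(self) -> "Tensor":
        return _scale(self, -1.0)

    def __sub__(self, other: "Tensor") -> "Tensor":
        return add(self, _scale(other, -1.0))

    def __matmul__(self, other: "Tensor") -> "Tensor":
        return matmul(self, other)

    def reshape(self, *shape: int) -> "Tensor":
        return reshape(self, shape)

    def transpose(self, *axes: int) -> "Tensor":
        return transpose(self, axes)


class Parameter(Tensor):
    """A leaf tensor that is always trainable."""

    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


def _make(data: np.ndarray, parents: Sequence[Tensor], backward) -> Tensor:
    req = _GRAD_ENABLED and any(p.requires_grad for p in parents)
    out = Tensor(data, req)
    if req:
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _accum(t: Tensor, g: np.ndarray) -> None:
    if not t.requires_grad:
        return
    if t.grad is None:
        t.grad = g.copy() if g.base is not None or not g.flags.owndata else g
    else:
        t.grad = t.grad + g


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


# ---------------------------------------------------------------------------
# elementwise / structural primitives
# ---------------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def backward(g: np.ndarray) -> None:
        _accum(a, _unbroadcast(g, a.data.shape))
        _accum(b, _unbroadcast(g, b.data.shape))

    return _make(out_data, (a, b), backward)


def _ewise_mul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data * b.data

    def backward(g: np.ndarray) -> None:
        _accum(a, _unbroadcast(g * b.data, a.data.shape))
        _accum(b, _unbroadcast(g * a.data, b.data.shape))

    return _make(out_data, (a, b), backward)


def _scale(a: Tensor, s: float) -> Tensor:
    def backward(g: np.ndarray) -> None:
        _accum(a, g * s)

    return _make(a.data * s, (a,), backward)


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0
    out_data = a.data * mask

    def backward(g: np.ndarray) -> None:
        _accum(a, g * mask)

    return _make(out_data, (a,), backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    """Batched matrix product with numpy broadcasting over leading axes."""
    out_data = np.matmul(a.data, b.data)

    def backward(g: np.ndarray) -> None:
        if a.requires_grad:
            ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
            _accum(a, _unbroadcast(ga, a.data.shape))
        if b.requires_grad:
            gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
            _accum(b, _unbroadcast(gb, b.data.shape))

    return _make(out_data, (a, b), backward)


def reshape(a: Tensor, shape: Sequence[int]) -> Tensor:
    shape = tuple(shape)
    orig = a.data.shape

    def backward(g: np.ndarray) -> None:
        _accum(a, g.reshape(orig))

    return _make(a.data.reshape(shape), (a,), backward)


def transpose(a: Tensor, axes: Sequence[int]) -> Tensor:
    axes = tuple(axes)
    inv = tuple(np.argsort(axes))

    def backward(g: np.ndarray) -> None:
        _accum(a, np.ascontiguousarray(g.transpose(inv)))

    return _make(np.ascontiguousarray(a.data.transpose(axes)), (a,), backward)


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    tensors = list(tensors)
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g: np.ndarray) -> None:
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            _accum(t, g[tuple(sl)])

    return _make(out_data, tensors, backward)


def mean(a: Tensor, axes: Sequence[int]) -> Tensor:
    axes = tuple(axes)
    out_data = a.data.mean(axis=axes)
    count = int(np.prod([a.data.shape[ax] for ax in axes]))

    def backward(g: np.ndarray) -> None:
        ge = np.expand_dims(g, axes)
        _accum(a, np.broadcast_to(ge / count, a.data.shape))

    return _make(out_data, (a,), backward)


def pad2d_br(a: Tensor, pad_h: int, pad_w: int) -> Tensor:
    """Zero-pad the bottom/right of an NCHW map (patch divisibility policy)."""
    if pad_h == 0 and pad_w == 0:
        return a
    out_data = np.pad(a.data, ((0, 0), (0, 0), (0, pad_h), (0, pad_w)))
    H, W = a.data.shape[2], a.data.shape[3]

    def backward(g: np.ndarray) -> None:
        _accum(a, g[:, :, :H, :W])

    return _make(out_data, (a,), backward)


def crop2d(a: Tensor, H: int, W: int) -> Tensor:
    """Crop an NCHW map to the top-left H×W window (inverse of pad2d_br)."""
    if a.data.shape[2] == H and a.data.shape[3] == W:
        return a
    out_data = np.ascontiguousarray(a.data[:, :, :H, :W])
    full_h, full_w = a.data.shape[2], a.data.shape[3]

    def backward(g: np.ndarray) -> None:
        gp = np.zeros(a.data.shape, dtype=g.dtype)
        gp[:, :, :H, :W] = g
        _accum(a, gp)

    return _make(out_data, (a,), backward)


# ---------------------------------------------------------------------------
# convolution and pooling
# ---------------------------------------------------------------------------

def _conv1x1(x: Tensor, w: Tensor, b: Tensor | None) -> Tensor:
    """Pointwise conv as a pure batched GEMM over the flattened spatial axis."""
    B, C, H, W = x.data.shape
    Cout = w.data.shape[0]
    wm = w.data.reshape(Cout, C)
    xm = x.data.reshape(B, C, H * W)
    y = np.matmul(wm, xm)
    if b is not None:
        y += b.data[:, None]
    out_data = y.reshape(B, Cout, H, W)

    def backward(g: np.ndarray) -> None:
        gm = np.ascontiguousarray(g).reshape(B, Cout, H * W)
        if w.requires_grad:
            gw = np.matmul(gm, xm.transpose(0, 2, 1)).sum(axis=0)
            _accum(w, gw.reshape(w.data.shape))
        if b is not None and b.requires_grad:
            _accum(b, gm.sum(axis=(0, 2)))
        if x.requires_grad:
            _accum(x, np.matmul(wm.T, gm).reshape(B, C, H, W))

    return _make(out_data, tuple(t for t in (x, w, b) if t is not None), backward)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1,
           padding: int = 0) -> Tensor:
    """2-D convolution, weights (C_out, C_in, k, k), NCHW activations.

    Implemented as a shift-and-add over the k² kernel offsets, each a
    batched channel GEMM; 1×1/stride-1 convs take a copy-free fast path.
    """
    B, C, H, W = x.data.shape
    Cout, Cin, k, _ = w.data.shape
    if C != Cin:
        raise ShapeError(f"conv2d: input has {C} channels, weights expect {Cin}")
    s, p = int(stride), int(padding)
    if k == 1 and s == 1 and p == 0:
        return _conv1x1(x, w, b)
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
    Ho = (H + 2 * p - k) // s + 1
    Wo = (W + 2 * p - k) // s + 1
    wk = w.data  # (Cout, Cin, k, k)

    def slab(src: np.ndarray, ki: int, kj: int) -> np.ndarray:
        sl = src[:, :, ki:ki + s * Ho:s, kj:kj + s * Wo:s]
        return np.ascontiguousarray(sl).reshape(B, Cin, Ho * Wo)

    y = np.zeros((B, Cout, Ho * Wo), dtype=x.data.dtype)
    for ki in range(k):
        for kj in range(k):
            y += np.matmul(np.ascontiguousarray(wk[:, :, ki, kj]), slab(xp, ki, kj))
    if b is not None:
        y += b.data[:, None]
    out_data = y.reshape(B, Cout, Ho, Wo)

    def backward(g: np.ndarray) -> None:
        gm = np.ascontiguousarray(g).reshape(B, Cout, Ho * Wo)
        gw = np.zeros_like(wk) if w.requires_grad else None
        gxp = np.zeros_like(xp) if x.requires_grad else None
        for ki in range(k):
            for kj in range(k):
                if gw is not None:
                    sl = slab(xp, ki, kj)  # recomputed to cap peak memory
                    gw[:, :, ki, kj] = np.matmul(gm, sl.transpose(0, 2, 1)).sum(axis=0)
                if gxp is not None:
                    dsl = np.matmul(np.ascontiguousarray(wk[:, :, ki, kj]).T, gm)
                    gxp[:, :, ki:ki + s * Ho:s, kj:kj + s * Wo:s] += dsl.reshape(
                        B, Cin, Ho, Wo)
        if gw is not None:
            _accum(w, gw)
        if b is not None and b.requires_grad:
            _accum(b, gm.sum(axis=(0, 2)))
        if gxp is not None:
            _accum(x, gxp[:, :, p:p + H, p:p + W] if p else gxp)

    return _make(out_data, tuple(t for t in (x, w, b) if t is not None), backward)


def maxpool2d(x: Tensor, kernel: int = 3, stride: int = 2, padding: int = 1) -> Tensor:
    """Max pooling with floor-mode output dims; padded cells hold -inf.

    Gradient routes each window's incoming gradient to the first offset
    (row-major) attaining the maximum, matching argmax tie-breaking.
    """
    B, C, H, W = x.data.shape
    k, s, p = int(kernel), int(stride), int(padding)
    if p:
        xp = np.full((B, C, H + 2 * p, W + 2 * p), -np.inf, dtype=x.data.dtype)
        xp[:, :, p:p + H, p:p + W] = x.data
    else:
        xp = x.data
    Ho = (H + 2 * p - k) // s + 1
    Wo = (W + 2 * p - k) // s + 1
    out_data = None
    for ki in range(k):
        for kj in range(k):
            sl = xp[:, :, ki:ki + s * Ho:s, kj:kj + s * Wo:s]
            out_data = sl.copy() if out_data is None else np.maximum(out_data, sl)

    def backward(g: np.ndarray) -> None:
        gxp = np.zeros(xp.shape, dtype=g.dtype)
        claimed = np.zeros(out_data.shape, dtype=bool)
        for ki in range(k):
            for kj in range(k):
                sl = xp[:, :, ki:ki + s * Ho:s, kj:kj + s * Wo:s]
                m = (sl == out_data) & ~claimed
                claimed |= m
                gxp[:, :, ki:ki + s * Ho:s, kj:kj + s * Wo:s] += g * m
        _accum(x, gxp[:, :, p:p + H, p:p + W] if p else gxp)

    return _make(out_data, (x,), backward)


# ---------------------------------------------------------------------------
# normalisation, softmax, loss
# ---------------------------------------------------------------------------

def layer_norm(x: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    """Layer normalisation over the last axis."""
    mu = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out_data = gain.data * xhat + bias.data

    def backward(g: np.ndarray) -> None:
        if gain.requires_grad:
            _accum(gain, (g * xhat).sum(axis=tuple(range(g.ndim - 1))))
        if bias.requires_grad:
            _accum(bias, g.sum(axis=tuple(range(g.ndim - 1))))
        if x.requires_grad:
            gh = g * gain.data
            gx = inv * (
                gh
                - gh.mean(axis=-1, keepdims=True)
                - xhat * (gh * xhat).mean(axis=-1, keepdims=True)
            )
            _accum(x, gx)

    return _make(out_data, (x, gain, bias), backward)


def softmax(x: Tensor) -> Tensor:
    """Softmax over the last axis."""
    z = x.data - x.data.max(axis=-1, keepdims=True)
    e = np.exp(z)
    out_data = e / e.sum(axis=-1, keepdims=True)

    def backward(g: np.ndarray) -> None:
        dot = (g * out_data).sum(axis=-1, keepdims=True)
        _accum(x, out_data * (g - dot))

    return _make(out_data, (x,), backward)


def sigmoid(z: np.ndarray) -> np.ndarray:
    """Numerically stable logistic function (plain ndarray helper)."""
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy computed in the stable logit form.

    loss = mean( y·softplus(−z) + (1−y)·softplus(z) ), with
    softplus(z) = max(z,0) + log1p(exp(−|z|)).
    """
    z = logits.data
    y = np.asarray(targets, dtype=z.dtype)
    if z.shape != y.shape:
        raise ShapeError(f"bce_with_logits: logits {z.shape} vs labels {y.shape}")
    sp_pos = np.maximum(z, 0) + np.log1p(np.exp(-np.abs(z)))  # softplus(z)
    loss = float((sp_pos - y * z).mean())

    def backward(g: np.ndarray) -> None:
        _accum(logits, (g / z.size) * (sigmoid(z) - y).astype(z.dtype))

    return _make(np.asarray(loss), (logits,), backward)


# ---------------------------------------------------------------------------
# modules and optimizer
# ---------------------------------------------------------------------------

class Module:
    """Base class with recursive parameter discovery."""

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        seen: set[int] = set()

        def walk(obj) -> None:
            if isinstance(obj, Parameter):
                if id(obj) not in seen:
                    seen.add(id(obj))
                    params.append(obj)
            elif isinstance(obj, Module):
                for v in vars(obj).values():
                    walk(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    walk(v)

        walk(self)
        return params

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays: Iterable[np.ndarray]) -> None:
        arrays = list(arrays)
        params = self.parameters()
        if len(arrays) != len(params):
            raise ShapeError(
                f"checkpoint holds {len(arrays)} arrays, model has {len(params)}"
            )
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ShapeError(f"checkpoint array {a.shape} vs param {p.data.shape}")
            p.data = a.astype(p.data.dtype)


def kaiming_conv(rng: np.random.Generator, c_out: int, c_in: int, k: int,
                 nonneg_sum: bool = False) -> Parameter:
    """He fan-in normal initialisation for a conv weight.

    ``nonneg_sum`` flips each filter so its coefficient sum is >= 0.  The
    He distribution is sign-symmetric, so this preserves it — but for a
    very narrow layer fed by non-negative activations (the 1-channel-wide
    squeeze bottleneck, the 3-channel stem) it guarantees the filter's
    mean response is not driven below the ReLU cut for every pixel.
    """
    fan_in = c_in * k * k
    std = np.sqrt(2.0 / fan_in)
    w = rng.normal(0.0, std, size=(c_out, c_in, k, k))
    if nonneg_sum:
        flip = np.sign(w.sum(axis=(1, 2, 3)))
        flip[flip == 0] = 1.0
        w *= flip[:, None, None, None]
    return Parameter(w.astype(np.float32))


def kaiming_linear(rng: np.random.Generator, d_in: int, d_out: int) -> Parameter:
    std = np.sqrt(2.0 / d_in)
    return Parameter(rng.normal(0.0, std, size=(d_in, d_out)).astype(np.float32))


def zeros_param(*shape: int) -> Parameter:
    return Parameter(np.zeros(shape, dtype=np.float32))


def const_param(value: float, *shape: int) -> Parameter:
    return Parameter(np.full(shape, value, dtype=np.float32))


# Small positive bias for ReLU-gated convs. The narrowest squeeze layer is a
# single channel wide; with zero bias a sign-unlucky init leaves that ReLU
# dead everywhere and the whole network constant, so give every gated unit a
# nudge into its linear region.
RELU_BIAS_INIT = 0.01


def ones_param(*shape: int) -> Parameter:
    return Parameter(np.ones(shape, dtype=np.float32))


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, params: Sequence[Parameter], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = float(eps)
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad.astype(p.data.dtype)
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * (g * g)
            mhat = self.m[i] / bc1
            vhat = self.v[i] / bc2
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
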