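"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Provides the handful of differentiable operations the estrus-detection
models need (dense and convolutional layers, attention building blocks,
layer normalisation, softmax cross-entropy) plus an Adam optimiser.
Everything is float64; determinism is guaranteed by seeding the
``numpy.random.Generator`` passed to the initialisers.
"""

from __future__ import annotations

import copy
from typing import Callable, Sequence

import numpy as np

DTYPE = np.float64

_GRAD_ENABLED = True


class no_grad:
    """Context manager: build no graph (faster, cycle-free inference)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev: tuple = ()):
        self.data = np.asarray(data, dtype=DTYPE)
        self.requires_grad = requires_grad
        self.grad: np.ndarray | None = None
        self._backward: Callable[[], None] = lambda: None
        self._prev = _prev

    # -- convenience -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        """Backpropagate from this (scalar or any-shape) tensor."""
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            t._backward()
        # free the graph eagerly: the closures reference their outputs,
        # forming reference cycles the gc would otherwise have to find
        for t in topo:
            t._backward = _noop
            t._prev = ()

    # -- operator sugar ----------------------------------------------
    def __add__(self, other):
        return add(self, _wrap(other))

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, _wrap(other))

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, Tensor(-1.0))

    def __sub__(self, other):
        return add(self, -_wrap(other))

    def __rsub__(self, other):
        return add(_wrap(other), -self)

    def __matmul__(self, other):
        return matmul(self, _wrap(other))

    def __truediv__(self, other):
        other = _wrap(other)
        return mul(self, powc(other, -1.0))

    def reshape(self, *shape):
        return reshape(self, shape)

    def transpose(self, *axes):
        return transpose(self, axes)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis, keepdims)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _needs(*ts: Tensor) -> bool:
    return any(t.requires_grad for t in ts)


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum gradient g down to ``shape`` (inverse of NumPy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def _noop() -> None:
    return None


def _make(data, parents: Sequence[Tensor]) -> Tensor:
    if _GRAD_ENABLED and _needs(*parents):
        return Tensor(data, requires_grad=True, _prev=tuple(parents))
    return Tensor(data)


def _set_backward(out: Tensor, fn: Callable[[], None]) -> None:
    """Attach the backward closure only on graph-building tensors, so
    inference tensors carry no reference cycles."""
    if out.requires_grad:
        out._backward = fn


# ---------------------------------------------------------------------
# elementwise / linear algebra
# ---------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    out = _make(a.data + b.data, (a, b))

    def _bw():
        if a.requires_grad:
            a._accum(_unbroadcast(out.grad, a.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(out.grad, b.shape))

    _set_backward(out, _bw)
    return out


def mul(a: Tensor, b: Tensor) -> Tensor:
    out = _make(a.data * b.data, (a, b))

    def _bw():
        if a.requires_grad:
            a._accum(_unbroadcast(out.grad * b.data, a.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(out.grad * a.data, b.shape))

    _set_backward(out, _bw)
    return out


def powc(a: Tensor, p: float) -> Tensor:
    out = _make(a.data ** p, (a,))

    def _bw():
        if a.requires_grad:
            a._accum(out.grad * p * a.data ** (p - 1.0))

    _set_backward(out, _bw)
    return out


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out = _make(a.data @ b.data, (a, b))

    def _bw():
        if a.requires_grad:
            ga = out.grad @ np.swapaxes(b.data, -1, -2)
            a._accum(_unbroadcast(ga, a.shape))
        if b.requires_grad:
            gb = np.swapaxes(a.data, -1, -2) @ out.grad
            b._accum(_unbroadcast(gb, b.shape))

    _set_backward(out, _bw)
    return out


def relu(a: Tensor) -> Tensor:
    out = _make(np.maximum(a.data, 0.0), (a,))

    def _bw():
        if a.requires_grad:
            a._accum(out.grad * (a.data > 0))

    _set_backward(out, _bw)
    return out


def sigmoid(a: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-a.data))
    out = _make(s, (a,))

    def _bw():
        if a.requires_grad:
            a._accum(out.grad * s * (1.0 - s))

    _set_backward(out, _bw)
    return out


def softmax(a: Tensor, axis: int = -1) -> Tensor:
    z = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)
    out = _make(s, (a,))

    def _bw():
        if a.requires_grad:
            g = out.grad
            a._accum(s * (g - (g * s).sum(axis=axis, keepdims=True)))

    _set_backward(out, _bw)
    return out


def tsum(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    out = _make(a.data.sum(axis=axis, keepdims=keepdims), (a,))

    def _bw():
        if a.requires_grad:
            g = out.grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            a._accum(np.broadcast_to(g, a.shape).copy())

    _set_backward(out, _bw)
    return out


def tmean(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    n = a.data.size if axis is None else a.data.shape[axis]
    return mul(tsum(a, axis, keepdims), Tensor(1.0 / n))


def reshape(a: Tensor, shape) -> Tensor:
    out = _make(a.data.reshape(shape), (a,))

    def _bw():
        if a.requires_grad:
            a._accum(out.grad.reshape(a.shape))

    _set_backward(out, _bw)
    return out


def transpose(a: Tensor, axes) -> Tensor:
    out = _make(a.data.transpose(axes), (a,))
    inv = np.argsort(axes)

    def _bw():
        if a.requires_grad:
            a._accum(out.grad.transpose(inv))

    _set_backward(out, _bw)
    return out


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    out = _make(np.concatenate([t.data for t in tensors], axis=axis), tensors)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def _bw():
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * out.grad.ndim
                idx[axis] = slice(lo, hi)
                t._accum(out.grad[tuple(idx)])

    _set_backward(out, _bw)
    return out


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-6) -> Tensor:
    """Layer normalisation over the last axis."""
    mu = x.data.mean(axis=-1, keepdims=True)
    xc = x.data - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out = _make(gamma.data * xhat + beta.data, (x, gamma, beta))
    n = x.data.shape[-1]

    def _bw():
        g = out.grad
        if gamma.requires_grad:
            gamma._accum(_unbroadcast(g * xhat, gamma.shape))
        if beta.requires_grad:
            beta._accum(_unbroadcast(g, beta.shape))
        if x.requires_grad:
            gh = g * gamma.data
            x._accum(inv * (gh - gh.mean(axis=-1, keepdims=True)
                            - xhat * (gh * xhat).mean(axis=-1, keepdims=True)))

    _set_backward(out, _bw)
    return out


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy. labels: int array (B,)."""
    z = logits.data - logits.data.max(axis=-1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=-1, keepdims=True)
    B = logits.data.shape[0]
    nll = -np.log(p[np.arange(B), labels] + 1e-300)
    out = _make(nll.mean(), (logits,))

    def _bw():
        if logits.requires_grad:
            g = p.copy()
            g[np.arange(B), labels] -= 1.0
            logits._accum(out.grad * g / B)

    _set_backward(out, _bw)
    return out


# ---------------------------------------------------------------------
# convolution / pooling
# ---------------------------------------------------------------------

def _pad1d(x: np.ndarray, pl: int, pr: int, mode: str) -> np.ndarray:
    if pl == 0 and pr == 0:
        return x
    if mode == "wrap":
        return np.pad(x, ((0, 0), (0, 0), (pl, pr)), mode="wrap")
    return np.pad(x, ((0, 0), (0, 0), (pl, pr)))


def conv1d(x: Tensor, w: Tensor, b: Tensor | None, dilation: int = 1,
           pad_mode: str = "wrap") -> Tensor:
    """Same-length 1-D convolution. x: (B,Cin,L), w: (Cout,Cin,K)."""
    B, Cin, L = x.shape
    Cout, _, K = w.shape
    eff = dilation * (K - 1) + 1
    pl = (eff - 1) // 2
    pr = eff - 1 - pl
    xp = _pad1d(x.data, pl, pr, pad_mode)
    s = xp.strides
    win = np.ascontiguousarray(np.lib.stride_tricks.as_strided(
        xp, (B, Cin, L, K), (s[0], s[1], s[2], s[2] * dilation)))
    # (B,L,Cin*K) @ (Cin*K,Cout) -> (B,L,Cout)
    win2 = win.transpose(0, 2, 1, 3).reshape(B, L, Cin * K)
    # contiguous output: keeps downstream reduction order layout-independent
    out_data = np.ascontiguousarray(
        (win2 @ w.data.reshape(Cout, Cin * K).T).transpose(0, 2, 1))
    if b is not None:
        out_data = out_data + b.data[None, :, None]
    parents = (x, w) if b is None else (x, w, b)
    out = _make(out_data, parents)

    def _bw():
        g = out.grad  # (B,Cout,L)
        if w.requires_grad:
            gw = np.tensordot(g.transpose(1, 0, 2).reshape(Cout, B * L),
                              win2.reshape(B * L, Cin * K), axes=1)
            w._accum(gw.reshape(Cout, Cin, K))
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2)))
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for k in range(K):
                # dL/dxp[:, :, k*dil + t] += sum_o g[:,o,t] * w[o,:,k]
                gxp[:, :, k * dilation:k * dilation + L] += np.einsum(
                    "bol,oc->bcl", g, w.data[:, :, k], optimize=True)
            if pad_mode == "wrap":
                core = gxp[:, :, pl:pl + L].copy()
                if pl:
                    core[:, :, -pl:] += gxp[:, :, :pl]
                if pr:
                    core[:, :, :pr] += gxp[:, :, pl + L:]
                x._accum(core)
            else:
                x._accum(gxp[:, :, pl:pl + L])

    _set_backward(out, _bw)
    return out


def avg_pool1d(x: Tensor, factor: int) -> Tensor:
    """Non-overlapping average pooling; trailing remainder is dropped."""
    B, C, L = x.shape
    Lo = L // factor
    xv = x.data[:, :, :Lo * factor].reshape(B, C, Lo, factor)
    out = _make(xv.mean(axis=3), (x,))

    def _bw():
        if x.requires_grad:
            g = np.zeros_like(x.data)
            g[:, :, :Lo * factor] = np.repeat(out.grad, factor, axis=2) / factor
            x._accum(g)

    _set_backward(out, _bw)
    return out


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, padding: int = 1) -> Tensor:
    """Stride-1 zero-padded 2-D convolution. x: (B,C,H,W), w: (O,C,KH,KW)."""
    B, C, H, W = x.shape
    O, _, KH, KW = w.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    Ho = H + 2 * padding - KH + 1
    Wo = W + 2 * padding - KW + 1
    s = xp.strides
    win = np.lib.stride_tricks.as_strided(
        xp, (B, C, Ho, Wo, KH, KW), (s[0], s[1], s[2], s[3], s[2], s[3]))
    out_data = np.ascontiguousarray(
        np.einsum("bchwij,ocij->bohw", win, w.data, optimize=True))
    if b is not None:
        out_data = out_data + b.data[None, :, None, None]
    parents = (x, w) if b is None else (x, w, b)
    out = _make(out_data, parents)

    def _bw():
        g = out.grad
        if w.requires_grad:
            w._accum(np.einsum("bohw,bchwij->ocij", g, win, optimize=True))
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for i in range(KH):
                for j in range(KW):
                    gxp[:, :, i:i + Ho, j:j + Wo] += np.einsum(
                        "bohw,oc->bchw", g, w.data[:, :, i, j], optimize=True)
            x._accum(gxp[:, :, padding:padding + H, padding:padding + W]
                     if padding else gxp)

    _set_backward(out, _bw)
    return out


def avg_pool2d(x: Tensor, factor: int = 2) -> Tensor:
    B, C, H, W = x.shape
    Ho, Wo = H // factor, W // factor
    xv = x.data[:, :, :Ho * factor, :Wo * factor].reshape(
        B, C, Ho, factor, Wo, factor)
    out = _make(xv.mean(axis=(3, 5)), (x,))

    def _bw():
        if x.requires_grad:
            g = np.zeros_like(x.data)
            gg = np.repeat(np.repeat(out.grad, factor, axis=2), factor, axis=3)
            g[:, :, :Ho * factor, :Wo * factor] = gg / (factor * factor)
            x._accum(g)

    _set_backward(out, _bw)
    return out


# ---------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------

class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Container with recursive parameter discovery (torch-like)."""

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        seen: set[int] = set()

        def collect(obj):
            if isinstance(obj, Parameter):
                if id(obj) not in seen:
                    seen.add(id(obj))
                    params.append(obj)
            elif isinstance(obj, Module):
                for v in vars(obj).values():
                    collect(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    collect(v)

        collect(self)
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_dict(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_dict(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(params) != len(state):
            raise ValueError("state length mismatch")
        for p, d in zip(params, state):
            p.data = np.array(d, dtype=DTYPE).reshape(p.data.shape)

    def copy_state(self) -> list[np.ndarray]:
        return copy.deepcopy(self.state_dict())


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=shape)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.W = Parameter(glorot(rng, d_in, d_out, (d_in, d_out)))
        self.b = Parameter(np.zeros(d_out))

    def __call__(self, x: Tensor) -> Tensor:
        return matmul(x, self.W) + self.b


class Conv1d(Module):
    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 dilation: int = 1, pad_mode: str = "wrap"):
        fan_in = c_in * k
        self.weight = Parameter(glorot(rng, fan_in, c_out * k, (c_out, c_in, k)))
        self.bias = Parameter(np.zeros(c_out))
        self.dilation = dilation
        self.pad_mode = pad_mode

    def __call__(self, x: Tensor) -> Tensor:
        return conv1d(x, self.weight, self.bias, self.dilation, self.pad_mode)


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 padding: int | None = None):
        fan_in = c_in * k * k
        self.weight = Parameter(glorot(rng, fan_in, c_out * k * k, (c_out, c_in, k, k)))
        self.bias = Parameter(np.zeros(c_out))
        self.padding = (k - 1) // 2 if padding is None else padding

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.padding)


class LayerNorm(Module):
    def __init__(self, dim: int):
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))

    def __call__(self, x: Tensor) -> Tensor:
        return layer_norm(x, self.gamma, self.beta)


class Adam:
    """Adam optimiser (Kingma & Ba) over a parameter list."""

    def __init__(self, params: Sequence[Parameter], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
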