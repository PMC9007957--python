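"""Minimal reverse-mode autodiff engine for small convolutional segmentation networks.

Everything is float32 and NHWC (channels last — convolutions lower to im2col +
BLAS matmul without layout transposes).  The engine implements exactly the
operations the U-Net / W-Net family needs — 3x3 and 1x1 convolutions, 2x2
stride-2 transposed convolution, batch normalization, 2x2 max pooling,
ReLU / sigmoid / channel softmax, channel concatenation, elementwise addition
and (soft-target) cross-entropy losses — plus an Adam optimizer.  It is
deliberately small: no broadcasting algebra, no graph optimization, no GPU.
"""

from __future__ import annotations

import contextlib
from typing import Iterator

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import expit

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction (inference / evaluation paths)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


class Tensor:
    """An ndarray node in a reverse-mode computation tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents = ()

    @property
    def shape(self):
        return self.data.shape

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen = set()
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                node._backward = None  # release cached activations eagerly

    def item(self) -> float:
        return float(self.data)


def _make(out_data, parents, backward):
    """Build an output node; skip the tape when gradients are off."""
    if _GRAD_ENABLED and any(p.requires_grad for p in parents):
        out = Tensor(out_data, requires_grad=True)
        out._parents = tuple(p for p in parents if p.requires_grad)
        out._backward = backward
        return out
    return Tensor(out_data)


def _accum(t: Tensor, g):
    if not t.requires_grad:
        return
    if t.grad is None:
        t.grad = g.astype(np.float32, copy=True)
    else:
        t.grad += g


# ---------------------------------------------------------------- elementwise

def add(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        _accum(a, g)
        _accum(b, g)
    return _make(a.data + b.data, (a, b), backward)


def relu(x: Tensor) -> Tensor:
    y = np.maximum(x.data, np.float32(0.0))

    def backward(g):
        _accum(x, g * (x.data > 0))
    return _make(y, (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    y = expit(x.data).astype(np.float32)

    def backward(g):
        _accum(x, g * y * (1.0 - y))
    return _make(y, (x,), backward)


def softmax_channels(x: Tensor) -> Tensor:
    z = x.data - x.data.max(axis=-1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=-1, keepdims=True)

    def backward(g):
        dot = (g * p).sum(axis=-1, keepdims=True)
        _accum(x, p * (g - dot))
    return _make(p, (x,), backward)


def concat_channels(a: Tensor, b: Tensor) -> Tensor:
    ca = a.data.shape[-1]

    def backward(g):
        _accum(a, g[..., :ca])
        _accum(b, g[..., ca:])
    return _make(np.concatenate([a.data, b.data], axis=-1), (a, b), backward)


def maxpool2x2(x: Tensor) -> Tensor:
    n, h, w, c = x.data.shape
    if h % 2 or w % 2:
        raise ValueError(f"maxpool2x2 needs even spatial dims, got {h}x{w}")
    win = x.data.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 5, 2, 4)
    win = np.ascontiguousarray(win).reshape(n, h // 2, w // 2, c, 4)
    idx = win.argmax(axis=-1)
    y = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        dwin = np.zeros((n, h // 2, w // 2, c, 4), dtype=np.float32)
        np.put_along_axis(dwin, idx[..., None], g[..., None], axis=-1)
        dx = dwin.reshape(n, h // 2, w // 2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        _accum(x, np.ascontiguousarray(dx).reshape(n, h, w, c))
    return _make(y, (x,), backward)


# -------------------------------------------------------------------- losses

def bce_mean(p: Tensor, target: np.ndarray, weight: np.ndarray | None = None,
             eps: float = 1e-6) -> Tensor:
    """Mean binary cross-entropy of probabilities against (possibly soft) targets.

    `weight` is an optional 0/1 (or float) pixel weight; the mean is taken over
    the weight mass.  Probabilities are clamped to [eps, 1-eps] so the loss is
    always finite.
    """
    y = np.asarray(target, dtype=np.float32)
    if y.shape != p.data.shape:
        raise ValueError(f"target shape {y.shape} != prediction shape {p.data.shape}")
    pc = np.clip(p.data, eps, 1.0 - eps)
    ll = -(y * np.log(pc) + (1.0 - y) * np.log1p(-pc))
    if weight is None:
        denom = float(y.size)
        val = ll.mean()
    else:
        w = np.asarray(weight, dtype=np.float32)
        denom = max(float(w.sum()), 1.0)
        val = float((ll * w).sum() / denom)

    def backward(g):
        d = (pc - y) / (pc * (1.0 - pc)) / denom
        if weight is not None:
            d = d * weight
        _accum(p, g * d)
    return _make(np.float32(val), (p,), backward)


def ce_mean(p: Tensor, target_onehot: np.ndarray, eps: float = 1e-6) -> Tensor:
    """Mean multiclass cross-entropy against one-hot (or soft) channel targets."""
    y = np.asarray(target_onehot, dtype=np.float32)
    pc = np.clip(p.data, eps, 1.0)
    n_pix = p.data.size / p.data.shape[-1]
    val = float(-(y * np.log(pc)).sum() / n_pix)

    def backward(g):
        _accum(p, g * (-y / pc) / n_pix)
    return _make(np.float32(val), (p,), backward)


# ------------------------------------------------------------------- modules

class Module:
    """Tiny module base: tracks parameters and submodules by attribute order."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Tensor):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for name, p in self._params.items():
            yield prefix + name, p
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def parameters(self) -> Iterator[Tensor]:
        for _, p in self.named_parameters():
            yield p

    def train(self, mode: bool = True):
        object.__setattr__(self, "training", mode)
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        if isinstance(self, BatchNorm2d):
            yield prefix + "running_mean", self.running_mean
            yield prefix + "running_var", self.running_var
        for name, m in self._modules.items():
            yield from m.buffers(prefix + name + ".")

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({name: b.copy() for name, b in self.buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]):
        params = dict(self.named_parameters())
        bufs = dict(self.buffers())
        for name, arr in state.items():
            if name in params:
                if params[name].data.shape != arr.shape:
                    raise ValueError(f"shape mismatch for {name}")
                params[name].data = np.asarray(arr, dtype=np.float32).copy()
            elif name in bufs:
                bufs[name][...] = arr
            else:
                raise KeyError(f"unknown state entry {name}")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(Module):
    def __init__(self, modules=()):
        super().__init__()
        self._list = []
        for m in modules:
            self.append(m)

    def append(self, m: Module):
        setattr(self, str(len(self._list)), m)
        self._list.append(m)

    def __iter__(self):
        return iter(self._list)

    def __getitem__(self, i):
        return self._list[i]

    def __len__(self):
        return len(self._list)


def _he_init(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    std = np.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(np.float32)


class Conv2d(Module):
    """kxk same-padding convolution (k in {1, 3}); weight is (Cin*k*k, Cout)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if kernel not in (1, 3):
            raise ValueError("only 1x1 and 3x3 kernels are supported")
        rng = rng or np.random.default_rng()
        self.c_in, self.c_out, self.kernel = c_in, c_out, kernel
        self.weight = Tensor(_he_init(rng, c_in * kernel * kernel,
                                      (c_in * kernel * kernel, c_out)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(c_out, dtype=np.float32), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        n, h, w, c = x.data.shape
        if c != self.c_in:
            raise ValueError(f"expected {self.c_in} input channels, got {c}")
        k = self.kernel
        if k == 1:
            col = x.data.reshape(n * h * w, c)
        else:
            xp = np.pad(x.data, ((0, 0), (1, 1), (1, 1), (0, 0)))
            # window over the spatial axes -> (n, h, w, c, 3, 3); flattening the
            # trailing (c, 3, 3) matches the weight's (Cin*9, Cout) layout
            win = sliding_window_view(xp, (3, 3), axis=(1, 2))
            col = win.reshape(n * h * w, c * 9)  # single gather copy
        out = col @ self.weight.data
        if self.bias is not None:
            out += self.bias.data
        y = out.reshape(n, h, w, self.c_out)
        weight, bias = self.weight, self.bias

        def backward(g):
            gm = g.reshape(n * h * w, self.c_out)
            _accum(weight, col.T @ gm)
            if bias is not None:
                _accum(bias, gm.sum(axis=0))
            if x.requires_grad:
                dcol = gm @ weight.data.T
                if k == 1:
                    dx = dcol.reshape(n, h, w, c)
                else:
                    dcol = dcol.reshape(n, h, w, c, 3, 3)
                    dxp = np.zeros((n, h + 2, w + 2, c), dtype=np.float32)
                    for i in range(3):
                        for j in range(3):
                            dxp[:, i:i + h, j:j + w, :] += dcol[:, :, :, :, i, j]
                    dx = dxp[:, 1:-1, 1:-1, :]
                _accum(x, dx)
        parents = (x, weight) if bias is None else (x, weight, bias)
        return _make(y, parents, backward)


class ConvTranspose2d(Module):
    """2x2 stride-2 transposed convolution (exact 2x upsampling, no overlap)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.c_in, self.c_out = c_in, c_out
        self.weight = Tensor(_he_init(rng, c_in, (c_in, 4 * c_out)), requires_grad=True)
        self.bias = Tensor(np.zeros(c_out, dtype=np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        n, h, w, c = x.data.shape
        col = x.data.reshape(n * h * w, c)
        out = col @ self.weight.data  # (nhw, 4*cout), 4 = (2, 2) offsets
        y = out.reshape(n, h, w, 2, 2, self.c_out).transpose(0, 1, 3, 2, 4, 5)
        y = np.ascontiguousarray(y).reshape(n, 2 * h, 2 * w, self.c_out)
        y += self.bias.data
        weight, bias = self.weight, self.bias

        def backward(g):
            gwin = g.reshape(n, h, 2, w, 2, self.c_out).transpose(0, 1, 3, 2, 4, 5)
            gm = np.ascontiguousarray(gwin).reshape(n * h * w, 4 * self.c_out)
            _accum(weight, col.T @ gm)
            _accum(bias, g.sum(axis=(0, 1, 2)))
            if x.requires_grad:
                _accum(x, (gm @ weight.data.T).reshape(n, h, w, c))
        return _make(y, (x, weight, bias), backward)


class BatchNorm2d(Module):
    def __init__(self, c: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.c, self.eps, self.momentum = c, eps, momentum
        self.gamma = Tensor(np.ones(c, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(c, dtype=np.float32), requires_grad=True)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        gamma, beta = self.gamma, self.beta
        if self.training:
            mu = x.data.mean(axis=(0, 1, 2))
            var = x.data.var(axis=(0, 1, 2))
            self.running_mean += self.momentum * (mu - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mu, var = self.running_mean, self.running_var
        ivar = (1.0 / np.sqrt(var + self.eps)).astype(np.float32)
        xhat = (x.data - mu) * ivar
        y = gamma.data * xhat + beta.data
        training = self.training

        def backward(g):
            _accum(gamma, (g * xhat).sum(axis=(0, 1, 2)))
            _accum(beta, g.sum(axis=(0, 1, 2)))
            if not x.requires_grad:
                return
            if not training:
                _accum(x, g * (gamma.data * ivar))
                return
            m = x.data.size // x.data.shape[-1]
            gx = g * gamma.data
            s1 = gx.sum(axis=(0, 1, 2))
            s2 = (gx * xhat).sum(axis=(0, 1, 2))
            dx = (gx - s1 / m - xhat * (s2 / m)) * ivar
            _accum(x, dx if dx.dtype == np.float32 else dx.astype(np.float32))
        return _make(y.astype(np.float32), (x, gamma, beta), backward)


# ----------------------------------------------------------------- optimizer

class Adam:
    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m += (1.0 - self.b1) * (g - m)
            v += (1.0 - self.b2) * (g * g - v)
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
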