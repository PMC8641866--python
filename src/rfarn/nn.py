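"""Minimal reverse-mode automatic differentiation on numpy arrays.

This module provides the tensor/layer substrate for the segmentation
network: a taped :class:`Tensor`, the differentiable ops the architecture
needs (3x3 and 1x1 convolutions with dilation, 2x2 stride-2 transposed
convolution, 2x2 max pooling, batch normalisation, sigmoid/ReLU/softmax,
broadcasting arithmetic, batched matmul, concatenation, global pooling),
layer classes with seeded He-uniform initialisation, and the Adam
optimiser with L2 weight decay.

Conventions: feature maps are NCHW float arrays; convolutions are
stride 1 with "same" zero padding; gradients accumulate into
``Tensor.grad``. Max-pool ties break toward the first (row-major)
maximum so backward passes are deterministic.
"""

from __future__ import annotations

import json
from typing import Iterable, Sequence

import numpy as np

DTYPE = np.float32


class Tensor:
    """A numpy array plus the tape metadata needed for backprop."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self._parents = tuple(parents)
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self, grad=None):
        """Run reverse-mode accumulation from this tensor."""
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
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self._accumulate(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self):
        self.grad = None

    # Sugar so model code reads naturally.
    def __add__(self, other):
        return add(self, other)

    def __mul__(self, other):
        return mul(self, other)

    def __neg__(self):
        return mul(self, Tensor(np.asarray(-1.0, dtype=self.data.dtype)))

    def __sub__(self, other):
        return add(self, -_as_tensor(other))


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


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
    return grad


# ---------------------------------------------------------------------------
# elementwise / shape ops
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.shape))

    return Tensor(out_data, parents=(a, b), backward=backward)


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.shape))

    return Tensor(out_data, parents=(a, b), backward=backward)


def reshape(x: Tensor, shape) -> Tensor:
    x = _as_tensor(x)
    orig = x.shape
    out = Tensor(x.data.reshape(shape), parents=(x,))
    out._backward = lambda g: x._accumulate(g.reshape(orig))
    return out


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)

    def backward(g):
        start = 0
        for t, s in zip(tensors, sizes):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(start, start + s)
            if t.requires_grad:
                t._accumulate(g[tuple(sl)])
            start += s

    return Tensor(out_data, parents=tuple(tensors), backward=backward)


def relu(x: Tensor) -> Tensor:
    x = _as_tensor(x)
    mask = x.data > 0
    out = Tensor(np.where(mask, x.data, 0), parents=(x,))
    out._backward = lambda g: x._accumulate(g * mask)
    return out


def _stable_sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    e = np.exp(z[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def sigmoid(x: Tensor) -> Tensor:
    x = _as_tensor(x)
    s = _stable_sigmoid(x.data)
    out = Tensor(s, parents=(x,))
    out._backward = lambda g: x._accumulate(g * s * (1.0 - s))
    return out


def log(x: Tensor) -> Tensor:
    x = _as_tensor(x)
    out = Tensor(np.log(x.data), parents=(x,))
    out._backward = lambda g: x._accumulate(g / x.data)
    return out


def clip(x: Tensor, lo: float, hi: float) -> Tensor:
    """Clamp; gradient passes only through the unclipped region."""
    x = _as_tensor(x)
    mask = (x.data >= lo) & (x.data <= hi)
    out = Tensor(np.clip(x.data, lo, hi), parents=(x,))
    out._backward = lambda g: x._accumulate(g * mask)
    return out


def mean(x: Tensor) -> Tensor:
    x = _as_tensor(x)
    n = x.data.size
    out = Tensor(np.asarray(x.data.mean(), dtype=x.data.dtype), parents=(x,))
    out._backward = lambda g: x._accumulate(np.broadcast_to(g / n, x.shape))
    return out


def softmax(x: Tensor, axis: int) -> Tensor:
    x = _as_tensor(x)
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * s).sum(axis=axis, keepdims=True)
        x._accumulate(s * (g - dot))

    return Tensor(s, parents=(x,), backward=backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    """Batched matrix product (last two axes), batch dims must match."""
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = np.matmul(a.data, b.data)

    def backward(g):
        if a.requires_grad:
            a._accumulate(np.matmul(g, np.swapaxes(b.data, -1, -2)))
        if b.requires_grad:
            b._accumulate(np.matmul(np.swapaxes(a.data, -1, -2), g))

    return Tensor(out_data, parents=(a, b), backward=backward)


# ---------------------------------------------------------------------------
# spatial ops (NCHW)
# ---------------------------------------------------------------------------

def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None, dilation: int = 1) -> Tensor:
    """Stride-1 'same' convolution; weight is (O, C, k, k)."""
    x, weight = _as_tensor(x), _as_tensor(weight)
    N, C, H, W = x.shape
    O, _, k, _ = weight.shape
    pad = dilation * (k - 1) // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    cols = np.empty((N, C, k, k, H, W), dtype=x.data.dtype)
    for ky in range(k):
        for kx in range(k):
            cols[:, :, ky, kx] = xp[:, :, ky * dilation:ky * dilation + H,
                                    kx * dilation:kx * dilation + W]
    cols2 = cols.reshape(N, C * k * k, H * W)
    w2 = weight.data.reshape(O, C * k * k)
    out_data = np.matmul(w2, cols2).reshape(N, O, H, W)
    if bias is not None:
        out_data = out_data + bias.data.reshape(1, O, 1, 1)

    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        g2 = g.reshape(N, O, H * W)
        if weight.requires_grad:
            gw = np.matmul(g2, cols2.swapaxes(1, 2)).sum(axis=0)
            weight._accumulate(gw.reshape(weight.shape))
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for ky in range(k):
                for kx in range(k):
                    # (N,O,H,W) x (O,C) -> (N,C,H,W)
                    t = np.tensordot(g, weight.data[:, :, ky, kx], axes=([1], [0]))
                    gxp[:, :, ky * dilation:ky * dilation + H,
                        kx * dilation:kx * dilation + W] += t.transpose(0, 3, 1, 2)
            if pad:
                gxp = gxp[:, :, pad:-pad, pad:-pad]
            x._accumulate(gxp)

    return Tensor(out_data, parents=parents, backward=backward)


def conv_transpose2d(x: Tensor, weight: Tensor, bias: Tensor | None) -> Tensor:
    """2x2 stride-2 transposed convolution; weight is (C_in, O, 2, 2)."""
    x, weight = _as_tensor(x), _as_tensor(weight)
    N, C, H, W = x.shape
    _, O, k, _ = weight.shape
    out_data = np.zeros((N, O, 2 * H, 2 * W), dtype=x.data.dtype)
    for ky in range(2):
        for kx in range(2):
            t = np.tensordot(x.data, weight.data[:, :, ky, kx], axes=([1], [0]))
            out_data[:, :, ky::2, kx::2] = t.transpose(0, 3, 1, 2)
    if bias is not None:
        out_data += bias.data.reshape(1, O, 1, 1)

    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        for ky in range(2):
            for kx in range(2):
                gs = g[:, :, ky::2, kx::2]  # (N,O,H,W)
                if weight.requires_grad:
                    gw = np.tensordot(x.data, gs, axes=([0, 2, 3], [0, 2, 3]))
                    weight.grad = weight.grad if weight.grad is not None else \
                        np.zeros_like(weight.data)
                    weight.grad[:, :, ky, kx] += gw
                if x.requires_grad:
                    t = np.tensordot(gs, weight.data[:, :, ky, kx], axes=([1], [1]))
                    x._accumulate(t.transpose(0, 3, 1, 2))

    return Tensor(out_data, parents=parents, backward=backward)


def max_pool2d(x: Tensor) -> Tensor:
    """2x2 stride-2 max pool; ties resolve to the first window element."""
    x = _as_tensor(x)
    N, C, H, W = x.shape
    h2, w2 = H // 2, W // 2
    xr = x.data.reshape(N, C, h2, 2, w2, 2).transpose(0, 1, 2, 4, 3, 5)
    windows = xr.reshape(N, C, h2, w2, 4)
    idx = windows.argmax(axis=-1)
    out_data = np.take_along_axis(windows, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        gw = np.zeros((N, C, h2, w2, 4), dtype=g.dtype)
        np.put_along_axis(gw, idx[..., None], g[..., None], axis=-1)
        gx = gw.reshape(N, C, h2, w2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(N, C, H, W)
        x._accumulate(gx)

    return Tensor(out_data, parents=(x,), backward=backward)


def global_avg_pool(x: Tensor) -> Tensor:
    """(N,C,H,W) -> (N,C) spatial mean."""
    x = _as_tensor(x)
    N, C, H, W = x.shape
    out = Tensor(x.data.mean(axis=(2, 3)), parents=(x,))
    out._backward = lambda g: x._accumulate(
        np.broadcast_to(g[:, :, None, None] / (H * W), x.shape))
    return out


def global_max_pool(x: Tensor) -> Tensor:
    """(N,C,H,W) -> (N,C) spatial max; first-maximum tie-break."""
    x = _as_tensor(x)
    N, C, H, W = x.shape
    flat = x.data.reshape(N, C, H * W)
    idx = flat.argmax(axis=-1)
    out_data = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        gf = np.zeros_like(flat)
        np.put_along_axis(gf, idx[..., None], g[..., None], axis=-1)
        x._accumulate(gf.reshape(x.shape))

    return Tensor(out_data, parents=(x,), backward=backward)


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class Module:
    """Base class: tracks parameters and submodules by attribute name."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._modules: dict[str, Module] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def register(self, name: str, value: Tensor):
        self._params[name] = value
        object.__setattr__(self, name, value)

    def parameters(self) -> list[Tensor]:
        out = list(self._params.values())
        for m in self._modules.values():
            out.extend(m.parameters())
        return out

    def named_parameters(self, prefix: str = "") -> dict[str, Tensor]:
        out = {prefix + n: p for n, p in self._params.items()}
        for mn, m in self._modules.items():
            out.update(m.named_parameters(prefix + mn + "."))
        return out

    def buffers(self, prefix: str = "") -> dict[str, np.ndarray]:
        out = {}
        if isinstance(self, BatchNorm2d):
            out[prefix + "running_mean"] = self.running_mean
            out[prefix + "running_var"] = self.running_var
        for mn, m in self._modules.items():
            out.update(m.buffers(prefix + mn + "."))
        return out

    def train(self):
        self.training = True
        for m in self._modules.values():
            m.train()
        return self

    def eval(self):
        self.training = False
        for m in self._modules.values():
            m.eval()
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        d = {n: p.data.copy() for n, p in self.named_parameters().items()}
        d.update({n: b.copy() for n, b in self.buffers().items()})
        return d

    def load_state_dict(self, d: dict):
        params = self.named_parameters()
        for n, p in params.items():
            p.data = np.asarray(d[n], dtype=p.data.dtype)
        bufs = self.buffers()
        for n in bufs:
            bufs[n][...] = np.asarray(d[n])


def he_uniform(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    bound = np.sqrt(6.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(DTYPE)


class Conv2d(Module):
    def __init__(self, in_ch, out_ch, kernel, rng, dilation=1, bias=True):
        super().__init__()
        self.dilation = dilation
        fan_in = in_ch * kernel * kernel
        self.register("weight", Tensor(
            he_uniform(rng, (out_ch, in_ch, kernel, kernel), fan_in), requires_grad=True))
        self.bias = None
        if bias:
            self.register("bias", Tensor(np.zeros(out_ch, dtype=DTYPE), requires_grad=True))

    def __call__(self, x):
        return conv2d(x, self.weight, self.bias, dilation=self.dilation)


class ConvTranspose2d(Module):
    """Fixed 2x2 kernel, stride 2 (the only upsampling the network uses)."""

    def __init__(self, in_ch, out_ch, rng, bias=True):
        super().__init__()
        self.register("weight", Tensor(
            he_uniform(rng, (in_ch, out_ch, 2, 2), in_ch * 4), requires_grad=True))
        self.bias = None
        if bias:
            self.register("bias", Tensor(np.zeros(out_ch, dtype=DTYPE), requires_grad=True))

    def __call__(self, x):
        return conv_transpose2d(x, self.weight, self.bias)


class BatchNorm2d(Module):
    def __init__(self, channels, eps=1e-5, momentum=0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.register("gamma", Tensor(np.ones(channels, dtype=DTYPE), requires_grad=True))
        self.register("beta", Tensor(np.zeros(channels, dtype=DTYPE), requires_grad=True))
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)

    def __call__(self, x: Tensor) -> Tensor:
        x = _as_tensor(x)
        N, C, H, W = x.shape
        if self.training:
            mu = x.data.mean(axis=(0, 2, 3))
            var = x.data.var(axis=(0, 2, 3))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu).astype(DTYPE)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(DTYPE)
        else:
            mu, var = self.running_mean, self.running_var
        mu4 = mu.reshape(1, C, 1, 1)
        ivar = 1.0 / np.sqrt(var + self.eps)
        ivar4 = ivar.reshape(1, C, 1, 1)
        xhat = (x.data - mu4) * ivar4
        out_data = self.gamma.data.reshape(1, C, 1, 1) * xhat + \
            self.beta.data.reshape(1, C, 1, 1)
        gamma, beta = self.gamma, self.beta
        training = self.training
        m = N * H * W

        def backward(g):
            if gamma.requires_grad:
                gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
            if beta.requires_grad:
                beta._accumulate(g.sum(axis=(0, 2, 3)))
            if x.requires_grad:
                gxh = g * gamma.data.reshape(1, C, 1, 1)
                if training:
                    # full batch-statistics backward
                    sum_gxh = gxh.sum(axis=(0, 2, 3), keepdims=True)
                    sum_gxh_xhat = (gxh * xhat).sum(axis=(0, 2, 3), keepdims=True)
                    gx = (gxh - sum_gxh / m - xhat * sum_gxh_xhat / m) * ivar4
                else:
                    gx = gxh * ivar4
                x._accumulate(gx)

        return Tensor(out_data, parents=(x, gamma, beta), backward=backward)


class Adam:
    """Adam with additive L2 weight decay (decay folded into the gradient)."""

    def __init__(self, params: Iterable[Tensor], lr=1e-3, betas=(0.9, 0.999),
                 eps=1e-8, weight_decay=0.0):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data, dtype=np.float32) for p in self.params]
        self.v = [np.zeros_like(p.data, dtype=np.float32) for p in self.params]

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1 - b1 ** self.t
        bc2 = 1 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()


def save_checkpoint(path, model: Module, config_dict: dict):
    """Write weights as .npz with a JSON sidecar describing the network."""
    np.savez(path, **model.state_dict())
    sidecar = str(path) + ".json" if not str(path).endswith(".npz") \
        else str(path)[:-4] + ".json"
    with open(sidecar, "w") as fh:
        json.dump(config_dict, fh, indent=2)


def load_checkpoint(path, model: Module):
    with np.load(path) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model
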