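"""Minimal NumPy neural-network layer library with reverse-mode gradients.

Layers cache what their backward pass needs during ``forward`` and release
it after ``backward``.  Shapes follow the (N, C, H, W) convention for image
tensors.  All computation is float64, which keeps finite-difference gradient
checks tight and is fast enough at the tile resolutions this package trains
at.

Every layer with weights draws its initial values from a caller-supplied
``numpy.random.Generator``, so model construction is fully seeded.
"""

from __future__ import annotations

from collections import OrderedDict

import numpy as np

__all__ = [
    "Parameter",
    "Module",
    "Linear",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "MaxPool2d",
    "GlobalAvgPool2d",
    "SqueezeExcite",
    "Sequential",
    "BasicBlock",
    "Adam",
    "sigmoid",
]


def sigmoid(x: np.ndarray) -> np.ndarray:
    """Numerically stable logistic function."""
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Parameter:
    """A weight tensor with an accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)


class Module:
    """Base class: parameter/buffer registration, train/eval mode."""

    def __init__(self) -> None:
        self._params: OrderedDict[str, Parameter] = OrderedDict()
        self._buffers: OrderedDict[str, np.ndarray] = OrderedDict()
        self._children: OrderedDict[str, Module] = OrderedDict()
        self.training = True

    # -- registration -------------------------------------------------------
    def register_parameter(self, name: str, param: Parameter) -> Parameter:
        self._params[name] = param
        return param

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = np.asarray(value, dtype=np.float64)

    def add_child(self, name: str, module: "Module") -> "Module":
        self._children[name] = module
        return module

    # -- traversal ----------------------------------------------------------
    def parameters(self) -> list[Parameter]:
        out = list(self._params.values())
        for child in self._children.values():
            out.extend(child.parameters())
        return out

    def named_parameters(self, prefix: str = "") -> "OrderedDict[str, Parameter]":
        out: OrderedDict[str, Parameter] = OrderedDict()
        for name, p in self._params.items():
            out[prefix + name] = p
        for cname, child in self._children.items():
            out.update(child.named_parameters(prefix + cname + "."))
        return out

    def named_buffers(self, prefix: str = "") -> "OrderedDict[str, np.ndarray]":
        out: OrderedDict[str, np.ndarray] = OrderedDict()
        for name, b in self._buffers.items():
            out[prefix + name] = b
        for cname, child in self._children.items():
            out.update(child.named_buffers(prefix + cname + "."))
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {f"param.{k}": v.value for k, v in self.named_parameters().items()}
        state.update({f"buffer.{k}": v for k, v in self.named_buffers().items()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.named_parameters()
        for key, value in state.items():
            kind, _, name = key.partition(".")
            if kind == "param":
                params[name].value = np.asarray(value, dtype=np.float64)
            elif kind == "buffer":
                self._set_buffer(name, np.asarray(value, dtype=np.float64))
            else:  # pragma: no cover - corrupt checkpoint
                raise KeyError(f"unknown state entry {key!r}")

    def _set_buffer(self, dotted: str, value: np.ndarray) -> None:
        mod: Module = self
        parts = dotted.split(".")
        for part in parts[:-1]:
            mod = mod._children[part]
        mod._buffers[parts[-1]] = value

    def train(self) -> "Module":
        self.training = True
        for c in self._children.values():
            c.train()
        return self

    def eval(self) -> "Module":
        self.training = False
        for c in self._children.values():
            c.eval()
        return self

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        scale = np.sqrt(2.0 / in_features)
        self.W = self.register_parameter(
            "W", Parameter(rng.normal(0.0, scale, size=(out_features, in_features)))
        )
        self.b = self.register_parameter("b", Parameter(np.zeros(out_features))) if bias else None
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        y = x @ self.W.value.T
        if self.b is not None:
            y = y + self.b.value
        return y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.W.grad += grad.T @ self._x
        if self.b is not None:
            self.b.grad += grad.sum(axis=0)
        dx = grad @ self.W.value
        self._x = None
        return dx


def _im2col(x: np.ndarray, k: int, stride: int, pad: int) -> tuple[np.ndarray, tuple]:
    """(N, C, H, W) -> (N*Ho*Wo, C*k*k) patch matrix."""
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    hp, wp = x.shape[2], x.shape[3]
    ho = (hp - k) // stride + 1
    wo = (wp - k) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]  # (N, C, Ho, Wo, k, k)
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * k * k)
    return np.ascontiguousarray(cols), (n, c, hp, wp, ho, wo)


def _col2im(dcols: np.ndarray, shape: tuple, k: int, stride: int, pad: int) -> np.ndarray:
    """Scatter-add patch gradients back to the (padded) input."""
    n, c, hp, wp, ho, wo = shape
    dxp = np.zeros((n, c, hp, wp))
    d = dcols.reshape(n, ho, wo, c, k, k).transpose(0, 3, 4, 5, 1, 2)  # N,C,k,k,Ho,Wo
    for i in range(k):
        for j in range(k):
            dxp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += d[:, :, i, j]
    if pad:
        return dxp[:, :, pad:-pad, pad:-pad]
    return dxp


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, pad: int = 0, bias: bool = False):
        super().__init__()
        fan_in = in_ch * kernel * kernel
        self.W = self.register_parameter(
            "W", Parameter(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_ch, in_ch, kernel, kernel)))
        )
        self.b = self.register_parameter("b", Parameter(np.zeros(out_ch))) if bias else None
        self.kernel, self.stride, self.pad = kernel, stride, pad
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        cols, shape = _im2col(x, self.kernel, self.stride, self.pad)
        n, _, _, _, ho, wo = shape
        out_ch = self.W.value.shape[0]
        y = cols @ self.W.value.reshape(out_ch, -1).T
        if self.b is not None:
            y = y + self.b.value
        self._cache = (cols, shape)
        return y.reshape(n, ho, wo, out_ch).transpose(0, 3, 1, 2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        cols, shape = self._cache
        self._cache = None
        out_ch = self.W.value.shape[0]
        g = grad.transpose(0, 2, 3, 1).reshape(-1, out_ch)
        self.W.grad += (g.T @ cols).reshape(self.W.value.shape)
        if self.b is not None:
            self.b.grad += g.sum(axis=0)
        dcols = g @ self.W.value.reshape(out_ch, -1)
        return _col2im(dcols, shape, self.kernel, self.stride, self.pad)


class BatchNorm2d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = self.register_parameter("gamma", Parameter(np.ones(channels)))
        self.beta = self.register_parameter("beta", Parameter(np.zeros(channels)))
        self.register_buffer("running_mean", np.zeros(channels))
        self.register_buffer("running_var", np.ones(channels))
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.training:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            self._buffers["running_mean"] = (1 - m) * self._buffers["running_mean"] + m * mu
            self._buffers["running_var"] = (1 - m) * self._buffers["running_var"] + m * var
        else:
            mu = self._buffers["running_mean"]
            var = self._buffers["running_var"]
        std = np.sqrt(var + self.eps)
        xhat = (x - mu[None, :, None, None]) / std[None, :, None, None]
        if self.training:
            self._cache = (xhat, std)
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, std = self._cache
        self._cache = None
        axes = (0, 2, 3)
        m = grad.shape[0] * grad.shape[2] * grad.shape[3]
        self.gamma.grad += (grad * xhat).sum(axis=axes)
        self.beta.grad += grad.sum(axis=axes)
        dxhat = grad * self.gamma.value[None, :, None, None]
        s1 = dxhat.sum(axis=axes, keepdims=True)
        s2 = (dxhat * xhat).sum(axis=axes, keepdims=True)
        return (dxhat - s1 / m - xhat * s2 / m) / std[None, :, None, None]


class ReLU(Module):
    def __init__(self) -> None:
        super().__init__()
        self._mask = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = grad * self._mask
        self._mask = None
        return g


class MaxPool2d(Module):
    def __init__(self, kernel: int, stride: int, pad: int = 0):
        super().__init__()
        self.kernel, self.stride, self.pad = kernel, stride, pad
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        k, s, p = self.kernel, self.stride, self.pad
        n, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)), constant_values=-np.inf) if p else x
        hp, wp = xp.shape[2], xp.shape[3]
        ho = (hp - k) // s + 1
        wo = (wp - k) // s + 1
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        flat = win.reshape(n, c, ho, wo, k * k)
        arg = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]
        self._cache = (arg, (n, c, hp, wp, ho, wo))
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        k, s, p = self.kernel, self.stride, self.pad
        arg, (n, c, hp, wp, ho, wo) = self._cache
        self._cache = None
        dxp = np.zeros((n, c, hp, wp))
        di, dj = np.unravel_index(arg, (k, k))
        oy, ox = np.meshgrid(np.arange(ho), np.arange(wo), indexing="ij")
        rows = oy[None, None] * s + di
        colz = ox[None, None] * s + dj
        ni = np.arange(n)[:, None, None, None]
        ci = np.arange(c)[None, :, None, None]
        np.add.at(dxp, (ni, ci, rows, colz), grad)
        if p:
            return dxp[:, :, p:-p, p:-p]
        return dxp


class GlobalAvgPool2d(Module):
    """(N, C, H, W) -> (N, C) mean over the spatial extent."""

    def __init__(self) -> None:
        super().__init__()
        self._hw = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._hw = x.shape[2:]
        return x.mean(axis=(2, 3))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        h, w = self._hw
        self._hw = None
        return np.broadcast_to(grad[:, :, None, None] / (h * w), grad.shape + (h, w)).copy()


class SqueezeExcite(Module):
    """Channel recalibration: sigmoid gates from globally pooled statistics.

    Gates are ``s = sigmoid(W2 @ relu(W1 @ gap(x)))`` with a reduction-ratio
    bottleneck and no biases; the output rescales each input channel by its
    gate.
    """

    def __init__(self, channels: int, rng: np.random.Generator, reduction: int = 16):
        super().__init__()
        hidden = max(1, channels // reduction)
        self.W1 = self.register_parameter(
            "W1", Parameter(rng.normal(0.0, np.sqrt(2.0 / channels), size=(hidden, channels)))
        )
        self.W2 = self.register_parameter(
            "W2", Parameter(rng.normal(0.0, np.sqrt(2.0 / hidden), size=(channels, hidden)))
        )
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        g = x.mean(axis=(2, 3))                       # (N, C)
        a1 = g @ self.W1.value.T                      # (N, hidden)
        r = np.maximum(a1, 0.0)
        a2 = r @ self.W2.value.T                      # (N, C)
        s = sigmoid(a2)
        self._cache = (x, g, a1, r, s)
        return x * s[:, :, None, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x, g, a1, r, s = self._cache
        self._cache = None
        h, w = x.shape[2], x.shape[3]
        dx = grad * s[:, :, None, None]
        ds = (grad * x).sum(axis=(2, 3))
        da2 = ds * s * (1.0 - s)
        self.W2.grad += da2.T @ r
        dr = da2 @ self.W2.value
        da1 = dr * (a1 > 0)
        self.W1.grad += da1.T @ g
        dg = da1 @ self.W1.value
        dx += dg[:, :, None, None] / (h * w)
        return dx


class Sequential(Module):
    def __init__(self, *modules: Module):
        super().__init__()
        for i, m in enumerate(modules):
            self.add_child(str(i), m)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for m in self._children.values():
            x = m(x)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for m in reversed(self._children.values()):
            grad = m.backward(grad)
        return grad


class BasicBlock(Module):
    """Two 3x3 convs with identity (or 1x1-projected) shortcut; optional SE."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator,
                 stride: int = 1, se: bool = False, se_reduction: int = 16):
        super().__init__()
        self.conv1 = self.add_child("conv1", Conv2d(in_ch, out_ch, 3, rng, stride=stride, pad=1))
        self.bn1 = self.add_child("bn1", BatchNorm2d(out_ch))
        self.relu1 = self.add_child("relu1", ReLU())
        self.conv2 = self.add_child("conv2", Conv2d(out_ch, out_ch, 3, rng, stride=1, pad=1))
        self.bn2 = self.add_child("bn2", BatchNorm2d(out_ch))
        self.se = self.add_child("se", SqueezeExcite(out_ch, rng, se_reduction)) if se else None
        if stride != 1 or in_ch != out_ch:
            self.down_conv = self.add_child("down_conv", Conv2d(in_ch, out_ch, 1, rng, stride=stride))
            self.down_bn = self.add_child("down_bn", BatchNorm2d(out_ch))
        else:
            self.down_conv = None
        self._relu_mask = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        out = self.relu1(self.bn1(self.conv1(x)))
        out = self.bn2(self.conv2(out))
        if self.se is not None:
            out = self.se(out)
        shortcut = self.down_bn(self.down_conv(x)) if self.down_conv is not None else x
        out = out + shortcut
        self._relu_mask = out > 0
        return out * self._relu_mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        grad = grad * self._relu_mask
        self._relu_mask = None
        g = grad
        if self.se is not None:
            g = self.se.backward(g)
        g = self.conv1.backward(self.bn1.backward(self.relu1.backward(
            self.conv2.backward(self.bn2.backward(g))
        )))
        if self.down_conv is not None:
            g_short = self.down_conv.backward(self.down_bn.backward(grad))
        else:
            g_short = grad
        return g + g_short


class Adam:
    """Adam with per-group learning rates and L2 weight decay."""

    def __init__(self, groups: list[dict], weight_decay: float = 0.0,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.groups = groups
        self.weight_decay = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = {id(p): np.zeros_like(p.value) for g in groups for p in g["params"]}
        self._v = {id(p): np.zeros_like(p.value) for g in groups for p in g["params"]}

    def zero_grad(self) -> None:
        for g in self.groups:
            for p in g["params"]:
                p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for g in self.groups:
            lr = g["lr"]
            for p in g["params"]:
                grad = p.grad
                if self.weight_decay:
                    grad = grad + self.weight_decay * p.value
                m = self._m[id(p)]
                v = self._v[id(p)]
                m *= self.b1
                m += (1 - self.b1) * grad
                v *= self.b2
                v += (1 - self.b2) * grad * grad
                p.value -= lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
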