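"""Minimal reverse-mode automatic differentiation on NumPy arrays.

This module implements exactly the primitives needed to train and run the
residual encoder and projection head of this package on a CPU: 2-D
convolution (im2col + BLAS), batch normalization, ReLU, max/average pooling,
fully connected layers, row L2 normalization, and a fused normalized-
temperature cross-entropy (InfoNCE) loss, together with an Adam optimizer.

Gradients are accumulated through a tape of :class:`Tensor` nodes and
released eagerly after the backward pass.  All parameters are float32.
"""

from __future__ import annotations

from typing import Callable, Iterable

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "Module",
    "Conv2d",
    "BatchNorm2d",
    "Linear",
    "relu",
    "add",
    "max_pool2d",
    "global_avg_pool",
    "l2_normalize_rows",
    "nt_xent_loss",
    "Adam",
]


class Tensor:
    """A node in the computation graph wrapping a float32 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(
        self,
        data: np.ndarray,
        requires_grad: bool = False,
        parents: tuple["Tensor", ...] = (),
        backward: Callable[[np.ndarray], None] | None = None,
    ) -> None:
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float32)
        else:
            self.grad += g

    def backward(self) -> None:
        """Reverse-topological backward pass from this (scalar) node."""
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
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            if node._parents:
                node.grad = None  # free intermediate gradients
                node._backward = None
                node._parents = ()


class Parameter(Tensor):
    def __init__(self, data: np.ndarray) -> None:
        super().__init__(data, requires_grad=True)


class Module:
    """Base class holding parameters, buffers and a train/eval switch."""

    def __init__(self) -> None:
        self._params: dict[str, Parameter] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self._modules: dict[str, "Module"] = {}
        self.training = True

    def __setattr__(self, name: str, value) -> None:
        if isinstance(value, Parameter):
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def parameters(self) -> list[Parameter]:
        out = list(self._params.values())
        for m in self._modules.values():
            out.extend(m.parameters())
        return out

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def state_dict(self, prefix: str = "") -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for k, p in self._params.items():
            out[prefix + k] = p.data
        for k in self._buffers:
            out[prefix + k] = getattr(self, k)
        for k, m in self._modules.items():
            out.update(m.state_dict(prefix + k + "."))
        return out

    def load_state_dict(self, state: dict[str, np.ndarray], prefix: str = "") -> None:
        for k, p in self._params.items():
            p.data = np.asarray(state[prefix + k], dtype=np.float32)
        for k in list(self._buffers):
            val = np.asarray(state[prefix + k])
            self._buffers[k] = val
            object.__setattr__(self, k, val)
        for k, m in self._modules.items():
            m.load_state_dict(state, prefix + k + ".")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


# ---------------------------------------------------------------------------
# Functional ops
# ---------------------------------------------------------------------------

def _im2col(xp: np.ndarray, kh: int, kw: int, stride: int) -> np.ndarray:
    view = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    view = view[:, :, ::stride, ::stride]
    n, c, ho, wo = view.shape[:4]
    return view.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * kh * kw), (n, ho, wo)


def conv2d(x: Tensor, weight: Parameter, bias: Parameter | None, stride: int, padding: int) -> Tensor:
    cout, cin, kh, kw = weight.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    cols, (n, ho, wo) = _im2col(xp, kh, kw, stride)
    w2 = weight.data.reshape(cout, -1)
    out_mat = cols @ w2.T
    if bias is not None:
        out_mat += bias.data
    out = out_mat.reshape(n, ho, wo, cout).transpose(0, 3, 1, 2)

    def backward(g: np.ndarray) -> None:
        g_mat = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(-1, cout)
        weight.accumulate((g_mat.T @ cols).reshape(weight.shape))
        if bias is not None:
            bias.accumulate(g_mat.sum(axis=0))
        dcols = g_mat @ w2
        dview = dcols.reshape(n, ho, wo, cin, kh, kw).transpose(0, 3, 1, 2, 4, 5)
        dxp = np.zeros_like(xp)
        for i in range(kh):
            for j in range(kw):
                dxp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += dview[..., i, j]
        if padding:
            dxp = dxp[:, :, padding:-padding, padding:-padding]
        x.accumulate(dxp)

    return Tensor(out, parents=(x,), backward=backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out = x.data * mask

    def backward(g: np.ndarray) -> None:
        x.accumulate(g * mask)

    return Tensor(out, parents=(x,), backward=backward)


def add(a: Tensor, b: Tensor) -> Tensor:
    out = a.data + b.data

    def backward(g: np.ndarray) -> None:
        a.accumulate(g)
        b.accumulate(g)

    return Tensor(out, parents=(a, b), backward=backward)


def max_pool2d(x: Tensor, kernel: int = 3, stride: int = 2, padding: int = 1) -> Tensor:
    n, c, h, w = x.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)), constant_values=-np.inf)
    view = np.lib.stride_tricks.sliding_window_view(xp, (kernel, kernel), axis=(2, 3))
    view = view[:, :, ::stride, ::stride]
    ho, wo = view.shape[2], view.shape[3]
    flat = view.reshape(n, c, ho, wo, kernel * kernel)
    idx = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def backward(g: np.ndarray) -> None:
        hi = (np.arange(ho) * stride)[None, None, :, None] + idx // kernel
        wi = (np.arange(wo) * stride)[None, None, None, :] + idx % kernel
        dxp = np.zeros((n, c, h + 2 * padding, w + 2 * padding), dtype=np.float32)
        ni = np.arange(n)[:, None, None, None]
        ci = np.arange(c)[None, :, None, None]
        np.add.at(dxp, (ni, ci, hi, wi), g)
        if padding:
            dxp = dxp[:, :, padding:-padding, padding:-padding]
        x.accumulate(dxp)

    return Tensor(out, parents=(x,), backward=backward)


def global_avg_pool(x: Tensor) -> Tensor:
    n, c, h, w = x.shape
    out = x.data.mean(axis=(2, 3))

    def backward(g: np.ndarray) -> None:
        x.accumulate(np.broadcast_to(g[:, :, None, None] / (h * w), x.shape))

    return Tensor(out, parents=(x,), backward=backward)


def linear(x: Tensor, weight: Parameter, bias: Parameter | None) -> Tensor:
    out = x.data @ weight.data.T
    if bias is not None:
        out += bias.data

    def backward(g: np.ndarray) -> None:
        weight.accumulate(g.T @ x.data)
        if bias is not None:
            bias.accumulate(g.sum(axis=0))
        x.accumulate(g @ weight.data)

    return Tensor(out, parents=(x,), backward=backward)


def l2_normalize_rows(x: Tensor, eps: float = 1e-12) -> Tensor:
    norm = np.sqrt((x.data**2).sum(axis=1, keepdims=True))
    if np.any(norm < eps):
        raise ValueError("cannot normalize a zero-norm projection")
    out = x.data / norm

    def backward(g: np.ndarray) -> None:
        dot = (g * out).sum(axis=1, keepdims=True)
        x.accumulate((g - out * dot) / norm)

    return Tensor(out, parents=(x,), backward=backward)


def nt_xent_loss(z: Tensor, pair_index: np.ndarray, tau: float) -> Tensor:
    """Normalized-temperature cross entropy over a batch of 2N projections.

    ``z`` holds 2N unit-norm projection vectors; ``pair_index[i]`` is the
    index of the positive partner of sample ``i`` (an involution without
    fixed points).  Each sample's loss contrasts its positive against all
    other 2N-2 batch members under temperature-scaled cosine similarity; the
    total is the mean over all 2N directed terms, which equals the
    symmetrized per-pair average.  With a single pair (N = 1) there are no
    negatives and the loss is exactly zero.
    """
    if tau <= 0:
        raise ValueError("temperature must be positive")
    m = z.shape[0]
    pair_index = np.asarray(pair_index)
    if pair_index.shape != (m,) or np.any(pair_index == np.arange(m)):
        raise ValueError("pair_index must map each sample to a distinct partner")
    sim = (z.data @ z.data.T) / tau
    np.fill_diagonal(sim, -np.inf)
    smax = sim.max(axis=1, keepdims=True)
    exp = np.exp(sim - smax)
    denom = exp.sum(axis=1, keepdims=True)
    logprob = sim - smax - np.log(denom)
    losses = -logprob[np.arange(m), pair_index]
    out = np.array(losses.mean(), dtype=np.float32)

    def backward(g: np.ndarray) -> None:
        soft = exp / denom
        soft[np.arange(m), pair_index] -= 1.0
        gs = soft * (float(g) / m)
        dz = (gs + gs.T) @ z.data / tau
        z.accumulate(dz)

    return Tensor(out, parents=(z,), backward=backward)


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------

class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel: int, stride: int = 1, padding: int = 0, bias: bool = False, rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng()
        fan_in = in_channels * kernel * kernel
        std = np.sqrt(2.0 / fan_in)
        self.weight = Parameter(rng.normal(0.0, std, size=(out_channels, in_channels, kernel, kernel)))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None
        self.stride = stride
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.stride, self.padding)


class BatchNorm2d(Module):
    """Per-channel batch normalization with running statistics for eval."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1) -> None:
        super().__init__()
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.eps = eps
        self.momentum = momentum
        self.register_buffer("running_mean", np.zeros(channels, dtype=np.float32))
        self.register_buffer("running_var", np.ones(channels, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        gamma, beta = self.gamma, self.beta
        if self.training:
            mean = x.data.mean(axis=(0, 2, 3))
            var = x.data.var(axis=(0, 2, 3))
            rm = self._buffers["running_mean"]
            rv = self._buffers["running_var"]
            rm += self.momentum * (mean - rm)
            rv += self.momentum * (var - rv)
        else:
            mean = self._buffers["running_mean"]
            var = self._buffers["running_var"]
        std = np.sqrt(var + self.eps)
        xhat = (x.data - mean[None, :, None, None]) / std[None, :, None, None]
        out = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]
        training = self.training

        def backward(g: np.ndarray) -> None:
            gamma.accumulate((g * xhat).sum(axis=(0, 2, 3)))
            beta.accumulate(g.sum(axis=(0, 2, 3)))
            gx = g * gamma.data[None, :, None, None]
            if training:
                mcount = g.shape[0] * g.shape[2] * g.shape[3]
                xc = x.data - mean[None, :, None, None]
                dvar = (gx * xc).sum(axis=(0, 2, 3)) * -0.5 * (var + self.eps) ** -1.5
                dmean = -(gx.sum(axis=(0, 2, 3)) / std) + dvar * (-2.0 / mcount) * xc.sum(axis=(0, 2, 3))
                dx = (
                    gx / std[None, :, None, None]
                    + (2.0 / mcount) * dvar[None, :, None, None] * xc
                    + dmean[None, :, None, None] / mcount
                )
                x.accumulate(dx)
            else:
                x.accumulate(gx / std[None, :, None, None])

        return Tensor(out, parents=(x,), backward=backward)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True, rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng()
        bound = np.sqrt(1.0 / in_features)
        self.weight = Parameter(rng.uniform(-bound, bound, size=(out_features, in_features)))
        self.bias = Parameter(rng.uniform(-bound, bound, size=out_features)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return linear(x, self.weight, self.bias)


class Adam:
    """Adam with decoupled-from-nothing classic L2 weight decay into the gradient."""

    def __init__(
        self,
        params: Iterable[Parameter],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ) -> None:
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
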