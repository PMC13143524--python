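"""Layers with explicit forward/backward on channels-last float32 arrays.

Conventions
-----------
* Spatial tensors are NHWC, vector tensors are NC.
* ``forward(x, training)`` caches whatever ``backward`` needs; a backward
  call must follow the forward call it corresponds to.
* ``backward(dy)`` accumulates into each ``Parameter.grad`` and returns
  the gradient with respect to the layer input.
* All parameters are trainable; batch-norm running statistics are buffers,
  not parameters, and are excluded from parameter counts.
"""

from __future__ import annotations

import math
from typing import Callable, Iterator

import numpy as np

F32 = np.float32


class Parameter:
    __slots__ = ("name", "data", "grad")

    def __init__(self, name: str, data: np.ndarray):
        self.name = name
        self.data = np.asarray(data, dtype=F32)
        self.grad = np.zeros_like(self.data)

    @property
    def size(self) -> int:
        return self.data.size

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Parameter({self.name}, shape={self.data.shape})"


class Module:
    """Base class: parameter/submodule discovery via attribute scan."""

    #: set True to capture this module's output and output-gradient
    #: (used by Grad-CAM); see ``captured_output`` / ``captured_grad``.
    capture: bool = False
    captured_output: np.ndarray | None = None
    captured_grad: np.ndarray | None = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def __call__(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        y = self.forward(x, training=training)
        if self.capture:
            self.captured_output = y
        return y

    def _backprop(self, dy: np.ndarray) -> np.ndarray:
        if self.capture:
            self.captured_grad = dy
        return self.backward(dy)

    def modules(self) -> Iterator["Module"]:
        yield self
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def parameters(self) -> list[Parameter]:
        seen: set[int] = set()
        out: list[Parameter] = []
        for m in self.modules():
            for v in m.__dict__.values():
                if isinstance(v, Parameter) and id(v) not in seen:
                    seen.add(id(v))
                    out.append(v)
        return out

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def set_rng(self, rng: np.random.Generator) -> None:
        """Give every stochastic submodule (dropout) this random stream."""
        for m in self.modules():
            if isinstance(m, Dropout):
                m.rng = rng

    # -- (de)serialization -------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for i, p in enumerate(self.parameters()):
            state[f"p{i}:{p.name}"] = p.data
        for j, (m, name, buf) in enumerate(self._buffers()):
            state[f"b{j}:{name}"] = buf
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        bufs = self._buffers()
        for key, value in state.items():
            kind, idx = key[0], int(key[1:].split(":", 1)[0])
            if kind == "p":
                if params[idx].data.shape != value.shape:
                    raise ValueError(f"shape mismatch for {key}")
                params[idx].data = np.asarray(value, dtype=F32)
                params[idx].grad = np.zeros_like(params[idx].data)
            else:
                m, name, _ = bufs[idx]
                setattr(m, name, np.asarray(value, dtype=F32))

    def _buffers(self) -> list[tuple["Module", str, np.ndarray]]:
        out = []
        for m in self.modules():
            if isinstance(m, BatchNorm):
                out.append((m, "running_mean", m.running_mean))
                out.append((m, "running_var", m.running_var))
        return out


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer(x, training=training)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer._backprop(dy)
        return dy


class Identity(Module):
    def forward(self, x, training=False):
        return x

    def backward(self, dy):
        return dy


class Flatten(Module):
    def forward(self, x, training=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


# ---------------------------------------------------------------------------
# initializers
# ---------------------------------------------------------------------------

_INIT_RNG = np.random.default_rng(0)


def set_init_rng(rng: np.random.Generator) -> None:
    """Set the stream used by subsequently constructed layers' init."""
    global _INIT_RNG
    _INIT_RNG = rng


def _kaiming_fanout(shape: tuple[int, ...], fan_out: int) -> np.ndarray:
    std = math.sqrt(2.0 / fan_out)
    return _INIT_RNG.normal(0.0, std, size=shape)


def _xavier_uniform(shape: tuple[int, int]) -> np.ndarray:
    limit = math.sqrt(6.0 / (shape[0] + shape[1]))
    return _INIT_RNG.uniform(-limit, limit, size=shape)


# ---------------------------------------------------------------------------
# convolutions
# ---------------------------------------------------------------------------

class Conv2d(Module):
    """2-D convolution, NHWC, weight layout (k, k, C_in/groups, C_out).

    Three execution paths: 1x1 (a single matmul), depthwise
    (groups == C_in == C_out, shift-accumulate), and general (im2col).
    Only ``groups in {1, C_in}`` is supported — that is all the
    architectures here use.
    """

    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: int,
        stride: int = 1,
        padding: int | None = None,
        groups: int = 1,
        bias: bool = False,
        name: str = "conv",
    ):
        if groups not in (1, c_in):
            raise ValueError("only groups=1 or depthwise groups=C_in supported")
        if groups == c_in and c_out != c_in:
            raise ValueError("depthwise convolution requires c_out == c_in")
        self.c_in, self.c_out, self.k = c_in, c_out, kernel
        self.stride = stride
        self.padding = kernel // 2 if padding is None else padding
        self.depthwise = groups == c_in and c_in > 1
        if self.depthwise:
            wshape = (kernel, kernel, c_in)
            fan_out = kernel * kernel
        else:
            wshape = (kernel, kernel, c_in, c_out)
            fan_out = kernel * kernel * c_out
        self.weight = Parameter(f"{name}.weight", _kaiming_fanout(wshape, fan_out))
        self.bias = Parameter(f"{name}.bias", np.zeros(c_out)) if bias else None

    def _out_hw(self, h: int, w: int) -> tuple[int, int]:
        k, s, p = self.k, self.stride, self.padding
        return (h + 2 * p - k) // s + 1, (w + 2 * p - k) // s + 1

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=F32)
        n, h, w, _ = x.shape
        ho, wo = self._out_hw(h, w)
        k, s, p = self.k, self.stride, self.padding

        if self.k == 1 and not self.depthwise:
            xs = x[:, ::s, ::s, :] if s > 1 else x
            self._cache = (xs, x.shape)
            y = xs @ self.weight.data.reshape(self.c_in, self.c_out)
        elif self.depthwise:
            xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
            self._cache = xp
            y = np.zeros((n, ho, wo, self.c_out), dtype=F32)
            for di in range(k):
                for dj in range(k):
                    patch = xp[:, di : di + ho * s : s, dj : dj + wo * s : s, :]
                    y += patch * self.weight.data[di, dj]
        else:
            xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
            win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
            win = win[:, ::s, ::s]  # (n, ho, wo, c, k, k)
            col = np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3)).reshape(
                n * ho * wo, k * k * self.c_in
            )
            self._cache = (col, x.shape)
            y = (col @ self.weight.data.reshape(-1, self.c_out)).reshape(
                n, ho, wo, self.c_out
            )
        if self.bias is not None:
            y = y + self.bias.data
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dy = np.ascontiguousarray(dy, dtype=F32)
        n, ho, wo, _ = dy.shape
        k, s, p = self.k, self.stride, self.padding
        if self.bias is not None:
            self.bias.grad += dy.sum(axis=(0, 1, 2))

        if self.k == 1 and not self.depthwise:
            xs, xshape = self._cache
            w2 = self.weight.data.reshape(self.c_in, self.c_out)
            self.weight.grad += (
                xs.reshape(-1, self.c_in).T @ dy.reshape(-1, self.c_out)
            ).reshape(self.weight.data.shape)
            dxs = dy @ w2.T
            if s == 1:
                return dxs.astype(F32)
            dx = np.zeros(xshape, dtype=F32)  # skipped input pixels get zero grad
            dx[:, ::s, ::s, :] = dxs
            return dx
        if self.depthwise:
            xp = self._cache
            dxp = np.zeros_like(xp)
            for di in range(k):
                for dj in range(k):
                    patch = xp[:, di : di + ho * s : s, dj : dj + wo * s : s, :]
                    self.weight.grad[di, dj] += (patch * dy).sum(axis=(0, 1, 2))
                    dxp[:, di : di + ho * s : s, dj : dj + wo * s : s, :] += (
                        dy * self.weight.data[di, dj]
                    )
            return dxp[:, p : xp.shape[1] - p, p : xp.shape[2] - p, :]

        col, xshape = self._cache
        dyf = dy.reshape(-1, self.c_out)
        self.weight.grad += (col.T @ dyf).reshape(self.weight.data.shape)
        dcol = (dyf @ self.weight.data.reshape(-1, self.c_out).T).reshape(
            n, ho, wo, k, k, self.c_in
        )
        hp, wp = xshape[1] + 2 * p, xshape[2] + 2 * p
        dxp = np.zeros((n, hp, wp, self.c_in), dtype=F32)
        for di in range(k):
            for dj in range(k):
                dxp[:, di : di + ho * s : s, dj : dj + wo * s : s, :] += dcol[
                    :, :, :, di, dj, :
                ]
        return dxp[:, p : p + xshape[1], p : p + xshape[2], :]


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

class BatchNorm(Module):
    """Batch normalization over all axes except the last (channels).

    Works for NHWC feature maps and NC vectors alike.  Training mode uses
    batch statistics and updates running buffers; eval mode uses the
    running buffers (and its backward differentiates that affine map).
    """

    def __init__(self, c: int, eps: float = 1e-5, momentum: float = 0.1, name: str = "bn"):
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(f"{name}.weight", np.ones(c))
        self.beta = Parameter(f"{name}.bias", np.zeros(c))
        self.running_mean = np.zeros(c, dtype=F32)
        self.running_var = np.ones(c, dtype=F32)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=F32)
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            cnt = x.size // x.shape[-1]
            unbias = cnt / max(cnt - 1, 1)
            self.running_mean = ((1 - m) * self.running_mean + m * mean).astype(F32)
            self.running_var = ((1 - m) * self.running_var + m * var * unbias).astype(F32)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        self._cache = (xhat, inv.astype(F32), training)
        return (self.gamma.data * xhat + self.beta.data).astype(F32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv, training = self._cache
        axes = tuple(range(dy.ndim - 1))
        self.gamma.grad += (dy * xhat).sum(axis=axes)
        self.beta.grad += dy.sum(axis=axes)
        if not training:
            return dy * (self.gamma.data * inv)
        m = dy.size // dy.shape[-1]
        dxhat = dy * self.gamma.data
        return (
            inv / m * (m * dxhat - dxhat.sum(axis=axes) - xhat * (dxhat * xhat).sum(axis=axes))
        ).astype(F32)


class LayerNorm(Module):
    """Layer normalization over the last axis (transformer blocks)."""

    def __init__(self, c: int, eps: float = 1e-6, name: str = "ln"):
        self.eps = eps
        self.gamma = Parameter(f"{name}.weight", np.ones(c))
        self.beta = Parameter(f"{name}.bias", np.zeros(c))

    def forward(self, x, training=False):
        x = np.asarray(x, dtype=F32)
        mean = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        self._cache = (xhat, inv)
        return self.gamma.data * xhat + self.beta.data

    def backward(self, dy):
        xhat, inv = self._cache
        c = dy.shape[-1]
        axes = tuple(range(dy.ndim - 1))
        self.gamma.grad += (dy * xhat).sum(axis=axes)
        self.beta.grad += dy.sum(axis=axes)
        dxhat = dy * self.gamma.data
        return (
            inv / c * (c * dxhat - dxhat.sum(-1, keepdims=True) - xhat * (dxhat * xhat).sum(-1, keepdims=True))
        ).astype(F32)


# ---------------------------------------------------------------------------
# activations
# ---------------------------------------------------------------------------

class ReLU(Module):
    def forward(self, x, training=False):
        self._mask = x > 0
        return np.where(self._mask, x, 0).astype(F32)

    def backward(self, dy):
        return np.where(self._mask, dy, 0).astype(F32)


class Sigmoid(Module):
    def forward(self, x, training=False):
        y = 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=F32)))
        self._y = y
        return y.astype(F32)

    def backward(self, dy):
        return (dy * self._y * (1.0 - self._y)).astype(F32)


class SiLU(Module):
    """x * sigmoid(x)."""

    def forward(self, x, training=False):
        s = 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=F32)))
        self._cache = (x, s)
        return (x * s).astype(F32)

    def backward(self, dy):
        x, s = self._cache
        return (dy * (s * (1.0 + x * (1.0 - s)))).astype(F32)


class Hardswish(Module):
    """x * relu6(x + 3) / 6."""

    def forward(self, x, training=False):
        self._x = np.asarray(x, dtype=F32)
        return (self._x * np.clip(self._x + 3.0, 0.0, 6.0) / 6.0).astype(F32)

    def backward(self, dy):
        x = self._x
        d = np.where(x <= -3.0, 0.0, np.where(x >= 3.0, 1.0, (2.0 * x + 3.0) / 6.0))
        return (dy * d).astype(F32)


class Hardsigmoid(Module):
    """relu6(x + 3) / 6."""

    def forward(self, x, training=False):
        self._x = np.asarray(x, dtype=F32)
        return (np.clip(self._x + 3.0, 0.0, 6.0) / 6.0).astype(F32)

    def backward(self, dy):
        d = ((self._x > -3.0) & (self._x < 3.0)).astype(F32) / 6.0
        return (dy * d).astype(F32)


class gelu(Module):
    """Exact Gaussian-error linear unit (transformer MLPs)."""

    def forward(self, x, training=False):
        from scipy.special import erf

        x = np.asarray(x, dtype=F32)
        phi = 0.5 * (1.0 + erf(x / math.sqrt(2.0)))
        self._cache = (x, phi)
        return (x * phi).astype(F32)

    def backward(self, dy):
        x, phi = self._cache
        pdf = np.exp(-0.5 * x * x) / math.sqrt(2.0 * math.pi)
        return (dy * (phi + x * pdf)).astype(F32)


# ---------------------------------------------------------------------------
# dense / dropout / pooling
# ---------------------------------------------------------------------------

class Linear(Module):
    def __init__(self, c_in: int, c_out: int, bias: bool = True, name: str = "linear",
                 init: str = "normal"):
        if init == "normal":
            w = _INIT_RNG.normal(0.0, 0.01, size=(c_in, c_out))
        elif init == "xavier":
            w = _xavier_uniform((c_in, c_out))
        else:
            raise ValueError(f"unknown init {init!r}")
        self.weight = Parameter(f"{name}.weight", w)
        self.bias = Parameter(f"{name}.bias", np.zeros(c_out)) if bias else None

    def forward(self, x, training=False):
        self._x = np.asarray(x, dtype=F32)
        y = self._x @ self.weight.data
        if self.bias is not None:
            y = y + self.bias.data
        return y.astype(F32)

    def backward(self, dy):
        dy = np.asarray(dy, dtype=F32)
        xf = self._x.reshape(-1, self._x.shape[-1])
        dyf = dy.reshape(-1, dy.shape[-1])
        self.weight.grad += xf.T @ dyf
        if self.bias is not None:
            self.bias.grad += dyf.sum(axis=0)
        return (dy @ self.weight.data.T).astype(F32)


class Dropout(Module):
    """Inverted dropout; identity in eval mode.  Draws from ``self.rng``
    (set via ``Module.set_rng`` for reproducible runs)."""

    def __init__(self, p: float):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.p = p
        self.rng: np.random.Generator = np.random.default_rng(0)

    def forward(self, x, training=False):
        if not training or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p).astype(F32) / (1.0 - self.p)
        return (x * self._mask).astype(F32)

    def backward(self, dy):
        if self._mask is None:
            return dy
        return (dy * self._mask).astype(F32)


class GlobalAvgPool(Module):
    """NHWC -> NC spatial mean."""

    def forward(self, x, training=False):
        self._shape = x.shape
        return x.mean(axis=(1, 2)).astype(F32)

    def backward(self, dy):
        n, h, w, c = self._shape
        return (np.broadcast_to(dy[:, None, None, :], self._shape) / (h * w)).astype(F32)


class SEUnit(Module):
    """Squeeze-and-excitation channel gate for NHWC maps.

    Pool -> fc1 -> activation -> fc2 -> gate -> scale input.  Parameter
    shapes match the 1x1-convolution formulation (weights + biases).
    """

    def __init__(self, c: int, squeeze: int, gate: str = "hardsigmoid",
                 act: str = "relu", name: str = "se"):
        self.fc1 = Linear(c, squeeze, name=f"{name}.fc1")
        self.fc2 = Linear(squeeze, c, name=f"{name}.fc2")
        self.act: Module = SiLU() if act == "silu" else ReLU()
        self.gate: Module = Sigmoid() if gate == "sigmoid" else Hardsigmoid()

    def forward(self, x, training=False):
        n, h, w, c = x.shape
        z = x.mean(axis=(1, 2))
        g = self.gate(self.fc2(self.act(self.fc1(z, training), training), training), training)
        self._cache = (x, g)
        return (x * g[:, None, None, :]).astype(F32)

    def backward(self, dy):
        x, g = self._cache
        n, h, w, c = x.shape
        dx = dy * g[:, None, None, :]
        dg = (dy * x).sum(axis=(1, 2))
        dz = self.fc1.backward(self.act.backward(self.fc2.backward(self.gate.backward(dg))))
        dx += np.broadcast_to(dz[:, None, None, :], x.shape) / (h * w)
        return dx.astype(F32)


class Residual(Module):
    """y = x + body(x)."""

    def __init__(self, body: Module):
        self.body = body

    def forward(self, x, training=False):
        return (x + self.body(x, training=training)).astype(F32)

    def backward(self, dy):
        return (dy + self.body._backprop(dy)).astype(F32)
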