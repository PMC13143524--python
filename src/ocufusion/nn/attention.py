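"""Scaled dot-product self-attention with explicit backward.

``TokenSelfAttention`` implements Attention(Q, K, V) =
softmax(Q K^T / sqrt(d_k)) V with learnable projections Q = F W_q + b_q,
K = F W_k + b_k, V = F W_v + b_v over a (batch, tokens, dim) array
(biases on by default, matching the conventional linear-projection
parameterization; pass ``bias=False`` to drop them).

The fusion model's default uses a *single token* — the whole 3,072-d
concatenated feature vector.  With one token the softmax is over a 1x1
score matrix and equals exactly 1, so the output reduces analytically to
the value projection F W_v; the general code path realizes this identity
bitwise, and no gradient reaches W_q or W_k in that mode.  This is a
documented property of the architecture as described, not an
approximation.
"""

from __future__ import annotations

import math

import numpy as np

from .layers import F32, Module, Parameter, _xavier_uniform


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Numerically stable softmax."""
    z = x - np.max(x, axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


class TokenSelfAttention(Module):
    """Single-head self-attention over (N, T, D) token arrays.

    ``d_k`` defaults to the projection width D (the scaling the
    architecture prescribes).
    """

    def __init__(self, dim: int, d_k: int | None = None, bias: bool = True,
                 name: str = "attn"):
        self.dim = dim
        self.d_k = dim if d_k is None else d_k
        self.w_q = Parameter(f"{name}.w_q", _xavier_uniform((dim, dim)))
        self.w_k = Parameter(f"{name}.w_k", _xavier_uniform((dim, dim)))
        self.w_v = Parameter(f"{name}.w_v", _xavier_uniform((dim, dim)))
        if bias:
            self.b_q = Parameter(f"{name}.b_q", np.zeros(dim))
            self.b_k = Parameter(f"{name}.b_k", np.zeros(dim))
            self.b_v = Parameter(f"{name}.b_v", np.zeros(dim))
        else:
            self.b_q = self.b_k = self.b_v = None

    def _proj(self, xf: np.ndarray, w: Parameter, b: Parameter | None) -> np.ndarray:
        y = xf @ w.data
        return y if b is None else y + b.data

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=F32)
        squeeze = x.ndim == 2
        if squeeze:  # single-token mode: (N, D) -> (N, 1, D)
            x = x[:, None, :]
        n, t, d = x.shape
        # project via one 2-D matmul so the single-token output is
        # bitwise identical to the plain value projection F W_v + b_v
        xf = x.reshape(n * t, d)
        v = self._proj(xf, self.w_v, self.b_v).reshape(n, t, d)
        if t == 1:
            # the 1x1 softmax is identically 1 whatever the scores are,
            # so Q/K need not be materialized: output == value projection
            q = k = None
            a = np.ones((n, 1, 1), dtype=F32)
            y = v
        else:
            q = self._proj(xf, self.w_q, self.b_q).reshape(n, t, d)
            k = self._proj(xf, self.w_k, self.b_k).reshape(n, t, d)
            scores = q @ k.transpose(0, 2, 1) / math.sqrt(self.d_k)
            a = softmax(scores, axis=-1).astype(F32)
            y = a @ v
        self._cache = (x, q, k, v, a, squeeze)
        return (y[:, 0, :] if squeeze else y).astype(F32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, q, k, v, a, squeeze = self._cache
        dy = np.asarray(dy, dtype=F32)
        if squeeze:
            dy = dy[:, None, :]
        dv = a.transpose(0, 2, 1) @ dy
        xf = x.reshape(-1, self.dim)
        dvf = dv.reshape(-1, self.dim)
        self.w_v.grad += xf.T @ dvf
        if self.b_v is not None:
            self.b_v.grad += dvf.sum(axis=0)
        dx = dv @ self.w_v.data.T
        if x.shape[1] > 1:
            # with a single token the softmax is constant, so the score
            # gradient — and with it dW_q / dW_k — is identically zero
            da = dy @ v.transpose(0, 2, 1)
            ds = a * (da - (da * a).sum(axis=-1, keepdims=True))
            ds = ds / math.sqrt(self.d_k)
            dq = ds @ k
            dk = ds.transpose(0, 2, 1) @ q
            for w, b, dz in ((self.w_q, self.b_q, dq), (self.w_k, self.b_k, dk)):
                dzf = dz.reshape(-1, self.dim)
                w.grad += xf.T @ dzf
                if b is not None:
                    b.grad += dzf.sum(axis=0)
            dx = dx + dq @ self.w_q.data.T + dk @ self.w_k.data.T
        return (dx[:, 0, :] if squeeze else dx).astype(F32)


class MultiHeadSelfAttention(Module):
    """Standard multi-head attention for the transformer baseline.

    Fused QKV projection and output projection, both with bias (the
    conventional encoder parameterization).
    """

    def __init__(self, dim: int, heads: int, name: str = "mha"):
        if dim % heads:
            raise ValueError("dim must be divisible by heads")
        self.dim, self.heads, self.d_h = dim, heads, dim // heads
        self.w_qkv = Parameter(f"{name}.w_qkv", _xavier_uniform((dim, 3 * dim)))
        self.b_qkv = Parameter(f"{name}.b_qkv", np.zeros(3 * dim))
        self.w_o = Parameter(f"{name}.w_o", _xavier_uniform((dim, dim)))
        self.b_o = Parameter(f"{name}.b_o", np.zeros(dim))

    def _split(self, z: np.ndarray) -> np.ndarray:
        n, t, _ = z.shape
        return z.reshape(n, t, self.heads, self.d_h).transpose(0, 2, 1, 3)

    def forward(self, x, training=False):
        x = np.asarray(x, dtype=F32)
        n, t, d = x.shape
        qkv = x @ self.w_qkv.data + self.b_qkv.data
        q, k, v = (self._split(z) for z in np.split(qkv, 3, axis=-1))
        scores = q @ k.transpose(0, 1, 3, 2) / math.sqrt(self.d_h)
        a = softmax(scores, axis=-1).astype(F32)
        ctx = (a @ v).transpose(0, 2, 1, 3).reshape(n, t, d)
        y = ctx @ self.w_o.data + self.b_o.data
        self._cache = (x, q, k, v, a, ctx)
        return y.astype(F32)

    def backward(self, dy):
        x, q, k, v, a, ctx = self._cache
        n, t, d = x.shape
        dy = np.asarray(dy, dtype=F32)
        self.w_o.grad += ctx.reshape(-1, d).T @ dy.reshape(-1, d)
        self.b_o.grad += dy.reshape(-1, d).sum(axis=0)
        dctx = (dy @ self.w_o.data.T).reshape(n, t, self.heads, self.d_h).transpose(0, 2, 1, 3)
        dv = a.transpose(0, 1, 3, 2) @ dctx
        da = dctx @ v.transpose(0, 1, 3, 2)
        ds = a * (da - (da * a).sum(axis=-1, keepdims=True)) / math.sqrt(self.d_h)
        dq = ds @ k
        dk = ds.transpose(0, 1, 3, 2) @ q
        dqkv = np.concatenate(
            [z.transpose(0, 2, 1, 3).reshape(n, t, d) for z in (dq, dk, dv)], axis=-1
        )
        self.w_qkv.grad += x.reshape(-1, d).T @ dqkv.reshape(-1, 3 * d)
        self.b_qkv.grad += dqkv.reshape(-1, 3 * d).sum(axis=0)
        return (dqkv @ self.w_qkv.data.T).astype(F32)
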