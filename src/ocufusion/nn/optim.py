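"""Optimizers."""

from __future__ import annotations

import numpy as np

from .layers import F32, Parameter

try:  # fused single-pass update; NumPy fallback below is equivalent
    import numba

    @numba.njit(cache=True, fastmath=False)
    def _adam_kernel(p, g, m, v, b1, b2, alpha, epsp):  # pragma: no cover
        for i in range(p.size):
            gi = g[i]
            m[i] = b1 * m[i] + (1.0 - b1) * gi
            v[i] = b2 * v[i] + (1.0 - b2) * gi * gi
            p[i] -= alpha * m[i] / (np.sqrt(v[i]) + epsp)

except ImportError:  # pragma: no cover
    _adam_kernel = None


class Adam:
    """Adam with the conventional defaults: betas (0.9, 0.999), eps 1e-8,
    no weight decay, no schedule.

    ``step`` reuses the gradient buffers as scratch space, so gradients
    are invalid after a step; call ``zero_grad`` before the next backward
    pass (the training loop always does).
    """

    def __init__(
        self,
        params: list[Parameter],
        lr: float = 1e-4,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        # standard reformulation: p -= alpha * m / (sqrt(v) + eps')
        alpha = F32(self.lr * np.sqrt(b2t) / b1t)
        epsp = F32(self.eps * np.sqrt(b2t))
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            if _adam_kernel is not None:
                _adam_kernel(p.data.reshape(-1), g.reshape(-1),
                             m.reshape(-1), v.reshape(-1),
                             F32(self.b1), F32(self.b2), alpha, epsp)
                continue
            m *= self.b1
            m += F32(1.0 - self.b1) * g
            v *= self.b2
            np.multiply(g, g, out=g)  # grad buffer reused as scratch
            g *= F32(1.0 - self.b2)
            v += g
            denom = np.sqrt(v)
            denom += epsp
            np.divide(m, denom, out=denom)
            denom *= alpha
            p.data -= denom

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0
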