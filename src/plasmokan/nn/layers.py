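"""Minimal neural-network layers with explicit backward passes (pure numpy).

Every layer caches what its backward pass needs during ``forward`` and
accumulates parameter gradients in ``backward``; correctness of each backward
pass is pinned by finite-difference gradient checks in the test suite.
"""

from __future__ import annotations

import numpy as np

from .splines import bspline_basis, make_knots, n_basis


class Parameter:
    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.asarray(value, dtype=float)
        self.grad = np.zeros_like(self.value)
        self.name = name


class Module:
    """Base class: parameter discovery via attribute inspection."""

    def parameters(self) -> list[Parameter]:
        out: list[Parameter] = []
        for attr in vars(self).values():
            if isinstance(attr, Parameter):
                out.append(attr)
            elif isinstance(attr, Module):
                out.extend(attr.parameters())
            elif isinstance(attr, (list, tuple)):
                for item in attr:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
                    elif isinstance(item, Parameter):
                        out.append(item)
        return out

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    @property
    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.parameters()))

    def state_arrays(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("state does not match model parameter list")
        for p, a in zip(params, arrays):
            if p.value.shape != a.shape:
                raise ValueError(f"shape mismatch {p.value.shape} vs {a.shape}")
            p.value[...] = a


def _silu(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    s = 1.0 / (1.0 + np.exp(-x))
    return x * s, s * (1.0 + x * (1.0 - s))


class Linear(Module):
    """Affine map on the last axis; accepts (..., in) inputs."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        self.in_dim, self.out_dim = in_dim, out_dim
        scale = 1.0 / np.sqrt(in_dim)
        self.W = Parameter(rng.normal(0.0, scale, size=(in_dim, out_dim)), "W")
        self.b = Parameter(np.zeros(out_dim), "b")
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, gy: np.ndarray) -> np.ndarray:
        x = self._x
        xf = x.reshape(-1, self.in_dim)
        gf = gy.reshape(-1, self.out_dim)
        self.W.grad += xf.T @ gf
        self.b.grad += gf.sum(axis=0)
        return gy @ self.W.value.T


class ReLU(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return gy * self._mask


class KANLayer(Module):
    """Kolmogorov-Arnold layer: every edge carries a learnable univariate function.

    Edge function = B-spline combination (clamped to ``x_range``) plus a
    weighted SiLU base activation; node outputs are sums over incoming edges:
    ``y_q = sum_p [ spline_qp(x_p) + w_qp * silu(x_p) ]``.
    """

    def __init__(
        self,
        in_dim: int,
        out_dim: int,
        rng: np.random.Generator,
        grid_size: int = 5,
        order: int = 3,
        x_range: tuple[float, float] = (-3.0, 3.0),
        coef_scale: float = 0.1,
    ):
        self.in_dim, self.out_dim = in_dim, out_dim
        self.grid_size, self.order, self.x_range = grid_size, order, x_range
        self.knots = make_knots(grid_size, order, x_range)
        nb = n_basis(grid_size, order)
        self.coef = Parameter(rng.normal(0.0, coef_scale, size=(out_dim, in_dim, nb)), "coef")
        # zero-mean, fan-in-scaled base weights keep wide-layer outputs from
        # accumulating a large SiLU bias that would saturate downstream layers
        self.base_w = Parameter(
            rng.normal(0.0, 1.0 / np.sqrt(in_dim), size=(out_dim, in_dim)), "base_w"
        )

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.ndim != 2 or x.shape[1] != self.in_dim:
            raise ValueError(f"expected (batch, {self.in_dim}) input, got {x.shape}")
        if not np.all(np.isfinite(x)):
            raise ValueError("non-finite input to KAN layer")
        B, dB = bspline_basis(x, self.knots, self.order, with_deriv=True)
        silu, dsilu = _silu(x)
        self._cache = (B, dB, silu, dsilu)
        return np.einsum("bim,oim->bo", B, self.coef.value) + silu @ self.base_w.value.T

    def backward(self, gy: np.ndarray) -> np.ndarray:
        B, dB, silu, dsilu = self._cache
        self.coef.grad += np.einsum("bo,bim->oim", gy, B)
        self.base_w.grad += gy.T @ silu
        gx = np.einsum("bo,oim,bim->bi", gy, self.coef.value, dB)
        gx += (gy @ self.base_w.value) * dsilu
        return gx


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.dim, self.eps = dim, eps
        self.gamma = Parameter(np.ones(dim), "gamma")
        self.beta = Parameter(np.zeros(dim), "beta")

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mu) / self._std
        return self.gamma.value * self._xhat + self.beta.value

    def backward(self, gy: np.ndarray) -> np.ndarray:
        xhat, std = self._xhat, self._std
        axes = tuple(range(gy.ndim - 1))
        self.gamma.grad += (gy * xhat).sum(axis=axes)
        self.beta.grad += gy.sum(axis=axes)
        g = gy * self.gamma.value
        gm = g.mean(axis=-1, keepdims=True)
        gxm = (g * xhat).mean(axis=-1, keepdims=True)
        return (g - gm - xhat * gxm) / std


def _softmax(x: np.ndarray) -> np.ndarray:
    z = x - x.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class MultiHeadSelfAttention(Module):
    """Standard scaled dot-product self-attention over a patch sequence.

    Per-head attention weight matrices from the latest forward pass are kept in
    ``last_attention`` (shape ``(batch, heads, P, P)``) for interpretability.
    """

    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator):
        if d_model % n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        self.d_model, self.n_heads = d_model, n_heads
        self.d_head = d_model // n_heads
        self.wq = Linear(d_model, d_model, rng)
        self.wk = Linear(d_model, d_model, rng)
        self.wv = Linear(d_model, d_model, rng)
        self.wo = Linear(d_model, d_model, rng)
        self.last_attention: np.ndarray | None = None

    def _split(self, x: np.ndarray) -> np.ndarray:
        b, p, _ = x.shape
        return x.reshape(b, p, self.n_heads, self.d_head).transpose(0, 2, 1, 3)

    def _merge(self, x: np.ndarray) -> np.ndarray:
        b, h, p, dh = x.shape
        return x.transpose(0, 2, 1, 3).reshape(b, p, h * dh)

    def forward(self, x: np.ndarray) -> np.ndarray:
        q = self._split(self.wq.forward(x))
        k = self._split(self.wk.forward(x))
        v = self._split(self.wv.forward(x))
        scale = 1.0 / np.sqrt(self.d_head)
        scores = np.einsum("bhpd,bhqd->bhpq", q, k) * scale
        A = _softmax(scores)
        ctx = np.einsum("bhpq,bhqd->bhpd", A, v)
        self.last_attention = A
        self._cache = (q, k, v, A, scale)
        return self.wo.forward(self._merge(ctx))

    def backward(self, gy: np.ndarray) -> np.ndarray:
        q, k, v, A, scale = self._cache
        g_ctx = self._split(self.wo.backward(gy))
        dA = np.einsum("bhpd,bhqd->bhpq", g_ctx, v)
        dv = np.einsum("bhpq,bhpd->bhqd", A, g_ctx)
        dS = A * (dA - (dA * A).sum(axis=-1, keepdims=True))
        dq = np.einsum("bhpq,bhqd->bhpd", dS, k) * scale
        dk = np.einsum("bhpq,bhpd->bhqd", dS, q) * scale
        gx = self.wq.backward(self._merge(dq))
        gx += self.wk.backward(self._merge(dk))
        gx += self.wv.backward(self._merge(dv))
        return gx


class AttentionBlock(Module):
    """Pre-norm residual attention block: ``y = x + MHSA(LN(x))``."""

    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator):
        self.ln = LayerNorm(d_model)
        self.attn = MultiHeadSelfAttention(d_model, n_heads, rng)

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x + self.attn.forward(self.ln.forward(x))

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return gy + self.ln.backward(self.attn.backward(gy))
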