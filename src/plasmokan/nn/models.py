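"""Classifier architectures: feature-table KAN, MLP reference, full-spectrum KAN.

All models map their input to a single logit; probabilities are obtained with
a sigmoid.  The full-spectrum model is the deep pathway: linear patch
embedding, additive sinusoidal positional encoding, a stack of residual
self-attention blocks exposing per-head attention maps, mean pooling, and a
KAN head.
"""

from __future__ import annotations

import json

import numpy as np

from .encoding import positional_encoding
from .layers import AttentionBlock, KANLayer, LayerNorm, Linear, Module, ReLU

SPLINE_DEFAULTS = dict(grid_size=5, order=3, x_range=(-3.0, 3.0))


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class FeatureKAN(Module):
    """Stack of KAN layers over a readout feature vector -> logit."""

    def __init__(
        self,
        in_dim: int,
        hidden: tuple[int, ...] = (16, 8),
        seed: int = 0,
        **spline_kwargs,
    ):
        self.config = {
            "type": "feature_kan",
            "in_dim": in_dim,
            "hidden": tuple(hidden),
            "seed": seed,
            **spline_kwargs,
        }
        rng = np.random.default_rng(seed)
        kw = {**SPLINE_DEFAULTS, **spline_kwargs}
        widths = [in_dim, *hidden, 1]
        self.layers = [
            KANLayer(a, b, rng, **kw) for a, b in zip(widths, widths[1:])
        ]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x[:, 0]

    def backward(self, glogit: np.ndarray) -> np.ndarray:
        g = glogit[:, None]
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g


class MLPReference(Module):
    """Plain ReLU multilayer perceptron used as the comparison architecture."""

    def __init__(self, in_dim: int, hidden: tuple[int, ...] = (64, 32), seed: int = 0):
        self.config = {"type": "mlp", "in_dim": in_dim, "hidden": tuple(hidden), "seed": seed}
        rng = np.random.default_rng(seed)
        widths = [in_dim, *hidden, 1]
        self.layers = []
        for idx, (a, b) in enumerate(zip(widths, widths[1:])):
            self.layers.append(Linear(a, b, rng))
            if idx < len(widths) - 2:
                self.layers.append(ReLU())

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x[:, 0]

    def backward(self, glogit: np.ndarray) -> np.ndarray:
        g = glogit[:, None]
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g


class FullSpectrumKAN(Module):
    """Patch embedding + positional encoding + attention stack + KAN head."""

    def __init__(
        self,
        patch_dim: int,
        d_model: int = 64,
        n_layers: int = 2,
        n_heads: int = 4,
        head_hidden: tuple[int, ...] = (16,),
        seed: int = 0,
        **spline_kwargs,
    ):
        if n_layers < 2 or n_heads < 2:
            raise ValueError("the attention stack needs at least 2 layers and 2 heads")
        self.config = {
            "type": "full_spectrum_kan",
            "patch_dim": patch_dim,
            "d_model": d_model,
            "n_layers": n_layers,
            "n_heads": n_heads,
            "head_hidden": tuple(head_hidden),
            "seed": seed,
            **spline_kwargs,
        }
        rng = np.random.default_rng(seed)
        kw = {**SPLINE_DEFAULTS, **spline_kwargs}
        self.embed = Linear(patch_dim, d_model, rng)
        self.blocks = [AttentionBlock(d_model, n_heads, rng) for _ in range(n_layers)]
        self.final_ln = LayerNorm(d_model)
        widths = [d_model, *head_hidden, 1]
        self.head = [KANLayer(a, b, rng, **kw) for a, b in zip(widths, widths[1:])]
        self.d_model = d_model
        self._pe_cache: dict[int, np.ndarray] = {}

    def _pe(self, n_patches: int) -> np.ndarray:
        if n_patches not in self._pe_cache:
            self._pe_cache[n_patches] = positional_encoding(n_patches, self.d_model)
        return self._pe_cache[n_patches]

    def forward(self, X: np.ndarray) -> np.ndarray:
        if X.ndim != 3:
            raise ValueError(f"expected (batch, patches, patch_dim) input, got {X.shape}")
        x = self.embed.forward(X) + self._pe(X.shape[1])
        for blk in self.blocks:
            x = blk.forward(x)
        x = self.final_ln.forward(x)
        self._n_patches = x.shape[1]
        h = x.mean(axis=1)
        for layer in self.head:
            h = layer.forward(h)
        return h[:, 0]

    def backward(self, glogit: np.ndarray) -> np.ndarray:
        g = glogit[:, None]
        for layer in reversed(self.head):
            g = layer.backward(g)
        g = np.repeat(g[:, None, :], self._n_patches, axis=1) / self._n_patches
        g = self.final_ln.backward(g)
        for blk in reversed(self.blocks):
            g = blk.backward(g)
        return self.embed.backward(g)

    def attention_maps(self, X: np.ndarray) -> np.ndarray:
        """Per-layer, per-head attention weights averaged over records: (L, H, P, P)."""
        self.forward(X)
        return np.stack([blk.attn.last_attention.mean(axis=0) for blk in self.blocks])


def build_feature_model(in_dim: int, hidden: tuple[int, ...] = (16, 8), seed: int = 0, **kw) -> FeatureKAN:
    return FeatureKAN(in_dim, hidden, seed, **kw)


def build_mlp_reference(in_dim: int, hidden: tuple[int, ...] = (64, 32), seed: int = 0) -> MLPReference:
    return MLPReference(in_dim, hidden, seed)


def build_full_spectrum_model(
    patch_length: int = 16,
    d_model: int = 64,
    n_layers: int = 2,
    n_heads: int = 4,
    head_hidden: tuple[int, ...] = (16,),
    seed: int = 0,
    **kw,
) -> FullSpectrumKAN:
    """Model over pre/post patch pairs (patch vector = 2 * patch_length samples)."""
    return FullSpectrumKAN(2 * patch_length, d_model, n_layers, n_heads, head_hidden, seed, **kw)


_BUILDERS = {
    "feature_kan": FeatureKAN,
    "mlp": MLPReference,
    "full_spectrum_kan": FullSpectrumKAN,
}


def model_from_config(config: dict) -> Module:
    cfg = dict(config)
    kind = cfg.pop("type")
    for key in ("hidden", "head_hidden", "x_range"):
        if key in cfg and isinstance(cfg[key], list):
            cfg[key] = tuple(cfg[key])
    return _BUILDERS[kind](**cfg)


def save_model(model: Module, path: str) -> None:
    """Single-file parameter archive plus a JSON sidecar with the full config."""
    arrays = model.state_arrays()
    np.savez(path, **{f"p{i}": a for i, a in enumerate(arrays)})
    with open(str(path) + ".json", "w") as fh:
        json.dump(model.config, fh, indent=2, default=list)


def load_model(path: str) -> Module:
    with open(str(path) + ".json") as fh:
        config = json.load(fh)
    model = model_from_config(config)
    with np.load(path if str(path).endswith(".npz") else str(path) + ".npz") as data:
        arrays = [data[f"p{i}"] for i in range(len(data.files))]
    model.load_state_arrays(arrays)
    return model
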