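"""Convolutional Block Attention Module (CBAM).

CBAM refines a feature map in two sequential stages.  Channel attention
squeezes the map by global average- and max-pooling, passes both
descriptors through one shared two-layer MLP (bottleneck of
``channels // reduction_ratio`` units, ReLU in between), sums the two
outputs and applies a sigmoid, yielding one weight per channel.  Spatial
attention then stacks the channel-wise mean and max maps of the
channel-reweighted features and convolves them with a single
``spatial_kernel``-sided filter followed by a sigmoid, yielding one weight
per pixel.  The module output is ``x * channel_weights * spatial_map``,
channel stage first.

Two surfaces are provided: pure-numpy functional ops on a single
``(H, W, C)`` feature map (:func:`channel_attention`,
:func:`spatial_attention`, :func:`apply_cbam`) driven by an explicit
:class:`CBAMWeights`, and :func:`append_cbam` which inserts the identical
computation into an autodiff model graph for end-to-end training.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import ModelBuilder
from .nn.core import variance_scaling
from .nn.layers import (ChannelAvgMax, Conv2D, Dense, ExpandSpatial,
                        GlobalAvgPool2D, GlobalMaxPool2D, Multiply, ReLU,
                        Add, Sigmoid)


@dataclass(frozen=True)
class CBAMConfig:
    reduction_ratio: int = 16
    spatial_kernel: int = 7
    mlp_bias: bool = True

    def __post_init__(self):
        if self.reduction_ratio < 1:
            raise ValueError("reduction_ratio must be a positive integer")
        if self.spatial_kernel < 1 or self.spatial_kernel % 2 == 0:
            raise ValueError("spatial_kernel must be an odd positive integer")

    def hidden_units(self, channels: int) -> int:
        if self.reduction_ratio > channels:
            raise ValueError(
                f"reduction_ratio {self.reduction_ratio} exceeds channel count {channels}")
        return max(channels // self.reduction_ratio, 1)

    def param_count(self, channels: int) -> int:
        h = self.hidden_units(channels)
        mlp = channels * h + h * channels
        if self.mlp_bias:
            mlp += h + channels
        spatial = self.spatial_kernel ** 2 * 2 + 1
        return mlp + spatial


@dataclass
class CBAMWeights:
    """Explicit weights for the functional single-sample ops."""

    w1: np.ndarray  # (C, hidden) shared MLP squeeze
    b1: np.ndarray | None
    w2: np.ndarray  # (hidden, C) shared MLP excite
    b2: np.ndarray | None
    spatial_kernel: np.ndarray  # (k, k, 2)
    spatial_bias: float

    @classmethod
    def initialize(cls, channels: int, cfg: CBAMConfig, rng=None) -> "CBAMWeights":
        rng = rng or np.random.default_rng(0)
        h = cfg.hidden_units(channels)
        k = cfg.spatial_kernel
        return cls(
            w1=variance_scaling(rng, (channels, h), channels, scale=1.0),
            b1=np.zeros(h, dtype=np.float32) if cfg.mlp_bias else None,
            w2=variance_scaling(rng, (h, channels), h, scale=1.0),
            b2=np.zeros(channels, dtype=np.float32) if cfg.mlp_bias else None,
            spatial_kernel=variance_scaling(rng, (k, k, 2), k * k * 2, scale=1.0),
            spatial_bias=0.0,
        )


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _check_feature_map(f: np.ndarray) -> np.ndarray:
    f = np.asarray(f, dtype=float)
    if f.ndim != 3 or min(f.shape) < 1:
        raise ValueError("feature map must be a rank-3 (H, W, C) array")
    return f


def _mlp(v: np.ndarray, w: CBAMWeights) -> np.ndarray:
    h = v @ w.w1
    if w.b1 is not None:
        h = h + w.b1
    h = np.maximum(h, 0)
    o = h @ w.w2
    if w.b2 is not None:
        o = o + w.b2
    return o


def channel_attention(f: np.ndarray, weights: CBAMWeights,
                      cfg: CBAMConfig | None = None) -> np.ndarray:
    """Per-channel attention weights in (0, 1) for one (H, W, C) map."""
    f = _check_feature_map(f)
    if cfg is not None:
        cfg.hidden_units(f.shape[-1])  # validates ratio vs channels
    avg = f.mean(axis=(0, 1))
    mx = f.max(axis=(0, 1))
    return _sigmoid(_mlp(avg, weights) + _mlp(mx, weights))


def spatial_attention(f: np.ndarray, weights: CBAMWeights,
                      cfg: CBAMConfig | None = None) -> np.ndarray:
    """Per-pixel attention map in (0, 1), same (H, W) as the input."""
    f = _check_feature_map(f)
    k = weights.spatial_kernel.shape[0]
    stack = np.stack([f.mean(axis=-1), f.max(axis=-1)], axis=-1)  # (H, W, 2)
    pad = k // 2
    sp = np.pad(stack, ((pad, pad), (pad, pad), (0, 0)))
    h, w = f.shape[:2]
    logit = np.empty((h, w))
    for i in range(h):
        for j in range(w):
            logit[i, j] = (sp[i : i + k, j : j + k, :] * weights.spatial_kernel).sum()
    return _sigmoid(logit + weights.spatial_bias)


def apply_cbam(f: np.ndarray, weights: CBAMWeights,
               cfg: CBAMConfig | None = None) -> np.ndarray:
    """Channel-then-spatial refinement; output shape equals input shape."""
    f = _check_feature_map(f)
    ca = channel_attention(f, weights, cfg)
    f_ca = f * ca  # broadcast over space
    sa = spatial_attention(f_ca, weights, cfg)
    return f_ca * sa[..., None]


def append_cbam(builder: ModelBuilder, source: str, channels: int,
                cfg: CBAMConfig, rng, prefix: str = "cbam") -> str:
    """Insert CBAM nodes after ``source`` in a model graph; returns the
    output node name.  The two pooled descriptors share one MLP instance so
    gradients accumulate into the shared weights."""
    hidden = cfg.hidden_units(channels)
    d1 = Dense(channels, hidden, use_bias=cfg.mlp_bias, rng=rng, name=f"{prefix}/mlp1")
    d2 = Dense(hidden, channels, use_bias=cfg.mlp_bias, rng=rng, name=f"{prefix}/mlp2")
    relu_shared = ReLU()
    b = builder
    b.add(f"{prefix}_gap", GlobalAvgPool2D(), source)
    b.add(f"{prefix}_gap_h", d1)
    b.add(f"{prefix}_gap_hr", relu_shared)
    b.add(f"{prefix}_gap_o", d2)
    b.add(f"{prefix}_gmp", GlobalMaxPool2D(), source)
    b.add(f"{prefix}_gmp_h", d1)
    b.add(f"{prefix}_gmp_hr", relu_shared)
    b.add(f"{prefix}_gmp_o", d2)
    b.add(f"{prefix}_ca_logits", Add(), (f"{prefix}_gap_o", f"{prefix}_gmp_o"))
    b.add(f"{prefix}_ca", Sigmoid())
    b.add(f"{prefix}_ca_b", ExpandSpatial())
    b.add(f"{prefix}_ca_out", Multiply(), (source, f"{prefix}_ca_b"))
    b.add(f"{prefix}_sa_stack", ChannelAvgMax(), f"{prefix}_ca_out")
    b.add(f"{prefix}_sa_conv", Conv2D(2, 1, cfg.spatial_kernel, 1, "same",
                                      regularized=False, rng=rng,
                                      name=f"{prefix}/spatial"))
    b.add(f"{prefix}_sa", Sigmoid())
    return b.add(f"{prefix}_out", Multiply(), (f"{prefix}_ca_out", f"{prefix}_sa"))
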