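"""Segmentation generator: a 4-level encoder/decoder with per-level side
outputs, softmax attention fusion across levels, and an optional
inverted-residual input stem with channel attention.

The final probability map is ``sigmoid(sum_k w_k * A_k * U_k)`` where
``U_k`` is the upsampled single-channel projection of decoder level ``k``
and ``A_k`` the softmax-normalized attention map; a plain U-Net head is
available as an ablation toggle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from . import nn
from .errors import ShapeError
from .nn import Tensor
from .nn import functional as F

__all__ = ["GeneratorConfig", "SideOutputs", "Prediction", "HedUNetGenerator",
           "InvertedResidual", "build_generator"]


@dataclass(frozen=True)
class GeneratorConfig:
    in_channels: int = 3
    base_widths: tuple[int, int, int, int] = (32, 64, 128, 256)
    expansion_factor: int = 4
    use_inverted_residual: bool = True
    fusion: Literal["attention", "last"] = "attention"  # "last" = plain U-Net
    levels: int = 4

    def __post_init__(self):
        if self.levels != 4:
            raise ValueError("the architecture is fixed at 4 levels")
        if self.in_channels not in (1, 3):
            raise ValueError(f"in_channels must be 1 or 3, got {self.in_channels}")
        if len(self.base_widths) != 4:
            raise ValueError("base_widths must have 4 entries")


@dataclass
class SideOutputs:
    """Per-level maps of one forward pass (all autodiff tensors)."""

    native: list[Tensor]       # s_k logits at decoder resolution
    upsampled: list[Tensor]    # F_k at input resolution
    attention: list[Tensor]    # F'_k, sums to 1 across levels at every pixel
    fusion_weights: Tensor     # trainable omega_k, shape (4,)


@dataclass
class Prediction:
    mask_prob: Tensor          # sigmoid of the fused logit, in [0, 1]
    side: SideOutputs | None = None
    extras: dict = field(default_factory=dict)


class DoubleConv(nn.Module):
    def __init__(self, cin, cout, rng):
        super().__init__()
        self.block = nn.Sequential(
            nn.Conv2d(cin, cout, 3, padding=1, rng=rng),
            nn.BatchNorm2d(cout), nn.ReLU(),
            nn.Conv2d(cout, cout, 3, padding=1, rng=rng),
            nn.BatchNorm2d(cout), nn.ReLU(),
        )

    def forward(self, x):
        return self.block(x)


class InvertedResidual(nn.Module):
    """Expand -> depthwise conv -> channel-attention gate -> project, with a
    residual skip (the output keeps the input channel count)."""

    def __init__(self, channels: int, expansion: int, rng):
        super().__init__()
        mid = channels * expansion
        self.expand = nn.Conv2d(channels, mid, 1, rng=rng)
        self.bn1 = nn.BatchNorm2d(mid)
        self.depthwise = nn.Conv2d(mid, mid, 3, padding=1, groups=mid, rng=rng)
        self.bn2 = nn.BatchNorm2d(mid)
        hidden = max(mid // 4, 2)
        self.fc1 = nn.Linear(mid, hidden, rng=rng)
        self.fc2 = nn.Linear(hidden, mid, rng=rng)
        self.project = nn.Conv2d(mid, channels, 1, rng=rng)
        self.bn3 = nn.BatchNorm2d(channels)

    def forward(self, x: Tensor) -> Tensor:
        h = self.bn1(self.expand(x)).relu()
        h = self.bn2(self.depthwise(h)).relu()
        # squeeze-excitation style gate from the global average descriptor
        desc = F.global_avg_pool(h)                      # (N, mid)
        gates = self.fc2(self.fc1(desc).relu()).sigmoid()
        n, c = gates.shape
        h = h * gates.reshape(n, c, 1, 1)
        out = self.bn3(self.project(h))
        return out + x


class HedUNetGenerator(nn.Module):
    def __init__(self, config: GeneratorConfig,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.config = config
        w1, w2, w3, w4 = config.base_widths
        cin = config.in_channels

        if config.use_inverted_residual:
            self.stem = nn.Sequential(
                InvertedResidual(cin, config.expansion_factor, rng),
                InvertedResidual(cin, config.expansion_factor, rng))
        else:
            self.stem = nn.Identity()

        self.enc1 = DoubleConv(cin, w1, rng)
        self.enc2 = DoubleConv(w1, w2, rng)
        self.enc3 = DoubleConv(w2, w3, rng)
        self.enc4 = DoubleConv(w3, w4, rng)
        self.dec3 = DoubleConv(w4 + w3, w3, rng)
        self.dec2 = DoubleConv(w3 + w2, w2, rng)
        self.dec1 = DoubleConv(w2 + w1, w1, rng)

        # per-level 1x1 projections: p_k for side maps, q_k for attention
        self.p1 = nn.Conv2d(w1, 1, 1, rng=rng)
        self.p2 = nn.Conv2d(w2, 1, 1, rng=rng)
        self.p3 = nn.Conv2d(w3, 1, 1, rng=rng)
        self.p4 = nn.Conv2d(w4, 1, 1, rng=rng)
        self.q1 = nn.Conv2d(w1, 1, 1, rng=rng)
        self.q2 = nn.Conv2d(w2, 1, 1, rng=rng)
        self.q3 = nn.Conv2d(w3, 1, 1, rng=rng)
        self.q4 = nn.Conv2d(w4, 1, 1, rng=rng)
        self.head = nn.Conv2d(w1, 1, 1, rng=rng)  # plain U-Net output
        self.fusion_weights = nn.Parameter(np.ones(4))

    # -- pieces exposed for testing ---------------------------------------
    def side_project(self, d_k: Tensor, level: int,
                     out_size: tuple[int, int]) -> tuple[Tensor, Tensor]:
        """1x1-project decoder features to a logit map and upsample it."""
        p = getattr(self, f"p{level}")
        s_k = p(d_k)
        return s_k, F.upsample_bilinear(s_k, out_size)

    def forward(self, x: Tensor | np.ndarray) -> Prediction:
        x = nn.as_tensor(x)
        if x.ndim != 4:
            raise ShapeError(f"expected (N, C, H, W), got shape {x.shape}")
        n, c, h, w = x.shape
        if c != self.config.in_channels:
            raise ShapeError(
                f"input has {c} channels, model expects {self.config.in_channels}")
        if h % 8 or w % 8:
            raise ShapeError(f"spatial size {h}x{w} must be divisible by 8")

        x = self.stem(x)
        e1 = self.enc1(x)
        e2 = self.enc2(F.max_pool2d(e1))
        e3 = self.enc3(F.max_pool2d(e2))
        e4 = self.enc4(F.max_pool2d(e3))

        d4 = e4
        d3 = self.dec3(Tensor.concat(
            [F.upsample_bilinear(d4, (h // 4, w // 4)), e3], axis=1))
        d2 = self.dec2(Tensor.concat(
            [F.upsample_bilinear(d3, (h // 2, w // 2)), e2], axis=1))
        d1 = self.dec1(Tensor.concat(
            [F.upsample_bilinear(d2, (h, w)), e1], axis=1))
        decoder = [d1, d2, d3, d4]

        native, upsampled, attn_logits = [], [], []
        for k, d_k in enumerate(decoder, start=1):
            s_k, f_k = self.side_project(d_k, k, (h, w))
            native.append(s_k)
            upsampled.append(f_k)
            q = getattr(self, f"q{k}")
            attn_logits.append(F.upsample_bilinear(q(d_k), (h, w)))

        # softmax across the 4 levels at every pixel
        attn_stack = Tensor.concat(attn_logits, axis=1).softmax(axis=1)
        f_stack = Tensor.concat(upsampled, axis=1)          # (N, 4, H, W)
        attention = [attn_stack * Tensor(_level_selector(k)) for k in range(4)]

        side = SideOutputs(
            native=native, upsampled=upsampled,
            attention=[a.sum(axis=1, keepdims=True) for a in attention],
            fusion_weights=self.fusion_weights)

        if self.config.fusion == "last":
            logit = self.head(d1)
            return Prediction(mask_prob=logit.sigmoid().reshape(n, h, w),
                              side=side)

        omega = self.fusion_weights.reshape(1, 4, 1, 1)
        fused = (omega * attn_stack * f_stack).sum(axis=1)  # (N, H, W)
        return Prediction(mask_prob=fused.sigmoid(), side=side,
                          extras={"fused_logit": fused})


def _level_selector(k: int) -> np.ndarray:
    sel = np.zeros((1, 4, 1, 1))
    sel[0, k] = 1.0
    return sel


def build_generator(config: GeneratorConfig,
                    rng: np.random.Generator | None = None) -> HedUNetGenerator:
    return HedUNetGenerator(config, rng)
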