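"""Efficient Multi-Scale Attention (EMA), original and improved variants.

EMA reshapes a (B, C, H, W) feature map into G channel groups stacked along
the batch axis, so each group of C/G channels is recalibrated independently:

* 1x1 branch — directional global average pooling along H and W, a shared
  1x1 convolution over the concatenated profiles, sigmoid gates applied per
  spatial direction, then group normalization -> G1;
* 3x3 branch — a 3x3 convolution on the grouped input -> G3;
* cross-spatial fusion — each cross term projects the globally pooled
  channel descriptor of one branch against the flattened spatial map of the
  other and applies a softmax over spatial positions; the sigmoid of the
  summed terms is the per-pixel attention weight multiplied back onto the
  grouped input.

The improved variant adds a second, independent 1x1 convolution branch GN
and two extra cross terms — (pooled G1, spatial GN) and (pooled GN, spatial
G3) — summed with the original pair before sigmoid; the pre-sigmoid sum is
passed through a group normalization first (``prenorm``). ``cross_term`` is
exposed so alternate fusion wirings can be composed and tested explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn.tensor import Tensor, concat, matmul, narrow, softmax

__all__ = ["EMAConfig", "EMA", "directional_pool", "cross_term"]


@dataclass(frozen=True)
class EMAConfig:
    channels: int
    groups: int = 8
    variant: str = "original"  # or "improved"
    prenorm: bool = True  # improved variant: group-normalize before sigmoid

    def __post_init__(self):
        if self.groups < 1:
            raise ValueError("groups must be >= 1")
        if self.channels % self.groups:
            raise ValueError(
                f"channels ({self.channels}) must be divisible by groups ({self.groups})"
            )
        if self.variant not in ("original", "improved"):
            raise ValueError(f"unknown EMA variant {self.variant!r}")


def directional_pool(x: Tensor) -> tuple[Tensor, Tensor]:
    """Mean over width -> (N, c, H, 1) profile; mean over height -> (N, c, 1, W)."""
    return x.mean(axis=3, keepdims=True), x.mean(axis=2, keepdims=True)


def cross_term(pool_branch: Tensor, spatial_branch: Tensor) -> Tensor:
    """softmax over spatial positions of <pooled descriptor, flattened map>.

    ``pool_branch`` is globally average-pooled to a channel descriptor
    (N, 1, c) and projected against the flattened ``spatial_branch``
    (N, c, H*W); the softmax normalizes the resulting (N, 1, H*W) map over
    its spatial positions.
    """
    n, c, h, w = spatial_branch.shape
    desc = pool_branch.mean(axis=(2, 3)).reshape(n, 1, c)
    flat = spatial_branch.reshape(n, c, h * w)
    return softmax(matmul(desc, flat), axis=2)


class EMA(nn.Module):
    def __init__(self, cfg: EMAConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        c = cfg.channels // cfg.groups
        self.conv1x1 = nn.Conv2d(c, c, 1, rng)
        self.conv3x3 = nn.Conv2d(c, c, 3, rng, padding=1)
        self.gn = nn.GroupNorm(c, c)
        if cfg.variant == "improved":
            self.conv1x1_new = nn.Conv2d(c, c, 1, rng)  # independent weights
            if cfg.prenorm:
                self.fuse_norm = nn.GroupNorm(1, 1)

    # -- branches ------------------------------------------------------------
    def branch_1x1(self, xg: Tensor) -> Tensor:
        """Directionally gated + group-normalized branch (G1)."""
        n, c, h, w = xg.shape
        ph, pw = directional_pool(xg)
        stacked = concat([ph, pw.transpose((0, 1, 3, 2))], axis=2)  # (N, c, H+W, 1)
        a = self.conv1x1(stacked)
        ah = narrow(a, 2, 0, h)
        aw = narrow(a, 2, h, w).transpose((0, 1, 3, 2))
        return self.gn(xg * ah.sigmoid() * aw.sigmoid())

    def branch_3x3(self, xg: Tensor) -> Tensor:
        return self.conv3x3(xg)

    def branch_new(self, xg: Tensor) -> Tensor:
        return self.conv1x1_new(xg)

    # -- fusion ---------------------------------------------------------------
    def fuse(self, g1: Tensor, g3: Tensor, gn_new: Tensor | None = None) -> Tensor:
        """Pre-sigmoid attention logits (N, 1, H*W) from branch outputs."""
        pre = cross_term(g1, g3) + cross_term(g3, g1)
        if gn_new is not None:
            pre = pre + cross_term(g1, gn_new) + cross_term(gn_new, g3)
        return pre

    def forward(self, x: Tensor) -> Tensor:
        cfg = self.cfg
        b, ch, h, w = x.shape
        if ch != cfg.channels:
            raise ValueError(f"expected {cfg.channels} channels, got {ch}")
        g = cfg.groups
        xg = x.reshape(b * g, ch // g, h, w)
        g1 = self.branch_1x1(xg)
        g3 = self.branch_3x3(xg)
        gn_new = self.branch_new(xg) if cfg.variant == "improved" else None
        pre = self.fuse(g1, g3, gn_new).reshape(b * g, 1, h, w)
        if cfg.variant == "improved" and cfg.prenorm:
            pre = self.fuse_norm(pre)
        weights = pre.sigmoid()
        return (xg * weights).reshape(b, ch, h, w)
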