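"""Dual-scale attention enhancement decoder block.

Each decoding stage is processed at native resolution and at a 2x
up-sampled resolution in parallel.  Within each scale: 3x3 convolution,
channel attention, and a residual-style sum of the pre- and post-attention
maps ("retain the original structural information").  The up-sampled branch
is folded back to native resolution by 2x average pooling, the scales are
summed, and two convolution+attention stages (channel, then spatial) refine
the fused map.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import nn
from .attention import ChannelAttention, SpatialAttention
from .errors import ConfigurationError, ContractError
from .nn import functional as F
from .nn.tensor import Tensor, astensor


@dataclass
class DaemConfig:
    in_channels: int
    out_channels: int
    reduction: int = 8
    spatial_kernel: int = 7
    upsample_mode: str = "bilinear"

    def __post_init__(self):
        if self.in_channels < 1 or self.out_channels < 1:
            raise ConfigurationError("channel counts must be positive")
        if self.upsample_mode not in ("bilinear", "nearest"):
            raise ConfigurationError(
                f"upsample_mode must be 'bilinear' or 'nearest', got {self.upsample_mode!r}")


class DAEM(nn.Module):
    def __init__(self, cfg: DaemConfig):
        super().__init__()
        self.cfg = cfg
        c_in, c_out = cfg.in_channels, cfg.out_channels
        self.conv_native = nn.ConvBlock(c_in, c_out, 3)
        self.ca_native = ChannelAttention(c_out, cfg.reduction)
        self.conv_up = nn.ConvBlock(c_in, c_out, 3)
        self.ca_up = ChannelAttention(c_out, cfg.reduction)
        self.conv_stage1 = nn.ConvBlock(c_out, c_out, 3)
        self.ca_stage1 = ChannelAttention(c_out, cfg.reduction)
        self.conv_stage2 = nn.ConvBlock(c_out, c_out, 3)
        self.sa_stage2 = SpatialAttention(cfg.spatial_kernel)

    def forward(self, x) -> Tensor:
        x = astensor(x)
        if x.shape[1] != self.cfg.in_channels:
            raise ContractError(
                f"DAEM expects {self.cfg.in_channels} channels, got {x.shape[1]}")
        h, w = x.shape[2], x.shape[3]
        if h < 2 or w < 2:
            raise ContractError(f"DAEM needs spatial extents >= 2, got ({h}, {w})")
        # native-resolution scale
        a = self.conv_native(x)
        _, a_att = self.ca_native(a)
        a = F.add(a, a_att)
        # 2x up-sampled scale, folded back by average pooling
        b = self.conv_up(F.upsample2x(x, mode=self.cfg.upsample_mode))
        _, b_att = self.ca_up(b)
        b = F.avg_pool2d(F.add(b, b_att))
        fused = F.add(a, b)
        # two refinement stages: channel attention, then spatial attention
        _, fused = self.ca_stage1(self.conv_stage1(fused))
        _, fused = self.sa_stage2(self.conv_stage2(fused))
        return fused


def daem_forward(x, cfg: DaemConfig) -> Tensor:
    """One-shot forward through a freshly initialized DAEM."""
    return DAEM(cfg)(x)
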