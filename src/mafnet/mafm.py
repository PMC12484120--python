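"""Multi-receptive attention fusion module (encoder stages 3-4).

Three parallel 3x3 branches at increasing dilation rates (default 1, 3, 5)
widen the receptive field without extra parameters; cross-branch sums feed
each branch the outputs of the earlier ones, spatial/channel attention
alternates across branches, and a final concatenate + 1x1 fusion with one
more spatial attention refines the output.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import nn
from .attention import ChannelAttention, SpatialAttention
from .errors import ConfigurationError, ContractError
from .nn import functional as F
from .nn.tensor import Tensor, astensor


@dataclass
class MafmConfig:
    in_channels: int
    out_channels: int
    dilations: tuple[int, int, int] = (1, 3, 5)
    reduction: int = 8
    spatial_kernel: int = 7
    fusion: str = "concat"  # "concat" (default) or "sum"

    def __post_init__(self):
        if self.in_channels < 1 or self.out_channels < 1:
            raise ConfigurationError("channel counts must be positive")
        d = tuple(self.dilations)
        if len(d) != 3 or any(x < 1 for x in d) or not (d[0] < d[1] < d[2]):
            raise ConfigurationError(
                f"dilations must be a strictly increasing positive triple, got {d}")
        self.dilations = d
        if self.fusion not in ("concat", "sum"):
            raise ConfigurationError(f"fusion must be 'concat' or 'sum', got {self.fusion!r}")


def receptive_side(kernel: int, dilation: int) -> int:
    """Effective kernel side of a dilated convolution: k + (k-1)(d-1)."""
    return kernel + (kernel - 1) * (dilation - 1)


class MAFM(nn.Module):
    def __init__(self, cfg: MafmConfig):
        super().__init__()
        self.cfg = cfg
        w = cfg.out_channels  # working width of the main path
        d1, d2, d3 = cfg.dilations
        self.entry = nn.ConvBlock(cfg.in_channels, w, 1)
        self.branch1 = nn.ConvBlock(w, w, 3, dilation=d1)
        self.sa1 = SpatialAttention(cfg.spatial_kernel)
        self.branch2 = nn.ConvBlock(w, w, 3, dilation=d2)
        self.ca2 = ChannelAttention(w, cfg.reduction)
        self.branch3 = nn.ConvBlock(w, w, 3, dilation=d3)
        self.sa3 = SpatialAttention(cfg.spatial_kernel)
        fuse_in = 4 * w if cfg.fusion == "concat" else w
        self.fuse = nn.ConvBlock(fuse_in, cfg.out_channels, 1)
        self.sa_out = SpatialAttention(cfg.spatial_kernel)

    def forward(self, x) -> Tensor:
        x = astensor(x)
        if x.shape[1] != self.cfg.in_channels:
            raise ContractError(
                f"MAFM expects {self.cfg.in_channels} channels, got {x.shape[1]}")
        main = self.entry(x)
        _, y1 = self.sa1(self.branch1(main))
        _, y2 = self.ca2(self.branch2(F.add(main, y1)))
        _, y3 = self.sa3(self.branch3(F.add(F.add(main, y1), y2)))
        if self.cfg.fusion == "concat":
            fused = self.fuse(F.concat([y1, y2, y3, main], axis=1))
        else:
            fused = self.fuse(F.add(F.add(y1, y2), F.add(y3, main)))
        _, out = self.sa_out(fused)
        return out


def mafm_forward(x, cfg: MafmConfig) -> Tensor:
    """One-shot forward through a freshly initialized MAFM."""
    return MAFM(cfg)(x)
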