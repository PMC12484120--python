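"""Dual-path squeeze-and-excitation enhancement of skip connections.

Fuses the encoder skip tensor (input1, at skip resolution) with the
deeper decoder tensor (input2, at half that resolution, up-sampled 2x)
by channel concatenation, then applies two cascaded SE gates, each with
an additive residual shortcut, extracts a convolutional feature from the
result, and densely fuses [enhanced1, enhanced2, conv] with a 1x1
convolution.  Single-path variants keep the same machinery on one
aligned stream.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import nn
from .attention import SEBlock
from .errors import ConfigurationError, ContractError
from .nn import functional as F
from .nn.tensor import Tensor, astensor

PATH_MODES = ("dual", "input1_only", "input2_only")


@dataclass
class DseemConfig:
    enc_channels: int
    dec_channels: int
    out_channels: int
    reduction: int = 8
    path_mode: str = "dual"
    upsample_mode: str = "bilinear"
    residual: bool = True  # additive shortcut around each SE gate

    def __post_init__(self):
        if min(self.enc_channels, self.dec_channels, self.out_channels) < 1:
            raise ConfigurationError("channel counts must be positive")
        if self.path_mode not in PATH_MODES:
            raise ConfigurationError(
                f"path_mode must be one of {PATH_MODES}, got {self.path_mode!r}")


class DSEEM(nn.Module):
    def __init__(self, cfg: DseemConfig):
        super().__init__()
        self.cfg = cfg
        self.enc_conv = nn.ConvBlock(cfg.enc_channels, cfg.enc_channels, 3)
        if cfg.path_mode == "dual":
            base = cfg.enc_channels + cfg.dec_channels
        elif cfg.path_mode == "input1_only":
            base = cfg.enc_channels
        else:
            base = cfg.dec_channels
        self.base_channels = base
        self.se1 = SEBlock(base, cfg.reduction)
        self.se2 = SEBlock(base, cfg.reduction)
        self.conv = nn.ConvBlock(base, cfg.out_channels, 3)
        self.fuse = nn.ConvBlock(2 * base + cfg.out_channels, cfg.out_channels, 1)

    def forward(self, input1, input2, return_intermediates: bool = False):
        input1, input2 = astensor(input1), astensor(input2)
        cfg = self.cfg
        if input1.shape[1] != cfg.enc_channels:
            raise ContractError(
                f"input1 has {input1.shape[1]} channels, expected {cfg.enc_channels}")
        if input2.shape[1] != cfg.dec_channels:
            raise ContractError(
                f"input2 has {input2.shape[1]} channels, expected {cfg.dec_channels}")
        h, w = input1.shape[2], input1.shape[3]
        if abs(input2.shape[2] * 2 - h) > 2 or abs(input2.shape[3] * 2 - w) > 2:
            raise ContractError(
                f"input2 extents {input2.shape[2:]} are not ~half of input1's ({h}, {w})")
        up2 = F.resize(input2, (h, w), mode=cfg.upsample_mode)
        a1 = self.enc_conv(input1)
        if cfg.path_mode == "dual":
            base = F.concat([a1, up2], axis=1)
        elif cfg.path_mode == "input1_only":
            base = a1
        else:
            base = up2
        w1, gated1 = self.se1(base)
        enhanced1 = F.add(gated1, base) if cfg.residual else gated1
        w2, gated2 = self.se2(enhanced1)
        enhanced2 = F.add(gated2, enhanced1) if cfg.residual else gated2
        conv_feat = self.conv(enhanced2)
        out = self.fuse(F.concat([enhanced1, enhanced2, conv_feat], axis=1))
        if return_intermediates:
            return out, {"base": base, "enhanced1": enhanced1,
                         "enhanced2": enhanced2, "conv": conv_feat,
                         "w1": w1, "w2": w2}
        return out


def dseem_forward(input1, input2, cfg: DseemConfig) -> Tensor:
    """One-shot forward through a freshly initialized DSEEM."""
    return DSEEM(cfg)(input1, input2)
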