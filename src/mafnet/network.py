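"""MAF-Net assembly: 4-stage encoder, 3-step decoder, sigmoid head.

Encoder stages 1-2 are plain double 3x3 convolutions; stages 3-4 use the
multi-receptive attention fusion module (MAFM) when enabled.  Each decoder
step fuses the skip tensor with the deeper features through the dual-path
SE enhancement module (DSEEM) when enabled (plain 2x upsample + 1x1
projection + concatenation otherwise), then refines with the dual-scale
attention enhancement module (DAEM) when enabled (double conv otherwise).
All three modules have independent enable flags so the ablation grid of
{baseline, +MAFM, +DAEM, +DSEEM, all} is a config sweep.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml

from . import nn
from .daem import DAEM, DaemConfig
from .dseem import DSEEM, DseemConfig, PATH_MODES
from .errors import ConfigurationError, ContractError
from .mafm import MAFM, MafmConfig
from .nn import functional as F
from .nn.tensor import Tensor, astensor


@dataclass
class ModelConfig:
    in_channels: int = 1
    stage_widths: tuple[int, int, int, int] = (32, 64, 128, 256)
    use_mafm: bool = True
    use_daem: bool = True
    use_dseem: bool = True
    mafm_dilations: tuple[int, int, int] = (1, 3, 5)
    reduction: int = 8
    spatial_kernel: int = 7
    upsample_mode: str = "bilinear"
    dseem_path_mode: str = "dual"
    mafm_fusion: str = "concat"

    def __post_init__(self):
        if self.in_channels not in (1, 3):
            raise ConfigurationError(f"in_channels must be 1 or 3, got {self.in_channels}")
        widths = tuple(int(w) for w in self.stage_widths)
        if len(widths) != 4 or any(w < 1 for w in widths):
            raise ConfigurationError("stage_widths must be 4 positive integers")
        if not all(a < b for a, b in zip(widths, widths[1:])):
            raise ConfigurationError(f"stage_widths must be strictly increasing, got {widths}")
        self.stage_widths = widths
        self.mafm_dilations = tuple(int(d) for d in self.mafm_dilations)
        if self.spatial_kernel % 2 == 0:
            raise ConfigurationError("spatial_kernel must be odd")
        if self.upsample_mode not in ("bilinear", "nearest"):
            raise ConfigurationError(f"unknown upsample_mode {self.upsample_mode!r}")
        if self.dseem_path_mode not in PATH_MODES:
            raise ConfigurationError(f"unknown dseem_path_mode {self.dseem_path_mode!r}")

    # -- YAML round trip ---------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["stage_widths"] = list(self.stage_widths)
        d["mafm_dilations"] = list(self.mafm_dilations)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        if "stage_widths" in d:
            d["stage_widths"] = tuple(d["stage_widths"])
        if "mafm_dilations" in d:
            d["mafm_dilations"] = tuple(d["mafm_dilations"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "ModelConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


class _PlainUp(nn.Module):
    """2x upsample + 1x1 channel projection + concat with the skip tensor."""

    def __init__(self, dec_channels: int, skip_channels: int, mode: str):
        super().__init__()
        self.mode = mode
        self.proj = nn.ConvBlock(dec_channels, skip_channels, 1)

    def forward(self, skip: Tensor, deep: Tensor) -> Tensor:
        up = F.resize(deep, (skip.shape[2], skip.shape[3]), mode=self.mode)
        return F.concat([skip, self.proj(up)], axis=1)


class MAFNet(nn.Module):
    """Encoder-decoder segmentation network with optional MAFM/DAEM/DSEEM."""

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        self.cfg = cfg
        w1, w2, w3, w4 = cfg.stage_widths

        def enc_stage(cin, cout):
            if cfg.use_mafm:
                return MAFM(MafmConfig(cin, cout, dilations=cfg.mafm_dilations,
                                       reduction=cfg.reduction,
                                       spatial_kernel=cfg.spatial_kernel,
                                       fusion=cfg.mafm_fusion))
            return nn.DoubleConv(cin, cout)

        self.enc1 = nn.DoubleConv(cfg.in_channels, w1)
        self.enc2 = nn.DoubleConv(w1, w2)
        self.enc3 = enc_stage(w2, w3)
        self.enc4 = enc_stage(w3, w4)

        def dec_step(skip_w, deep_w):
            if cfg.use_dseem:
                merge = DSEEM(DseemConfig(skip_w, deep_w, skip_w,
                                          reduction=cfg.reduction,
                                          path_mode=cfg.dseem_path_mode,
                                          upsample_mode=cfg.upsample_mode))
                merged_w = skip_w
            else:
                merge = _PlainUp(deep_w, skip_w, cfg.upsample_mode)
                merged_w = 2 * skip_w
            if cfg.use_daem:
                refine = DAEM(DaemConfig(merged_w, skip_w, reduction=cfg.reduction,
                                         spatial_kernel=cfg.spatial_kernel,
                                         upsample_mode=cfg.upsample_mode))
            else:
                refine = nn.DoubleConv(merged_w, skip_w)
            return merge, refine

        self.merge3, self.refine3 = dec_step(w3, w4)
        self.merge2, self.refine2 = dec_step(w2, w3)
        self.merge1, self.refine1 = dec_step(w1, w2)
        self.head = nn.Conv2d(w1, 1, 1, bias=True)

    def forward(self, x) -> Tensor:
        x = astensor(x)
        if x.ndim != 4:
            raise ContractError(f"expected a (batch, channel, H, W) array, got ndim={x.ndim}")
        if x.shape[1] != self.cfg.in_channels:
            raise ContractError(
                f"expected {self.cfg.in_channels} input channels, got {x.shape[1]}")
        h, w = x.shape[2], x.shape[3]
        if h % 8 or w % 8:
            raise ContractError(
                f"input extents ({h}, {w}) must be divisible by 8 (three 2x poolings)")
        s1 = self.enc1(x)
        s2 = self.enc2(F.max_pool2d(s1))
        s3 = self.enc3(F.max_pool2d(s2))
        s4 = self.enc4(F.max_pool2d(s3))
        d3 = self.refine3(self.merge3(s3, s4))
        d2 = self.refine2(self.merge2(s2, d3))
        d1 = self.refine1(self.merge1(s1, d2))
        return F.sigmoid(self.head(d1))

    def predict(self, x) -> np.ndarray:
        """Inference-mode probabilities as a plain array."""
        was_training = self.training
        self.eval()
        try:
            with nn.no_grad():
                out = self.forward(x).data
        finally:
            if was_training:
                self.train()
        return out


def build_model(cfg: ModelConfig, seed: int = 0) -> MAFNet:
    """Deterministically initialize a MAFNet from its configuration."""
    nn.manual_seed(seed)
    return MAFNet(cfg)


def count_parameters(model: nn.Module) -> int:
    """Exact count of trainable scalars."""
    return model.num_parameters()


# -- checkpointing ----------------------------------------------------------


def save_checkpoint(model: MAFNet, path) -> None:
    """Write weights (.npz) plus the model config as YAML alongside."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **model.state_dict())
    model.cfg.to_yaml(path.with_suffix(".yaml"))


def load_checkpoint(path) -> MAFNet:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"checkpoint not found: {path}")
    cfg_path = path.with_suffix(".yaml")
    if not cfg_path.exists():
        raise FileNotFoundError(f"checkpoint config not found: {cfg_path}")
    cfg = ModelConfig.from_yaml(cfg_path)
    model = build_model(cfg, seed=0)
    with np.load(path) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model
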