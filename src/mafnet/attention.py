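"""Attention building blocks: spatial attention, channel attention, SE.

All three produce gating weights through a sigmoid, so every weight lies
strictly in (0, 1), and return both the weights and the gated features.
Spatial/channel attention follow the CBAM lineage (mean+max descriptors,
shared bottleneck); the squeeze-and-excitation block keeps only the
average-pool squeeze.
"""

from __future__ import annotations

from . import nn
from .errors import ConfigurationError, ContractError
from .nn import functional as F
from .nn.tensor import Tensor, astensor


def _hidden_width(channels: int, reduction: int) -> int:
    if reduction <= 0:
        raise ConfigurationError(f"reduction must be positive, got {reduction}")
    return max(1, channels // reduction)


class SpatialAttention(nn.Module):
    """Per-pixel gate from the channel-wise mean and max maps.

    The two descriptor maps are concatenated and convolved with a single
    ``kernel x kernel`` filter; a sigmoid yields one weight per pixel,
    broadcast over channels.
    """

    def __init__(self, kernel: int = 7):
        super().__init__()
        if kernel % 2 == 0 or kernel < 3:
            raise ConfigurationError(f"spatial-attention kernel must be odd and >= 3, got {kernel}")
        self.kernel = kernel
        self.conv = nn.Conv2d(2, 1, kernel, bias=True)

    def forward(self, x) -> tuple[Tensor, Tensor]:
        x = astensor(x)
        desc = F.concat([F.channel_mean(x), F.channel_max(x)], axis=1)
        weights = F.sigmoid(self.conv(desc))
        return weights, F.mul(x, weights)


class ChannelAttention(nn.Module):
    """Per-channel gate from global average- and max-pooled descriptors.

    Both descriptors pass the same two-layer bottleneck
    (C -> C/reduction -> C, ReLU between); the outputs are summed and
    squashed by a sigmoid.
    """

    def __init__(self, channels: int, reduction: int = 8):
        super().__init__()
        hidden = _hidden_width(channels, reduction)
        self.channels = channels
        self.fc1 = nn.Linear(channels, hidden)
        self.fc2 = nn.Linear(hidden, channels)

    def _bottleneck(self, pooled: Tensor) -> Tensor:
        flat = F.reshape(pooled, (pooled.shape[0], self.channels))
        return self.fc2(F.relu(self.fc1(flat)))

    def forward(self, x) -> tuple[Tensor, Tensor]:
        x = astensor(x)
        if x.shape[1] != self.channels:
            raise ContractError(f"expected {self.channels} channels, got {x.shape[1]}")
        avg = self._bottleneck(F.global_avg_pool(x))
        mx = self._bottleneck(F.global_max_pool(x))
        weights = F.sigmoid(F.reshape(F.add(avg, mx), (x.shape[0], self.channels, 1, 1)))
        return weights, F.mul(x, weights)


class SEBlock(nn.Module):
    """Squeeze-and-excitation: average-pool squeeze, FC bottleneck, sigmoid."""

    def __init__(self, channels: int, reduction: int = 8):
        super().__init__()
        hidden = _hidden_width(channels, reduction)
        self.channels = channels
        self.fc1 = nn.Linear(channels, hidden)
        self.fc2 = nn.Linear(hidden, channels)

    def forward(self, x) -> tuple[Tensor, Tensor]:
        x = astensor(x)
        if x.shape[1] != self.channels:
            raise ContractError(f"expected {self.channels} channels, got {x.shape[1]}")
        squeezed = F.reshape(F.global_avg_pool(x), (x.shape[0], self.channels))
        excited = self.fc2(F.relu(self.fc1(squeezed)))
        weights = F.sigmoid(F.reshape(excited, (x.shape[0], self.channels, 1, 1)))
        return weights, F.mul(x, weights)


def spatial_attention(x, kernel: int = 7) -> tuple[Tensor, Tensor]:
    """Functional form (fresh parameters); returns (weights, gated features)."""
    return SpatialAttention(kernel)(x)


def channel_attention(x, reduction: int = 8) -> tuple[Tensor, Tensor]:
    x = astensor(x)
    return ChannelAttention(x.shape[1], reduction)(x)


def se_block(x, reduction: int = 8) -> tuple[Tensor, Tensor]:
    x = astensor(x)
    return SEBlock(x.shape[1], reduction)(x)
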