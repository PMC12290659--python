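"""Width-scalable 50-layer bottleneck residual encoder and projection head.

The encoder follows the standard 50-layer residual architecture (a 7x7
stem, four stages of bottleneck blocks with block counts 3-4-6-3, and global
average pooling instead of a classification layer), with every block's
channel width multiplied by a configurable ``width_fraction``.  At full width
the pooled output has 2048 channels; at 1/8 width — the default used for
3D-PLI texture learning, which limits encoder capacity so that rare,
high-contrast structures cannot trivially solve the contrastive objective —
it has 256.

The projection head is a two-layer MLP (hidden 90, output 32) used only
during contrastive training and discarded for inference.
"""

from __future__ import annotations

import numpy as np

from . import nn

__all__ = ["ResNetEncoder", "ProjectionHead", "scaled_width"]

_BLOCK_COUNTS = (3, 4, 6, 3)
_BASE_WIDTHS = (64, 128, 256, 512)
_EXPANSION = 4


def scaled_width(base: int, width_fraction: float) -> int:
    w = int(round(base * width_fraction))
    if w < 1:
        raise ValueError(f"width fraction {width_fraction} collapses a {base}-channel block to zero")
    return w


class _Bottleneck(nn.Module):
    """1x1 reduce -> 3x3 (carries the stride) -> 1x1 expand, with identity skip."""

    def __init__(self, cin: int, mid: int, cout: int, stride: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.conv1 = nn.Conv2d(cin, mid, 1, rng=rng)
        self.bn1 = nn.BatchNorm2d(mid)
        self.conv2 = nn.Conv2d(mid, mid, 3, stride=stride, padding=1, rng=rng)
        self.bn2 = nn.BatchNorm2d(mid)
        self.conv3 = nn.Conv2d(mid, cout, 1, rng=rng)
        self.bn3 = nn.BatchNorm2d(cout)
        if stride != 1 or cin != cout:
            self.down_conv = nn.Conv2d(cin, cout, 1, stride=stride, rng=rng)
            self.down_bn = nn.BatchNorm2d(cout)
            self.has_down = True
        else:
            self.has_down = False

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        out = nn.relu(self.bn1(self.conv1(x)))
        out = nn.relu(self.bn2(self.conv2(out)))
        out = self.bn3(self.conv3(out))
        skip = self.down_bn(self.down_conv(x)) if self.has_down else x
        return nn.relu(nn.add(out, skip))


class ResNetEncoder(nn.Module):
    """The 50-layer residual encoder with scaled channel widths.

    Parameters
    ----------
    width_fraction:
        Multiplier on every block's channel width; 1/8 yields a 256-d output,
        1 the full 2048-d output.
    input_channels:
        Number of input image channels (3 for the cyclic-safe PLI encoding).
    """

    def __init__(self, width_fraction: float = 0.125, input_channels: int = 3, rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        stem = scaled_width(64, width_fraction)
        self.width_fraction = width_fraction
        self.stem_conv = nn.Conv2d(input_channels, stem, 7, stride=2, padding=3, rng=rng)
        self.stem_bn = nn.BatchNorm2d(stem)
        self._block_names: list[str] = []
        cin = stem
        for stage, (blocks, base) in enumerate(zip(_BLOCK_COUNTS, _BASE_WIDTHS)):
            mid = scaled_width(base, width_fraction)
            cout = mid * _EXPANSION
            for b in range(blocks):
                stride = 2 if (stage > 0 and b == 0) else 1
                name = f"stage{stage + 1}_block{b + 1}"
                setattr(self, name, _Bottleneck(cin, mid, cout, stride, rng))
                self._block_names.append(name)
                cin = cout
        self.feature_dim = cin

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        out = nn.relu(self.stem_bn(self.stem_conv(x)))
        out = nn.max_pool2d(out, kernel=3, stride=2, padding=1)
        for name in self._block_names:
            out = getattr(self, name)(out)
        return nn.global_avg_pool(out)


class ProjectionHead(nn.Module):
    def __init__(self, feature_dim: int, hidden: int = 90, out: int = 32, rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.fc1 = nn.Linear(feature_dim, hidden, rng=rng)
        self.fc2 = nn.Linear(hidden, out, rng=rng)

    def forward(self, h: nn.Tensor) -> nn.Tensor:
        return self.fc2(nn.relu(self.fc1(h)))
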