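"""The dual-encoding multiscale-feature-fusion segmentation network.

Two four-level encoder paths read the same image at two resolutions: the
high-resolution view enters a path of single dense aggregation blocks
(SDAB) through a stride-2 stem, the half-resolution view enters a path of
residual bottleneck blocks (RB) through a stride-1 stem, so both paths
share one spatial grid at every level. At each level a multiscale fusion
block (MFB) cross-concatenates the two paths' features together with a
pooled-and-projected carry of the previous level's fused output. The
decoder upsamples from a fused bottleneck, concatenates a projected skip
of the two fused outputs per level, applies coordinate attention to the
concatenation, and refines with two 3x3 convolutions. A 1x1 head plus
sigmoid and a final 2x upsampling produce a per-pixel lesion probability
on the high-resolution grid.

Channel widths double per level. The free widths the architecture does not
pin down (``base_width``, ``sdab_growth``, ``carry_width``,
``bottleneck_width``) are calibrated so that the trainable-parameter count
of the reference configuration reproduces the published totals for
L = 4/6/8/10 dense-chain convolutions (13.24 / 14.97 / 16.69 / 18.42 M);
see docs/methods.md for the calibration procedure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .autodiff import Tensor, concat


@dataclass
class NetworkConfig:
    """Every architectural hyperparameter, including ablation switches.

    Defaults are the calibrated reference configuration.
    """

    n_levels: int = 4
    in_channels: int = 1
    out_channels: int = 1
    base_width: int = 64
    width_multiplier: int = 2
    sdab_layers: int = 10          # L, number of 3x3 convs per dense chain
    sdab_growth: int = 142         # channels of each dense-chain layer
    rb_bottleneck_ratio: int = 4   # residual-block 1x1 reduction factor
    ca_reduction: int = 16         # coordinate-attention bottleneck ratio
    carry_width: int = 304         # channels of the pooled previous-level carry
    bottleneck_width: int = 1024   # channels after the bottleneck projection
    use_rb: bool = True
    use_sdab: bool = True
    use_mfb: bool = True
    use_ca: bool = True
    ca_activation: str = "hardswish"   # "relu" also supported
    theta_order: str = "bn_first"      # dense-chain conv/BN/ReLU ordering
    seed: int = 0

    def __post_init__(self):
        if self.n_levels < 1:
            raise ValueError(f"n_levels must be >= 1, got {self.n_levels}")
        if self.sdab_layers < 2:
            raise ValueError(f"sdab_layers must be >= 2, got {self.sdab_layers}")
        for fld in ("base_width", "sdab_growth", "rb_bottleneck_ratio",
                    "ca_reduction", "carry_width", "bottleneck_width",
                    "width_multiplier", "in_channels", "out_channels"):
            if getattr(self, fld) < 1:
                raise ValueError(f"{fld} must be positive, got {getattr(self, fld)}")
        if self.base_width % self.rb_bottleneck_ratio:
            raise ValueError(
                f"base_width {self.base_width} not divisible by "
                f"rb_bottleneck_ratio {self.rb_bottleneck_ratio}"
            )
        if self.ca_activation not in ("hardswish", "relu"):
            raise ValueError(f"unknown ca_activation {self.ca_activation!r}")
        if self.theta_order not in ("bn_first", "act_first"):
            raise ValueError(f"unknown theta_order {self.theta_order!r}")

    def level_width(self, level: int) -> int:
        """Nominal channel width at encoder level (1-based)."""
        return self.base_width * self.width_multiplier ** (level - 1)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        return cls(**d)


@dataclass
class ParamCount:
    """Trainable-scalar accounting, raw and in millions (2 d.p.)."""

    total: int
    per_module: dict[str, int] = field(default_factory=dict)

    @property
    def millions(self) -> float:
        return round(self.total / 1e6, 2)

    def __post_init__(self):
        if self.per_module and sum(self.per_module.values()) != self.total:
            raise ValueError("per-module breakdown does not sum to total")


class ResidualBlock(nn.Module):
    """Bottleneck residual block: ReLU(x + BN(1x1(3x3(1x1(x)))))."""

    def __init__(self, width: int, ratio: int, rng):
        super().__init__()
        mid = width // ratio
        self.reduce = nn.ConvBNAct(width, mid, 1, rng)
        self.conv = nn.ConvBNAct(mid, mid, 3, rng)
        self.expand = nn.Conv2d(mid, width, 1, rng, bias=False)
        self.bn = nn.BatchNorm2d(width)
        self.width = width

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.width:
            raise ValueError(
                f"residual block expects {self.width} channels for the identity "
                f"skip, got {x.shape[1]}"
            )
        path = self.bn(self.expand(self.conv(self.reduce(x))))
        return (x + path).relu()

    __call__ = forward


class SingleDenseAggregationBlock(nn.Module):
    """Chain of L 3x3 convs; all L outputs concatenated once at the end.

    Unlike a dense block, intermediate layers see only their immediate
    predecessor; the block input itself is excluded from the aggregation.
    A 1x1 projection brings the L*growth concatenation to the level width.
    """

    def __init__(self, in_ch: int, L: int, growth: int, out_width: int, rng,
                 order: str = "bn_first"):
        super().__init__()
        if L < 2:
            raise ValueError(f"dense chain needs L >= 2 layers, got {L}")
        self.layers = [nn.ConvBNAct(in_ch, growth, 3, rng, order=order)]
        self.layers += [
            nn.ConvBNAct(growth, growth, 3, rng, order=order) for _ in range(L - 1)
        ]
        self.project = nn.ConvBNAct(L * growth, out_width, 1, rng)

    def aggregate(self, x: Tensor) -> Tensor:
        """The raw L*growth-channel concatenation, before projection."""
        feats = []
        for layer in self.layers:
            x = layer(x)
            feats.append(x)
        return concat(feats, axis=1)

    def forward(self, x: Tensor) -> Tensor:
        return self.project(self.aggregate(x))

    __call__ = forward


class PlainBlock(nn.Module):
    """Two 3x3 conv+BN+ReLU; ablation stand-in for RB or SDAB."""

    def __init__(self, in_ch: int, width: int, rng):
        super().__init__()
        self.c1 = nn.ConvBNAct(in_ch, width, 3, rng)
        self.c2 = nn.ConvBNAct(width, width, 3, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.c2(self.c1(x))

    __call__ = forward


class MultiscaleFusionBlock(nn.Module):
    """Cross-concatenate the two paths plus a carry of the previous fusion.

    O1 = proj(concat[I1, I2, down(O1_prev)]) and symmetrically for O2; the
    carry term is a 2x2 max-pool followed by a 1x1 projection to a fixed
    carry width. At level 1 there is no carry. With ``cross=False`` each
    path only self-concatenates (the fusion ablation).
    """

    def __init__(self, width: int, prev_width: int | None, carry: int, rng,
                 cross: bool = True):
        super().__init__()
        self.cross = cross
        self.has_carry = prev_width is not None
        in_ch = (2 * width if cross else width) + (carry if self.has_carry else 0)
        if self.has_carry:
            self.down1 = nn.ConvBNAct(prev_width, carry, 1, rng)
            self.down2 = nn.ConvBNAct(prev_width, carry, 1, rng)
        self.proj1 = nn.ConvBNAct(in_ch, width, 1, rng)
        self.proj2 = nn.ConvBNAct(in_ch, width, 1, rng)

    def forward(self, I1: Tensor, I2: Tensor,
                O1_prev: Tensor | None = None, O2_prev: Tensor | None = None):
        if self.has_carry:
            c1 = self.down1(O1_prev.maxpool2x2())
            c2 = self.down2(O2_prev.maxpool2x2())
            if c1.shape[2:] != I1.shape[2:]:
                raise ValueError(
                    f"carry grid {c1.shape[2:]} does not match level grid "
                    f"{I1.shape[2:]}"
                )
            parts1 = [I1, I2, c1] if self.cross else [I1, c1]
            parts2 = [I2, I1, c2] if self.cross else [I2, c2]
        else:
            parts1 = [I1, I2] if self.cross else [I1]
            parts2 = [I2, I1] if self.cross else [I2]
        return self.proj1(concat(parts1, axis=1)), self.proj2(concat(parts2, axis=1))

    __call__ = forward


class CoordinateAttention(nn.Module):
    """Attention from per-row and per-column average-pooled descriptors.

    Row means (C x H x 1) and permuted column means (C x W x 1) are
    concatenated along the spatial axis, encoded by a shared 1x1 conv +
    BN + non-linearity at reduced width, split back, and expanded by two
    1x1 convs with sigmoid into row- and column-attention maps that gate
    the input multiplicatively.
    """

    def __init__(self, channels: int, reduction: int, rng, act: str = "hardswish"):
        super().__init__()
        mid = max(1, channels // reduction)
        self.encode = nn.ConvBNAct(channels, mid, 1, rng, act=act)
        self.expand_h = nn.Conv2d(mid, channels, 1, rng, bias=True)
        self.expand_w = nn.Conv2d(mid, channels, 1, rng, bias=True)

    def forward(self, x: Tensor) -> Tensor:
        H, W = x.shape[2], x.shape[3]
        z_h = x.mean(axis=3, keepdims=True)                   # N,C,H,1
        z_w = x.mean(axis=2, keepdims=True).transpose((0, 1, 3, 2))  # N,C,W,1
        y = self.encode(concat([z_h, z_w], axis=2))           # N,mid,H+W,1
        y_h = y.narrow(2, 0, H)
        y_w = y.narrow(2, H, W).transpose((0, 1, 3, 2))       # N,mid,1,W
        a_h = self.expand_h(y_h).sigmoid()                    # N,C,H,1
        a_w = self.expand_w(y_w).sigmoid()                    # N,C,1,W
        return x * a_h * a_w

    __call__ = forward


class DecoderStep(nn.Module):
    """Upsample, fuse the level's skip, attend, refine."""

    def __init__(self, in_ch: int, width: int, config: NetworkConfig, rng):
        super().__init__()
        self.up = nn.ConvBNAct(in_ch, width, 3, rng)
        self.skip = nn.ConvBNAct(2 * width, width, 1, rng)
        self.ca = (CoordinateAttention(2 * width, config.ca_reduction, rng,
                                       act=config.ca_activation)
                   if config.use_ca else None)
        self.c1 = nn.ConvBNAct(2 * width, width, 3, rng)
        self.c2 = nn.ConvBNAct(width, width, 3, rng)

    def forward(self, x: Tensor, O1: Tensor, O2: Tensor) -> Tensor:
        x = self.up(x.upsample_bilinear2x())
        s = self.skip(concat([O1, O2], axis=1))
        y = concat([x, s], axis=1)
        if self.ca is not None:
            y = self.ca(y)
        return self.c2(self.c1(y))

    __call__ = forward


class DMFFNet(nn.Module):
    """The full network; ``forward`` maps a dual-resolution input to a
    per-pixel probability map on the high-resolution grid."""

    def __init__(self, config: NetworkConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        n = config.n_levels
        w1 = config.level_width(1)

        self.stem_high = nn.ConvBNAct(config.in_channels, w1, 3, rng, stride=2)
        self.stem_low = nn.ConvBNAct(config.in_channels, w1, 3, rng, stride=1)

        self.rb_blocks, self.sdab_blocks, self.fusion = [], [], []
        self.trans_rb, self.trans_sdab = [], []
        for i in range(1, n + 1):
            w = config.level_width(i)
            if config.use_rb:
                self.rb_blocks.append(
                    ResidualBlock(w, config.rb_bottleneck_ratio, rng))
            else:
                self.rb_blocks.append(PlainBlock(w, w, rng))
            if config.use_sdab:
                self.sdab_blocks.append(SingleDenseAggregationBlock(
                    w, config.sdab_layers, config.sdab_growth, w, rng,
                    order=config.theta_order))
            else:
                self.sdab_blocks.append(PlainBlock(w, w, rng))
            prev_w = config.level_width(i - 1) if i > 1 else None
            self.fusion.append(MultiscaleFusionBlock(
                w, prev_w, config.carry_width, rng, cross=config.use_mfb))
            if i < n:
                w_next = config.level_width(i + 1)
                self.trans_rb.append(nn.ConvBNAct(w, w_next, 1, rng))
                self.trans_sdab.append(nn.ConvBNAct(w, w_next, 1, rng))

        wn = config.level_width(n)
        self.bottleneck = nn.ConvBNAct(2 * wn, config.bottleneck_width, 1, rng)

        self.decoder = []
        in_ch = config.bottleneck_width
        for i in range(n - 1, 0, -1):
            w = config.level_width(i)
            self.decoder.append(DecoderStep(in_ch, w, config, rng))
            in_ch = w
        self.head = nn.Conv2d(w1, config.out_channels, 1, rng, bias=True)

    def forward(self, high: Tensor | np.ndarray, low: Tensor | np.ndarray,
                return_features: bool = False):
        """``high``: (N, C, H, W); ``low``: (N, C, H/2, W/2)."""
        high = high if isinstance(high, Tensor) else Tensor(high)
        low = low if isinstance(low, Tensor) else Tensor(low)
        if (high.shape[2] != 2 * low.shape[2]
                or high.shape[3] != 2 * low.shape[3]):
            raise ValueError(
                f"low-res view {low.shape[2:]} must be exactly half of "
                f"high-res {high.shape[2:]}"
            )
        cfg = self.config
        n = cfg.n_levels
        x1 = self.stem_low(low)      # RB path
        x2 = self.stem_high(high)    # SDAB path
        feats: dict[str, Tensor] = {}
        O1 = O2 = None
        skips = []
        for i in range(1, n + 1):
            I1 = self.rb_blocks[i - 1](x1)
            I2 = self.sdab_blocks[i - 1](x2)
            w = cfg.level_width(i)
            for name, t in (("I1", I1), ("I2", I2)):
                if t.shape[1] != w:
                    raise AssertionError(
                        f"level {i} {name}: declared width {w}, observed "
                        f"{t.shape[1]}"
                    )
            O1, O2 = self.fusion[i - 1](I1, I2, O1, O2)
            feats[f"I1_{i}"], feats[f"I2_{i}"] = I1, I2
            feats[f"O1_{i}"], feats[f"O2_{i}"] = O1, O2
            skips.append((O1, O2))
            if i < n:
                x1 = self.trans_rb[i - 1](O1.maxpool2x2())
                x2 = self.trans_sdab[i - 1](O2.maxpool2x2())
        y = self.bottleneck(concat([O1, O2], axis=1))
        for step, (s1, s2) in zip(self.decoder, reversed(skips[:-1])):
            y = step(y, s1, s2)
        out = self.head(y).sigmoid().upsample_bilinear2x()
        if return_features:
            return out, feats
        return out

    __call__ = forward

    def predict(self, high: np.ndarray, low: np.ndarray,
                threshold: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
        """Eval-mode soft and thresholded prediction (no graph kept)."""
        was_training = self.training
        self.eval()
        soft = self.forward(high, low).data
        if was_training:
            self.train()
        return soft, (soft >= threshold).astype(np.uint8)


def build_network(config: NetworkConfig) -> DMFFNet:
    """Construct the network; weight init is deterministic in ``config.seed``."""
    return DMFFNet(config)


def count_parameters(network: DMFFNet) -> ParamCount:
    """Count every trainable scalar, with a per-submodule breakdown."""
    per: dict[str, int] = {}
    for name, p in network.named_parameters():
        top = name.split(".")[0]
        per[top] = per.get(top, 0) + p.data.size
    return ParamCount(total=sum(per.values()), per_module=per)
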