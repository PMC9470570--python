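"""Xception backbone with embeddable residual attention (Xception-RA).

The backbone's 36 convolutional layers are organised into 14 modules across
three flows of 4, 8 and 2 blocks.  Block 1 is the stem (two unpadded
stride-2 3x3 convolutions); blocks 2–4 are entry-flow downsampling blocks
(two depthwise-separable convolutions plus ceil-mode max-pooling, with a
stride-2 1x1-convolution shortcut); blocks 5–12 are middle-flow blocks
(three separable convolutions with an identity shortcut, spatial size
preserved); block 13 downsamples like an entry block and block 14 is two
separable convolutions without a residual.  At the default input side of
441 px this yields the per-block side chain

    109, 55, 28, 14, 14 x 8, 7, 7

so the attention embedding points after blocks 2, 3 and 12 see maps of
55, 28 and 14, and the network minimum is 7.

A residual attention module splits into a trunk branch T(x) — one
middle-flow block — and a soft mask branch M(x), a bottom-up/top-down
encoder–decoder (max-pool downsamplings mirrored by nearest-neighbour
upsamplings, with skip connections between matching scales) ending in two
1x1 convolutions and a sigmoid, so M(x) is in (0, 1) and has the trunk's
shape.  The branches combine as

    H(x) = (1 + M(x)) * T(x)

which lets the mask amplify informative features but never erase the trunk
signal: at M = 0 the module is an identity on T(x).  The mask also filters
gradients: because M does not depend on the trunk parameters phi,
d(M*T)/d(phi) = M * dT/d(phi).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import functional as F
from .nn.autograd import Tensor, as_tensor

__all__ = [
    "ChannelPlan", "BackboneConfig", "AttentionConfig", "ConfigError",
    "XceptionBackbone", "AttentionModule", "XceptionRA",
    "build_backbone", "forward_shapes", "attention_combine",
    "build_attention_module", "assemble_xception_ra",
    "mask_gradient_property", "force_zero_mask", "describe",
]

TOTAL_BLOCKS = 14


class ConfigError(ValueError):
    """Invalid or mutually inconsistent architecture configuration."""


@dataclass(frozen=True)
class ChannelPlan:
    """Per-block channel widths.

    ``stem`` is the two stem convolutions; ``entry`` the outputs of the
    entry downsampling blocks; ``exit_sep`` the two separable-convolution
    widths of the first exit block; ``exit_final`` those of the last block.
    Defaults are the public Xception widths.
    """

    stem: tuple[int, int] = (32, 64)
    entry: tuple[int, ...] = (128, 256, 728)
    middle: int = 728
    exit_sep: tuple[int, int] = (728, 1024)
    exit_final: tuple[int, int] = (1536, 2048)

    @staticmethod
    def small() -> "ChannelPlan":
        """Desk-scale widths for tests and smoke training runs."""
        return ChannelPlan(stem=(4, 8), entry=(8, 12, 16), middle=16,
                           exit_sep=(16, 16), exit_final=(24, 32))


@dataclass(frozen=True)
class BackboneConfig:
    input_side: int = 441
    flow_blocks: tuple[int, int, int] = (4, 8, 2)
    channel_plan: ChannelPlan = field(default_factory=ChannelPlan)
    num_classes: int = 2

    def __post_init__(self):
        if self.input_side < 64:
            raise ConfigError("input_side must be >= 64")
        e, m, x = self.flow_blocks
        if e < 2 or m < 1 or x != 2:
            raise ConfigError("flow_blocks must be (entry >= 2, middle >= 1, "
                              "exit == 2)")
        if len(self.channel_plan.entry) != e - 1:
            raise ConfigError("channel_plan.entry must list one width per "
                              "entry downsampling block")
        if self.num_classes < 2:
            raise ConfigError("num_classes must be >= 2")

    @property
    def total_blocks(self) -> int:
        return sum(self.flow_blocks)


@dataclass(frozen=True)
class AttentionConfig:
    """Where attention modules sit and how deep their mask branches go.

    ``downsample_counts`` of ``None`` derives each count from the local map
    side so that the coarsest internal map matches the network minimum.
    """

    positions: tuple[int, ...] = (2, 3, 12)
    downsample_counts: tuple[int, ...] | None = None
    mask_activation: str = "sigmoid"

    def __post_init__(self):
        if list(self.positions) != sorted(set(self.positions)):
            raise ConfigError("positions must be strictly increasing")
        if self.positions and not (1 <= self.positions[0]
                                   and self.positions[-1] <= TOTAL_BLOCKS):
            raise ConfigError(f"positions must lie in 1..{TOTAL_BLOCKS}")
        if self.downsample_counts is not None and \
                len(self.downsample_counts) != len(self.positions):
            raise ConfigError("downsample_counts must match positions")
        if self.mask_activation != "sigmoid":
            raise ConfigError("mask_activation is fixed to sigmoid")


# ---------------------------------------------------------------------------
# shape arithmetic


def _stem_side(side: int) -> int:
    for _ in range(2):  # two unpadded stride-2 3x3 convolutions
        side = (side - 3) // 2 + 1
    return side


def _halve(side: int) -> int:
    return (side + 1) // 2  # 3x3/stride-2/pad-1 pooling: ceil(side / 2)


def forward_shapes(cfg: BackboneConfig) -> list[int]:
    """Spatial side of each block's output, block 1 first."""
    side = _stem_side(cfg.input_side)
    sides = [side]
    for _ in range(cfg.flow_blocks[0] - 1):
        side = _halve(side)
        sides.append(side)
    sides += [side] * cfg.flow_blocks[1]
    side = _halve(side)
    sides += [side, side]
    if sides[-1] < 1 or sides[0] < 1:
        raise ConfigError(f"input_side {cfg.input_side} does not survive "
                          "all downsamplings")
    return sides


def _halvings_to(side: int, target: int) -> int:
    n = 0
    while side > target:
        side = _halve(side)
        n += 1
    if side != target:
        raise ConfigError(f"side chain does not reach {target}")
    return n


# ---------------------------------------------------------------------------
# blocks


class _Stem(nn.Module):
    def __init__(self, c0: int, c1: int):
        super().__init__()
        self.conv1 = nn.Conv2d(3, c0, 3, stride=2, padding=0, bias=False)
        self.bn1 = nn.BatchNorm2d(c0)
        self.conv2 = nn.Conv2d(c0, c1, 3, stride=2, padding=0, bias=False)
        self.bn2 = nn.BatchNorm2d(c1)

    def forward(self, x):
        x = F.relu(self.bn1(self.conv1(x)))
        return F.relu(self.bn2(self.conv2(x)))


class _DownsampleBlock(nn.Module):
    """Entry-flow/exit-flow block: two separable convs, ceil-mode pooling,
    and a stride-2 1x1-convolution residual shortcut."""

    def __init__(self, cin: int, cmid: int, cout: int, first_relu: bool):
        super().__init__()
        self.first_relu = first_relu
        self.sep1 = nn.SeparableConv2d(cin, cmid)
        self.bn1 = nn.BatchNorm2d(cmid)
        self.sep2 = nn.SeparableConv2d(cmid, cout)
        self.bn2 = nn.BatchNorm2d(cout)
        self.pool = nn.MaxPool2d(3, 2, 1)
        self.shortcut = nn.Conv2d(cin, cout, 1, stride=2, padding=0, bias=False)
        self.bn_sc = nn.BatchNorm2d(cout)

    def forward(self, x):
        h = F.relu(x) if self.first_relu else x
        h = F.relu(self.bn1(self.sep1(h)))
        h = self.pool(self.bn2(self.sep2(h)))
        return h + self.bn_sc(self.shortcut(x))


class _MiddleBlock(nn.Module):
    """Three separable convolutions with an identity shortcut; preserves
    both channel count and spatial size."""

    def __init__(self, channels: int):
        super().__init__()
        self.seps = nn.ModuleList(
            [nn.SeparableConv2d(channels, channels) for _ in range(3)])
        self.bns = nn.ModuleList(
            [nn.BatchNorm2d(channels) for _ in range(3)])

    def forward(self, x):
        h = x
        for sep, bn in zip(self.seps, self.bns):
            h = bn(sep(F.relu(h)))
        return h + x


class _FinalBlock(nn.Module):
    """Last block: two separable convolutions, no residual connection."""

    def __init__(self, cin: int, ca: int, cb: int):
        super().__init__()
        self.sep1 = nn.SeparableConv2d(cin, ca)
        self.bn1 = nn.BatchNorm2d(ca)
        self.sep2 = nn.SeparableConv2d(ca, cb)
        self.bn2 = nn.BatchNorm2d(cb)

    def forward(self, x):
        x = F.relu(self.bn1(self.sep1(x)))
        return F.relu(self.bn2(self.sep2(x)))


def block_channels(cfg: BackboneConfig) -> list[int]:
    """Output channel width of each block, block 1 first."""
    plan = cfg.channel_plan
    chans = [plan.stem[1]]
    chans += list(plan.entry)
    chans += [plan.middle] * cfg.flow_blocks[1]
    chans += [plan.exit_sep[1], plan.exit_final[1]]
    return chans


class XceptionBackbone(nn.Module):
    """14-module backbone with per-block outputs addressable by index."""

    def __init__(self, cfg: BackboneConfig):
        super().__init__()
        forward_shapes(cfg)  # validates input_side survives the chain
        self.cfg = cfg
        plan = cfg.channel_plan
        blocks: list[nn.Module] = [_Stem(*plan.stem)]
        cin = plan.stem[1]
        for i, cout in enumerate(plan.entry):
            blocks.append(_DownsampleBlock(cin, cout, cout, first_relu=i > 0))
            cin = cout
        if plan.middle != cin:
            raise ConfigError("middle width must equal the last entry width")
        for _ in range(cfg.flow_blocks[1]):
            blocks.append(_MiddleBlock(plan.middle))
        blocks.append(_DownsampleBlock(plan.middle, plan.exit_sep[0],
                                       plan.exit_sep[1], first_relu=True))
        blocks.append(_FinalBlock(plan.exit_sep[1], *plan.exit_final))
        self.blocks = nn.ModuleList(blocks)
        self.head = nn.Linear(plan.exit_final[1], cfg.num_classes)

    @property
    def input_side(self) -> int:
        return self.cfg.input_side

    def forward_blocks(self, x) -> tuple[list[Tensor], Tensor]:
        """Per-block outputs (index i is block i+1) and the class logits."""
        outs = []
        h = as_tensor(x)
        for block in self.blocks:
            h = block(h)
            outs.append(h)
        logits = self.head(F.global_avg_pool(h))
        return outs, logits

    def forward(self, x) -> Tensor:
        return self.forward_blocks(x)[1]


def build_backbone(cfg: BackboneConfig | None = None,
                   seed: int = 0) -> XceptionBackbone:
    net = XceptionBackbone(cfg or BackboneConfig())
    return nn.initialize_parameters(net, seed)


# ---------------------------------------------------------------------------
# residual attention


def attention_combine(trunk, mask):
    """H = (1 + M) * F, elementwise; M must lie in [0, 1]."""
    t, m = as_tensor(trunk), as_tensor(mask)
    if t.shape != m.shape:
        raise ValueError(f"shape mismatch: trunk {t.shape} vs mask {m.shape}")
    if m.data.min() < 0 or m.data.max() > 1:
        raise ValueError("mask values must lie in [0, 1]")
    out = (1.0 + m) * t
    if isinstance(trunk, Tensor) or isinstance(mask, Tensor):
        return out
    return out.data


class AttentionModule(nn.Module):
    """Residual attention: trunk = one middle-flow block; soft mask branch
    = ``n_down`` pool+block downsamplings mirrored by block+upsample steps
    (skip connections between matching scales), two 1x1 convolutions and a
    sigmoid.  Output shape equals input shape."""

    def __init__(self, channels: int, local_side: int, n_down: int):
        super().__init__()
        if n_down < 1:
            raise ConfigError("n_down must be >= 1")
        side = local_side
        for _ in range(n_down):
            if side < 2:
                raise ConfigError(
                    f"local side {local_side} cannot be halved {n_down} times")
            side = _halve(side)
        self.channels = channels
        self.local_side = local_side
        self.n_down = n_down
        self.trunk = _MiddleBlock(channels)
        self.down_blocks = nn.ModuleList(
            [_MiddleBlock(channels) for _ in range(n_down)])
        self.up_blocks = nn.ModuleList(
            [_MiddleBlock(channels) for _ in range(n_down)])
        self.skip_blocks = nn.ModuleList(
            [_MiddleBlock(channels) for _ in range(n_down - 1)])
        self.pool = nn.MaxPool2d(3, 2, 1)
        self.mask_bn1 = nn.BatchNorm2d(channels)
        self.mask_conv1 = nn.Conv2d(channels, channels, 1)
        self.mask_bn2 = nn.BatchNorm2d(channels)
        self.mask_conv2 = nn.Conv2d(channels, channels, 1)
        self._last_mask: np.ndarray | None = None

    @property
    def last_mask(self) -> np.ndarray | None:
        """Mask values from the most recent forward pass (inspection only)."""
        return self._last_mask

    def mask_and_trunk(self, x) -> tuple[Tensor, Tensor]:
        x = as_tensor(x)
        t = self.trunk(x)
        sizes = [x.shape[2:]]
        feats = []
        h = x
        for block in self.down_blocks:
            h = self.pool(h)
            h = block(h)
            feats.append(h)
            sizes.append(h.shape[2:])
        for i in range(self.n_down - 1, -1, -1):
            h = self.up_blocks[i](h)
            h = F.upsample_nearest(h, sizes[i])
            if i > 0:
                h = h + self.skip_blocks[i - 1](feats[i - 1])
        h = self.mask_conv1(F.relu(self.mask_bn1(h)))
        h = self.mask_conv2(F.relu(self.mask_bn2(h)))
        m = F.sigmoid(h)
        return m, t

    def forward(self, x) -> Tensor:
        m, t = self.mask_and_trunk(x)
        self._last_mask = m.data
        return (1.0 + m) * t


def build_attention_module(channels: int, local_side: int, n_down: int,
                           seed: int = 0) -> AttentionModule:
    module = AttentionModule(channels, local_side, n_down)
    return nn.initialize_parameters(module, seed)


def force_zero_mask(module: AttentionModule) -> AttentionModule:
    """Pin the soft mask at exactly zero (the Eq. H=(1+M)F degenerate case):
    with the final 1x1 convolution zeroed and a large negative bias the
    stable sigmoid underflows to 0.0, so the module output equals the
    trunk output bit for bit."""
    module.mask_conv2.weight.data[...] = 0.0
    module.mask_conv2.bias.data[...] = -1e4
    return module


class XceptionRA(nn.Module):
    """Backbone with residual attention modules inserted after the
    configured blocks."""

    def __init__(self, backbone: XceptionBackbone, attn_cfg: AttentionConfig):
        super().__init__()
        cfg = backbone.cfg
        if attn_cfg.positions and attn_cfg.positions[-1] > cfg.total_blocks:
            raise ConfigError("attention position beyond block count")
        sides = forward_shapes(cfg)
        chans = block_channels(cfg)
        min_side = min(sides)
        self.backbone = backbone
        self.attn_cfg = attn_cfg
        modules = []
        for k, pos in enumerate(attn_cfg.positions):
            local = sides[pos - 1]
            derived = max(1, _halvings_to(local, min_side))
            if attn_cfg.downsample_counts is not None:
                n_down = attn_cfg.downsample_counts[k]
                if n_down != derived:
                    raise ConfigError(
                        f"downsample count {n_down} at position {pos} does "
                        f"not take side {local} to the network minimum "
                        f"{min_side} (needs {derived})")
            else:
                n_down = derived
            modules.append(AttentionModule(chans[pos - 1], local, n_down))
        self.attention = nn.ModuleList(modules)

    @property
    def cfg(self) -> BackboneConfig:
        return self.backbone.cfg

    @property
    def input_side(self) -> int:
        return self.backbone.cfg.input_side

    def attention_at(self, position: int) -> AttentionModule:
        return self.attention[self.attn_cfg.positions.index(position)]

    def forward(self, x) -> Tensor:
        by_pos = dict(zip(self.attn_cfg.positions, self.attention))
        h = as_tensor(x)
        for i, block in enumerate(self.backbone.blocks, start=1):
            h = block(h)
            if i in by_pos:
                h = by_pos[i](h)
        return self.backbone.head(F.global_avg_pool(h))


def assemble_xception_ra(backbone_cfg: BackboneConfig | None = None,
                         attn_cfg: AttentionConfig | None = None,
                         seed: int = 0) -> XceptionRA:
    backbone_cfg = backbone_cfg or BackboneConfig()
    attn_cfg = attn_cfg if attn_cfg is not None else AttentionConfig()
    net = XceptionRA(XceptionBackbone(backbone_cfg), attn_cfg)
    return nn.initialize_parameters(net, seed)


def describe(net: XceptionRA | XceptionBackbone) -> dict:
    """JSON-able architecture summary: blocks, shapes, attention layout."""
    backbone = net.backbone if isinstance(net, XceptionRA) else net
    cfg = backbone.cfg
    sides = forward_shapes(cfg)
    chans = block_channels(cfg)
    e = cfg.flow_blocks[0]
    m = cfg.flow_blocks[1]
    flows = ["entry"] * e + ["middle"] * m + ["exit"] * cfg.flow_blocks[2]
    out = {
        "input_side": cfg.input_side,
        "num_classes": cfg.num_classes,
        "blocks": [
            {"index": i + 1, "flow": flows[i], "out_channels": chans[i],
             "out_side": sides[i]}
            for i in range(cfg.total_blocks)
        ],
        "attention": [],
    }
    if isinstance(net, XceptionRA):
        out["attention"] = [
            {"position": pos, "channels": mod.channels,
             "local_side": mod.local_side, "n_down": mod.n_down}
            for pos, mod in zip(net.attn_cfg.positions, net.attention)
        ]
    return out


def mask_gradient_property(module: AttentionModule, probe_input,
                           n_params: int = 10, h: float = 1e-5,
                           seed: int = 0) -> dict:
    """Finite-difference check of the mask-as-gradient-filter identity.

    Because the soft mask M(x) does not depend on the trunk parameters phi,
    the gradient of the masked product M*T with respect to phi must equal M
    times the trunk gradient.  For sampled trunk parameters this compares a
    central difference of ``sum(R * M * T)`` (mask recomputed each time)
    against the autograd gradient of the same projection with the mask
    frozen at its unperturbed value; agreement verifies both the structural
    independence and the trunk gradients themselves.
    """
    rng = np.random.default_rng(seed)
    module.eval()
    x = as_tensor(probe_input).detach()
    m0, _ = module.mask_and_trunk(x)
    proj = rng.normal(size=m0.shape)
    weight = Tensor(proj * m0.data)  # R * M, held constant

    module.zero_grad()
    trunk_params = list(module.trunk.parameters())
    t = module.trunk(x)
    (weight * t).sum().backward()
    analytic = [p.grad.copy() if p.grad is not None else np.zeros_like(p.data)
                for p in trunk_params]

    def objective() -> float:
        m, tt = module.mask_and_trunk(x)
        return float((proj * m.data * tt.data).sum())

    max_rel = 0.0
    checked = 0
    candidates = [(i, p) for i, p in enumerate(trunk_params) if p.data.size]
    for _ in range(n_params):
        i, p = candidates[rng.integers(len(candidates))]
        flat = rng.integers(p.data.size)
        idx = np.unravel_index(flat, p.data.shape)
        orig = p.data[idx]
        p.data[idx] = orig + h
        fp = objective()
        p.data[idx] = orig - h
        fm = objective()
        p.data[idx] = orig
        numeric = (fp - fm) / (2 * h)
        denom = max(abs(numeric), abs(analytic[i][idx]), 1e-8)
        max_rel = max(max_rel, abs(numeric - analytic[i][idx]) / denom)
        checked += 1
    return {"max_relative_error": max_rel, "n_checked": checked}
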