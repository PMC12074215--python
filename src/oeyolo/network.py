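"""Model construction: EfficientNetV2 backbone, dynamic convolution,
C3k2_DConv feature blocks, and the assembled OE-YOLO oriented-box detector.

Architecture overview
---------------------
The backbone follows the EfficientNetV2-S stage table (stem conv, two
Fused-MBConv stages, one more Fused-MBConv stage, then three MBConv stages
with squeeze-and-excitation), taps the stride-8/16/32 stage outputs and
feeds them into a PAN-style neck (SPPF + C2PSA on the deepest tap, top-down
and bottom-up fusion).  The three head branches use C3k2 blocks whose
bottleneck convolutions may be replaced by *dynamic convolution*: a bank of
K parallel kernels fused per input by a softmax-gated attention vector

    W(x) = sum_k pi_k(x) W_k,   b(x) = sum_k pi_k(x) b_k,
    pi(x) = softmax(MLP(global_avg_pool(x)) / temperature),

so the effective kernel adapts to the input while the cost stays that of a
single convolution plus a tiny MLP.  Each detection branch predicts class
scores, discretized box-side distributions (``reg_max`` bins per side,
decoded by expectation) and one angle channel mapped to [-pi/2, pi/2) by a
sigmoid-affine transform.

Default multipliers (backbone width 0.25 / depth 0.5, neck width 0.25) are
calibrated so that the fully assembled default detector has ~2.45 M
trainable parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from oeyolo import nn
from oeyolo.nn import Tensor

__all__ = [
    "StageSpec",
    "BackboneSpec",
    "ModelConfig",
    "KernelBank",
    "GateParams",
    "gate_weights",
    "dynamic_conv",
    "make_divisible",
    "build_backbone",
    "build_oe_yolo",
    "model_complexity",
    "EfficientNetV2Backbone",
    "OEYOLO",
    "DynamicConv2d",
]


def make_divisible(value: float, divisor: int = 8) -> int:
    """Round channel counts to a multiple of ``divisor`` (min one divisor)."""
    out = max(divisor, int(value + divisor / 2) // divisor * divisor)
    if out < 0.9 * value:  # never round down by more than 10%
        out += divisor
    return out


# ---------------------------------------------------------------------------
# backbone specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StageSpec:
    """One backbone stage: operator, expansion, channels, stride, repeats."""

    operator: str  # "conv" | "fused_mbconv" | "mbconv"
    expansion: float
    channels: int
    stride: int
    layers: int
    se_ratio: float = 0.0


# EfficientNetV2-S trunk (classifier head stage omitted for detection use)
_EFFNETV2_S_STAGES: Tuple[StageSpec, ...] = (
    StageSpec("conv", 1.0, 24, 2, 1),
    StageSpec("fused_mbconv", 1.0, 24, 1, 2),
    StageSpec("fused_mbconv", 4.0, 48, 2, 4),
    StageSpec("fused_mbconv", 4.0, 64, 2, 4),
    StageSpec("mbconv", 4.0, 128, 2, 6, 0.25),
    StageSpec("mbconv", 6.0, 160, 1, 9, 0.25),
    StageSpec("mbconv", 6.0, 256, 2, 15, 0.25),
)


@dataclass(frozen=True)
class BackboneSpec:
    """EfficientNetV2 trunk description with width/depth scaling."""

    stages: Tuple[StageSpec, ...] = _EFFNETV2_S_STAGES
    width_mult: float = 1.0
    depth_mult: float = 1.0
    stochastic_depth: float = 0.1  # max drop rate, linearly ramped over blocks

    def scaled_channels(self, stage: int) -> int:
        return make_divisible(self.stages[stage].channels * self.width_mult)

    def scaled_layers(self, stage: int) -> int:
        if self.stages[stage].operator == "conv":
            return self.stages[stage].layers
        return max(1, int(math.ceil(self.stages[stage].layers * self.depth_mult)))

    def validate(self) -> None:
        for s in self.stages:
            if s.stride not in (1, 2):
                raise ValueError(f"stage stride must be 1 or 2, got {s.stride}")
            if s.layers < 1:
                raise ValueError("stage layer count must be >= 1")


# ---------------------------------------------------------------------------
# dynamic convolution (functional form on plain arrays)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KernelBank:
    """K parallel kernels (K, C_out, C_in, k, k) and biases (K, C_out)."""

    weights: np.ndarray
    biases: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=np.float32)
        b = np.asarray(self.biases, dtype=np.float32)
        if w.ndim != 5 or w.shape[0] < 2:
            raise ValueError("kernel bank needs K >= 2 kernels of shape (Cout, Cin, k, k)")
        if b.shape != w.shape[:2]:
            raise ValueError("bias bank shape must be (K, Cout)")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "biases", b)

    @property
    def K(self) -> int:
        return self.weights.shape[0]


@dataclass(frozen=True)
class GateParams:
    """Gating MLP: pooled (C,) -> hidden (C1,) -> logits (K,), softmax(T)."""

    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    temperature: float = 1.0

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        for name in ("W1", "b1", "W2", "b2"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=np.float64))
        if self.W1.shape[0] != self.b1.shape[0] or self.W2.shape[0] != self.b2.shape[0]:
            raise ValueError("gate weight/bias shapes inconsistent")
        if self.W2.shape[1] != self.W1.shape[0]:
            raise ValueError("gate hidden dimensions inconsistent")


def gate_weights(x: np.ndarray, g: GateParams, K: int) -> np.ndarray:
    """Attention weights of the dynamic-convolution gate for one feature map.

    ``x`` is (C, H, W); output is a length-K probability vector:
    global average pool -> ReLU MLP -> softmax of logits / temperature.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 3:
        raise ValueError("feature map must be (C, H, W)")
    if g.W1.shape[1] != x.shape[0]:
        raise ValueError(f"gate expects {g.W1.shape[1]} channels, got {x.shape[0]}")
    if g.W2.shape[0] != K:
        raise ValueError(f"gate produces {g.W2.shape[0]} logits, expected K={K}")
    pooled = x.mean(axis=(1, 2))
    h = np.maximum(g.W1 @ pooled + g.b1, 0.0)
    z = (g.W2 @ h + g.b2) / g.temperature
    z = z - z.max()
    e = np.exp(z)
    return e / e.sum()


def dynamic_conv(x: np.ndarray, bank: KernelBank, g: GateParams) -> np.ndarray:
    """Dynamic convolution of one feature map (C, H, W), stride 1, same pad.

    The kernel bank is fused by the gate's attention weights before a single
    convolution; by linearity this equals the attention-weighted sum of the
    K individual convolution outputs.
    """
    x = np.asarray(x, dtype=np.float32)
    if bank.weights.shape[2] != x.shape[0]:
        raise ValueError(
            f"kernel bank expects {bank.weights.shape[2]} input channels, got {x.shape[0]}"
        )
    pi = gate_weights(x, g, bank.K).astype(np.float32)
    w = np.tensordot(pi, bank.weights, axes=(0, 0))  # (Cout, Cin, k, k)
    b = pi @ bank.biases  # (Cout,)
    out = nn.conv2d(Tensor(x[None]), Tensor(w), Tensor(b), stride=1)
    return out.data[0]


# ---------------------------------------------------------------------------
# building blocks (modules)
# ---------------------------------------------------------------------------

class ConvBNAct(nn.Module):
    def __init__(self, cin: int, cout: int, k: int = 1, stride: int = 1, groups: int = 1,
                 act: bool = True):
        super().__init__()
        self.conv = nn.Conv2d(cin, cout, k, stride=stride, groups=groups, bias=False)
        self.bn = nn.BatchNorm2d(cout)
        self.act = nn.SiLU() if act else nn.Identity()

    def forward(self, x: Tensor) -> Tensor:
        return self.act(self.bn(self.conv(x)))


class SqueezeExcite(nn.Module):
    """Channel recalibration from globally pooled statistics."""

    def __init__(self, channels: int, se_channels: int):
        super().__init__()
        self.reduce = nn.Conv2d(channels, se_channels, 1)
        self.expand = nn.Conv2d(se_channels, channels, 1)

    def forward(self, x: Tensor) -> Tensor:
        s = x.mean(axis=(2, 3), keepdims=True)
        s = self.expand(self.reduce(s).silu()).sigmoid()
        return x * s


class StochasticDepth(nn.Module):
    """Randomly bypasses its residual branch during training (drop-path)."""

    def __init__(self, drop_rate: float):
        super().__init__()
        self.drop_rate = drop_rate

    def forward(self, branch: Tensor, identity: Tensor) -> Tensor:
        if self.training and self.drop_rate > 0.0:
            if nn.get_rng().random() < self.drop_rate:
                return identity
            return identity + branch * (1.0 / (1.0 - self.drop_rate))
        return identity + branch


class FusedMBConv(nn.Module):
    """Fused inverted residual: one 3x3 standard conv (+1x1 project when
    expanded), residual with stochastic depth at stride 1 / equal channels."""

    def __init__(self, cin: int, cout: int, stride: int, expansion: float, sd_rate: float):
        super().__init__()
        mid = make_divisible(cin * expansion) if expansion != 1.0 else cin
        self.expanded = expansion != 1.0
        if self.expanded:
            self.fused = ConvBNAct(cin, mid, 3, stride)
            self.project = ConvBNAct(mid, cout, 1, act=False)
        else:
            self.fused = ConvBNAct(cin, cout, 3, stride)
            self.project = nn.Identity()
        self.residual = stride == 1 and cin == cout
        self.sd = StochasticDepth(sd_rate)

    def forward(self, x: Tensor) -> Tensor:
        y = self.project(self.fused(x))
        return self.sd(y, x) if self.residual else y


class MBConv(nn.Module):
    """Inverted residual: 1x1 expand -> 3x3 depthwise -> SE -> 1x1 project."""

    def __init__(self, cin: int, cout: int, stride: int, expansion: float,
                 se_ratio: float, sd_rate: float):
        super().__init__()
        mid = make_divisible(cin * expansion)
        self.expand = ConvBNAct(cin, mid, 1)
        self.dw = ConvBNAct(mid, mid, 3, stride, groups=mid)
        self.se = (
            SqueezeExcite(mid, max(1, int(cin * se_ratio))) if se_ratio > 0 else nn.Identity()
        )
        self.project = ConvBNAct(mid, cout, 1, act=False)
        self.residual = stride == 1 and cin == cout
        self.sd = StochasticDepth(sd_rate)

    def forward(self, x: Tensor) -> Tensor:
        y = self.project(self.se(self.dw(self.expand(x))))
        return self.sd(y, x) if self.residual else y


class EfficientNetV2Backbone(nn.Module):
    """Scaled EfficientNetV2 trunk returning the tapped pyramid levels."""

    def __init__(self, spec: BackboneSpec, tap_stages: Tuple[int, ...] = (3, 5, 6),
                 in_channels: int = 3):
        super().__init__()
        spec.validate()
        self.spec = spec
        self.tap_stages = tuple(tap_stages)
        total_blocks = sum(spec.scaled_layers(i) for i in range(1, len(spec.stages)))
        block_idx = 0
        stages: List[nn.Module] = []
        cin = in_channels
        for si, stage in enumerate(spec.stages):
            cout = spec.scaled_channels(si)
            blocks: List[nn.Module] = []
            if stage.operator == "conv":
                blocks.append(ConvBNAct(cin, cout, 3, stage.stride))
            else:
                for li in range(spec.scaled_layers(si)):
                    stride = stage.stride if li == 0 else 1
                    sd = spec.stochastic_depth * block_idx / max(1, total_blocks - 1)
                    if stage.operator == "fused_mbconv":
                        blocks.append(FusedMBConv(cin if li == 0 else cout, cout, stride,
                                                  stage.expansion, sd))
                    elif stage.operator == "mbconv":
                        blocks.append(MBConv(cin if li == 0 else cout, cout, stride,
                                             stage.expansion, stage.se_ratio, sd))
                    else:
                        raise ValueError(f"unknown operator {stage.operator!r}")
                    block_idx += 1
            stages.append(nn.Sequential(*blocks))
            cin = cout
        self.stages = nn.ModuleList(stages)

    @property
    def tap_channels(self) -> Tuple[int, ...]:
        return tuple(self.spec.scaled_channels(i) for i in self.tap_stages)

    @property
    def tap_strides(self) -> Tuple[int, ...]:
        strides = []
        prod = 1
        for si, stage in enumerate(self.spec.stages):
            prod *= stage.stride
            if si in self.tap_stages:
                strides.append(prod)
        return tuple(strides)

    def forward(self, x: Tensor) -> List[Tensor]:
        taps = []
        for si, stage in enumerate(self.stages):
            x = stage(x)
            if si in self.tap_stages:
                taps.append(x)
        return taps


class DynamicConv2d(nn.Module):
    """Convolution whose kernel is an input-conditioned convex combination of
    K learned kernels (softmax-gated, temperature-annealed)."""

    def __init__(self, cin: int, cout: int, k: int = 3, K: int = 4, stride: int = 1,
                 temperature: float = 1.0):
        super().__init__()
        self.K = K
        self.cin, self.cout, self.k, self.stride = cin, cout, k, stride
        self.temperature = temperature
        rng = nn.get_rng()
        std = float(np.sqrt(2.0 / (cin * k * k)))
        self.weight = Tensor(rng.normal(0.0, std, (K, cout, cin, k, k)), requires_grad=True)
        self.bias = Tensor(np.zeros((K, cout)), requires_grad=True)
        hidden = max(cin // 4, 4)
        self.gate_fc1 = nn.Linear(cin, hidden)
        self.gate_fc2 = nn.Linear(hidden, K)

    def gates(self, x: Tensor) -> Tensor:
        pooled = x.mean(axis=(2, 3))  # (N, C)
        z = self.gate_fc2(self.gate_fc1(pooled).relu())
        return (z * (1.0 / self.temperature)).softmax(axis=-1)  # (N, K)

    def forward(self, x: Tensor) -> Tensor:
        n = x.shape[0]
        pi = self.gates(x)  # (N, K)
        # one convolution with all K kernels stacked, then gate-weighted sum
        wk = self.weight.reshape(self.K * self.cout, self.cin, self.k, self.k)
        out = nn.conv2d(x, wk, None, stride=self.stride)  # (N, K*Cout, H, W)
        oh, ow = out.shape[2], out.shape[3]
        out = out.reshape(n, self.K, self.cout, oh, ow)
        out = (out * pi.reshape(n, self.K, 1, 1, 1)).sum(axis=1)
        b = pi @ self.bias  # (N, Cout)
        return out + b.reshape(n, self.cout, 1, 1)


class DynamicConvBNAct(nn.Module):
    def __init__(self, cin: int, cout: int, k: int = 3, K: int = 4):
        super().__init__()
        self.conv = DynamicConv2d(cin, cout, k, K)
        self.bn = nn.BatchNorm2d(cout)

    def forward(self, x: Tensor) -> Tensor:
        return self.bn(self.conv(x)).silu()


class Bottleneck(nn.Module):
    """Paired 3x3 convolutions with an optional residual; the refinement conv
    becomes dynamic in the C3k2_DConv variant."""

    def __init__(self, c: int, shortcut: bool = True, dconv: bool = False, K: int = 4):
        super().__init__()
        self.cv1 = ConvBNAct(c, c, 3)
        self.cv2 = DynamicConvBNAct(c, c, 3, K) if dconv else ConvBNAct(c, c, 3)
        self.shortcut = shortcut

    def forward(self, x: Tensor) -> Tensor:
        y = self.cv2(self.cv1(x))
        return x + y if self.shortcut else y


class C3k2(nn.Module):
    """Cross-stage partial block of paired small convolutions (C3k2); with
    ``dconv=True`` the bottleneck refinement convs are dynamic (C3k2_DConv)."""

    def __init__(self, cin: int, cout: int, n: int = 1, dconv: bool = False, K: int = 4,
                 shortcut: bool = True):
        super().__init__()
        self.hidden = cout // 2
        self.cv1 = ConvBNAct(cin, 2 * self.hidden, 1)
        self.blocks = nn.ModuleList(
            [Bottleneck(self.hidden, shortcut, dconv, K) for _ in range(n)]
        )
        self.cv2 = ConvBNAct((2 + n) * self.hidden, cout, 1)
        self.dconv = dconv

    def forward(self, x: Tensor) -> Tensor:
        y = self.cv1(x)
        y1 = y[:, : self.hidden]
        y2 = y[:, self.hidden :]
        ys = [y1, y2]
        for b in self.blocks:
            ys.append(b(ys[-1]))
        return self.cv2(nn.concat(ys, axis=1))


class SPPF(nn.Module):
    """Spatial pyramid pooling (fast): three cascaded 5x5 max pools."""

    def __init__(self, c: int):
        super().__init__()
        self.cv1 = ConvBNAct(c, c // 2, 1)
        self.cv2 = ConvBNAct(2 * c, c, 1)

    def forward(self, x: Tensor) -> Tensor:
        y = self.cv1(x)
        p1 = nn.maxpool2d(y, 5)
        p2 = nn.maxpool2d(p1, 5)
        p3 = nn.maxpool2d(p2, 5)
        return self.cv2(nn.concat([y, p1, p2, p3], axis=1))


class _PSABlock(nn.Module):
    """Single-head spatial self-attention + pointwise FFN, both residual."""

    def __init__(self, c: int):
        super().__init__()
        self.qk_dim = max(c // 2, 8)
        self.q = nn.Conv2d(c, self.qk_dim, 1, bias=False)
        self.k = nn.Conv2d(c, self.qk_dim, 1, bias=False)
        self.v = nn.Conv2d(c, c, 1, bias=False)
        self.proj = nn.Conv2d(c, c, 1, bias=False)
        self.ffn = nn.Sequential(ConvBNAct(c, c * 2, 1), ConvBNAct(c * 2, c, 1, act=False))

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        q = self.q(x).reshape(n, self.qk_dim, h * w).transpose(0, 2, 1)
        k = self.k(x).reshape(n, self.qk_dim, h * w)
        v = self.v(x).reshape(n, c, h * w).transpose(0, 2, 1)
        attn = ((q @ k) * (1.0 / math.sqrt(self.qk_dim))).softmax(axis=-1)
        y = (attn @ v).transpose(0, 2, 1).reshape(n, c, h, w)
        x = x + self.proj(y)
        return x + self.ffn(x)


class C2PSA(nn.Module):
    """Cross-stage partial wrapper around spatial self-attention."""

    def __init__(self, c: int, n: int = 1):
        super().__init__()
        self.hidden = c // 2
        self.cv1 = ConvBNAct(c, 2 * self.hidden, 1)
        self.attn = nn.Sequential(*[_PSABlock(self.hidden) for _ in range(n)])
        self.cv2 = ConvBNAct(2 * self.hidden, c, 1)

    def forward(self, x: Tensor) -> Tensor:
        y = self.cv1(x)
        a = y[:, : self.hidden]
        b = self.attn(y[:, self.hidden :])
        return self.cv2(nn.concat([a, b], axis=1))


# ---------------------------------------------------------------------------
# model configuration and assembly
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the assembled detector.

    Defaults reproduce the reference configuration: EfficientNetV2-S trunk at
    width 0.25 / depth 0.5, PAN neck at matching width, K = 4 dynamic kernels
    and C3k2_DConv in all three head branches, one class, distributional box
    regression with ``reg_max`` = 16 bins.
    """

    backbone: BackboneSpec = field(
        default_factory=lambda: BackboneSpec(width_mult=0.25, depth_mult=0.5)
    )
    tap_stages: Tuple[int, int, int] = (3, 5, 6)
    K: int = 4
    head_dconv: Tuple[bool, bool, bool] = (True, True, True)  # 80x80 / 40x40 / 20x20
    num_classes: int = 1
    neck_channels: Tuple[int, int, int] = (48, 96, 188)  # P3 / P4 / P5, calibrated
    neck_depth: int = 1
    reg_max: int = 16
    box_regression: str = "dfl"  # "dfl" | "direct"
    box_weight: float = 7.5
    cls_weight: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if len(self.tap_stages) != 3 or len(self.head_dconv) != 3:
            raise ValueError("exactly three pyramid levels are expected")
        if self.box_regression not in ("dfl", "direct"):
            raise ValueError("box_regression must be 'dfl' or 'direct'")
        if self.K < 2:
            raise ValueError("dynamic convolution needs K >= 2 kernels")


class DetectHead(nn.Module):
    """Decoupled per-level head: box distribution, class scores, angle."""

    def __init__(self, cin: int, num_classes: int, reg_max: int, direct: bool):
        super().__init__()
        self.reg_max = reg_max
        self.direct = direct
        box_out = 4 if direct else 4 * reg_max
        c_mid = max(cin // 2, 16)
        self.box = nn.Sequential(
            ConvBNAct(cin, c_mid, 3), ConvBNAct(c_mid, c_mid, 3), nn.Conv2d(c_mid, box_out, 1)
        )
        self.cls = nn.Sequential(
            ConvBNAct(cin, c_mid, 3), ConvBNAct(c_mid, c_mid, 3), nn.Conv2d(c_mid, num_classes, 1)
        )
        self.angle = nn.Sequential(ConvBNAct(cin, c_mid, 3), nn.Conv2d(c_mid, 1, 1))
        # priors: background-heavy classification (p0 ~ 1%), and side-distance
        # distributions biased toward a slender box (long l/r, short t/b)
        self.cls.layers[-1].bias.data[:] = -4.6
        if not direct:
            bias = self.box.layers[-1].bias.data.reshape(4, reg_max)
            bins = np.arange(reg_max, dtype=np.float32)
            bias[0] = bias[2] = -0.25 * np.abs(bins - 3.0)  # l, r: ~2-3 cells
            bias[1] = bias[3] = -0.8 * bins  # t, b: well under one cell

    def forward(self, x: Tensor) -> Tuple[Tensor, Tensor, Tensor]:
        return self.box(x), self.cls(x), self.angle(x)


class OEYOLO(nn.Module):
    """Oriented-box detector: EfficientNetV2 trunk, PAN neck with SPPF and
    C2PSA, three decoupled heads with optional dynamic-conv feature blocks."""

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        cfg.validate()
        nn.manual_seed(cfg.seed)
        self.cfg = cfg
        self.backbone = EfficientNetV2Backbone(cfg.backbone, cfg.tap_stages)
        c3b, c4b, c5b = self.backbone.tap_channels
        c3, c4, c5 = cfg.neck_channels
        n, K = cfg.neck_depth, cfg.K

        self.sppf = SPPF(c5b)
        self.psa = C2PSA(c5b, n)
        self.reduce5 = ConvBNAct(c5b, c5, 1)

        # top-down
        self.td4 = C3k2(c5 + c4b, c4, n, shortcut=False)
        self.head3 = C3k2(c4 + c3b, c3, n, dconv=cfg.head_dconv[0], K=K, shortcut=False)
        # bottom-up
        self.down3 = ConvBNAct(c3, c3, 3, 2)
        self.head4 = C3k2(c3 + c4, c4, n, dconv=cfg.head_dconv[1], K=K, shortcut=False)
        self.down4 = ConvBNAct(c4, c4, 3, 2)
        self.head5 = C3k2(c4 + c5, c5, n, dconv=cfg.head_dconv[2], K=K, shortcut=False)

        direct = cfg.box_regression == "direct"
        self.detect = nn.ModuleList(
            [
                DetectHead(c3, cfg.num_classes, cfg.reg_max, direct),
                DetectHead(c4, cfg.num_classes, cfg.reg_max, direct),
                DetectHead(c5, cfg.num_classes, cfg.reg_max, direct),
            ]
        )
        self.strides = self.backbone.tap_strides

    def forward(self, x: Tensor) -> List[Tuple[Tensor, Tensor, Tensor]]:
        """Returns per level (box, cls, angle) raw maps, strides 8/16/32."""
        t3, t4, t5 = self.backbone(x)
        p5 = self.reduce5(self.psa(self.sppf(t5)))
        u4 = nn.concat([nn.upsample_nearest2x(p5), t4], axis=1)
        p4 = self.td4(u4)
        u3 = nn.concat([nn.upsample_nearest2x(p4), t3], axis=1)
        f3 = self.head3(u3)
        f4 = self.head4(nn.concat([self.down3(f3), p4], axis=1))
        f5 = self.head5(nn.concat([self.down4(f4), p5], axis=1))
        return [self.detect[0](f3), self.detect[1](f4), self.detect[2](f5)]

    def set_gate_temperature(self, t: float) -> None:
        for m in self.modules():
            if isinstance(m, DynamicConv2d):
                m.temperature = t

    def count_dynamic_blocks(self) -> int:
        return sum(1 for m in self.modules() if isinstance(m, DynamicConv2d))


def build_backbone(spec: Optional[BackboneSpec] = None,
                   tap_stages: Tuple[int, ...] = (3, 5, 6)) -> EfficientNetV2Backbone:
    """Construct the EfficientNetV2 trunk (defaults to the V2-S table)."""
    return EfficientNetV2Backbone(spec or BackboneSpec(), tap_stages)


def build_oe_yolo(cfg: Optional[ModelConfig] = None) -> OEYOLO:
    """Construct the assembled detector (defaults ~2.45 M parameters)."""
    return OEYOLO(cfg or ModelConfig())


def model_complexity(model: nn.Module, input_size: int = 608) -> Tuple[int, int]:
    """(trainable parameter count, FLOPs of one forward pass).

    FLOPs count one multiply-accumulate as 2 operations over convolutions,
    linear maps and attention matmuls at the given square input size.
    """
    params = model.num_parameters()
    was_training = model.training
    model.eval()
    x = Tensor(np.zeros((1, 3, input_size, input_size), dtype=np.float32))
    with nn.count_flops() as counter:
        model(x)
    if was_training:
        model.train()
    return params, counter[0]
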