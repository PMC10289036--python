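"""Neural building blocks of the detector.

The detector combines a lightweight convolutional block attention module
("Little-CBAM": 1-D-kernel channel attention instead of a fully connected
bottleneck, and a 3x3 dilation-2 convolution instead of CBAM's 7x7 spatial
convolution), a multi-scale squeeze-excitation gate ("MSSENet": 3/5/7
convolution fusion, dual global average/max pooling with shared FC layers
and Mish activation), MobileNetV3 inverted-residual bottlenecks carrying the
attention block, and CSP-style wrappers (C3Mobile for the detector, plain
C3/SPPF for the reference YOLOv5 baseline).

All blocks preserve the (N, C, H, W) shape of their input and operate on
either real tensors or profiling shadows.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import nn
from .nn import functional as F
from .nn import ConvBnAct, Conv1d, Conv2d, Linear, MaxPool2d, Module, Sequential

__all__ = [
    "separable_param_ratio", "standard_conv_weights", "separable_conv_weights",
    "LittleCBAM", "CBAM", "SENet", "MSSENet",
    "BlockSpec", "MobileNetV3Bottleneck", "C3Mobile",
    "Bottleneck", "C3", "SPPF",
]


def standard_conv_weights(d_in: int, d_out: int, k: int) -> int:
    """Weight count of a bias-free standard k x k convolution."""
    return d_in * k * k * d_out


def separable_conv_weights(d_in: int, d_out: int, k: int) -> int:
    """Weight count of a bias-free depthwise (k x k) + pointwise (1 x 1) pair."""
    return d_in * k * k + d_in * d_out


def separable_param_ratio(d_in: int, d_out: int, k: int) -> float:
    """Parameter ratio of a depthwise-separable vs. a standard convolution.

    (D_in k^2 + D_in D_out) / (D_in k^2 D_out) = 1/D_out + 1/k^2 — the
    saving that motivates the MobileNet-style backbone.
    """
    if d_in <= 0 or d_out <= 0 or k <= 0:
        raise ValueError("dimensions must be positive")
    return 1.0 / d_out + 1.0 / (k * k)


class LittleCBAM(Module):
    """Lightweight channel+spatial attention.

    Channel stage: global average- and max-pooled channel descriptors pass
    through one *shared* 1-D convolution (kernel ``k1d``) across the channel
    axis, are summed and squashed by a sigmoid into a per-channel gate.
    Spatial stage: channel-wise mean and max maps are concatenated and passed
    through a 3x3 convolution with dilation ``dilation`` (18 weights for the
    2->1 map, vs. 98 for CBAM's 7x7 — a 9/49 reduction), sigmoid-gated.
    """

    def __init__(self, channels: int, k1d: int = 3, dilation: int = 2):
        super().__init__()
        if channels < 1:
            raise ValueError("channels must be >= 1")
        if k1d % 2 == 0:
            raise ValueError("k1d must be odd")
        self.channel_conv = Conv1d(1, 1, k1d, bias=False)
        self.spatial_conv = Conv2d(2, 1, 3, padding=dilation, dilation=dilation, bias=False)

    def channel_gate(self, x):
        n, c = x.shape[:2]
        avg = F.global_avg_pool(x).reshape(n, 1, c)
        mx = F.global_max_pool(x).reshape(n, 1, c)
        logits = self.channel_conv(avg) + self.channel_conv(mx)
        return logits.sigmoid().reshape(n, c, 1, 1)

    def spatial_gate(self, x):
        pooled = nn.concat([F.channel_mean(x), F.channel_max(x)], axis=1)
        return self.spatial_conv(pooled).sigmoid()

    def forward(self, x):
        x = x * self.channel_gate(x)
        return x * self.spatial_gate(x)


class CBAM(Module):
    """Standard convolutional block attention (ablation baseline).

    Channel stage uses a shared two-layer FC bottleneck with reduction ``r``;
    spatial stage a 7x7 convolution on the concatenated mean/max maps.
    """

    def __init__(self, channels: int, reduction: int = 16):
        super().__init__()
        if channels % reduction:
            raise ValueError("channels must be divisible by reduction")
        self.fc1 = Linear(channels, channels // reduction, bias=False)
        self.fc2 = Linear(channels // reduction, channels, bias=False)
        self.spatial_conv = Conv2d(2, 1, 7, padding=3, bias=False)

    def _mlp(self, v):
        return self.fc2(self.fc1(v).relu())

    def channel_gate(self, x):
        n, c = x.shape[:2]
        avg = F.global_avg_pool(x).reshape(n, c)
        mx = F.global_max_pool(x).reshape(n, c)
        return (self._mlp(avg) + self._mlp(mx)).sigmoid().reshape(n, c, 1, 1)

    def spatial_gate(self, x):
        pooled = nn.concat([F.channel_mean(x), F.channel_max(x)], axis=1)
        return self.spatial_conv(pooled).sigmoid()

    def forward(self, x):
        x = x * self.channel_gate(x)
        return x * self.spatial_gate(x)


class SENet(Module):
    """Plain squeeze-and-excitation gate (reference for MSSENet tests)."""

    def __init__(self, channels: int, reduction: int = 16, act: str = "relu"):
        super().__init__()
        if channels % reduction:
            raise ValueError("channels must be divisible by reduction")
        self.fc1 = Linear(channels, channels // reduction)
        self.fc2 = Linear(channels // reduction, channels)
        self._act = nn.ACTIVATIONS[act]

    def gate(self, x):
        n, c = x.shape[:2]
        v = F.global_avg_pool(x).reshape(n, c)
        return self.fc2(self._act(self.fc1(v))).sigmoid().reshape(n, c, 1, 1)

    def forward(self, x):
        return x * self.gate(x)


class MSSENet(Module):
    """Multi-scale squeeze-excitation channel attention.

    X_c = (V_3x3 + V_5x5 + V_7x7)(X): a sum of channel-preserving 3/5/7
    convolutions fuses resolution and semantic context.  X_c is squeezed by
    *both* global average and global max pooling; the two descriptors pass
    through shared FC layers (Mish after the reduction layer), are summed
    and sigmoid-normalised into the channel gate, which rescales X_c.
    The max-pool branch keeps responses from small, localised features that
    the average branch washes out.
    """

    def __init__(self, channels: int, reduction: int = 16):
        super().__init__()
        if channels % reduction:
            raise ValueError("channels must be divisible by reduction")
        self.conv3 = Conv2d(channels, channels, 3, padding=1, bias=False)
        self.conv5 = Conv2d(channels, channels, 5, padding=2, bias=False)
        self.conv7 = Conv2d(channels, channels, 7, padding=3, bias=False)
        self.fc1 = Linear(channels, channels // reduction)
        self.fc2 = Linear(channels // reduction, channels)

    def multi_scale(self, x):
        return self.conv3(x) + self.conv5(x) + self.conv7(x)

    def gate(self, xc):
        n, c = xc.shape[:2]
        avg = F.global_avg_pool(xc).reshape(n, c)
        mx = F.global_max_pool(xc).reshape(n, c)
        xa = self.fc2(self.fc1(avg).mish())
        xm = self.fc2(self.fc1(mx).mish())
        return (xa + xm).sigmoid().reshape(n, c, 1, 1)

    def forward(self, x):
        xc = self.multi_scale(x)
        return xc * self.gate(xc)


@dataclass
class BlockSpec:
    """Configuration of one MobileNetV3 bottleneck."""

    in_channels: int
    out_channels: int
    expansion_channels: int
    stride: int = 1
    kernel: int = 3
    use_little_cbam: bool = True
    activation: str = "hswish"

    def __post_init__(self):
        if min(self.in_channels, self.out_channels, self.expansion_channels) < 1:
            raise ValueError("channels must be >= 1")
        if self.stride not in (1, 2):
            raise ValueError("stride must be 1 or 2")


class MobileNetV3Bottleneck(Module):
    """Inverted residual: 1x1 expand -> [Little-CBAM] -> depthwise k x k -> 1x1 project.

    The attention block sits immediately after the channel expansion, where
    the feature space is widest and a channel gate is most informative.
    Residual connection when stride is 1 and in == out channels.
    """

    def __init__(self, spec: BlockSpec):
        super().__init__()
        self.spec = spec
        mid = spec.expansion_channels
        self.expand = ConvBnAct(spec.in_channels, mid, 1, act=spec.activation)
        self.attn = LittleCBAM(mid) if spec.use_little_cbam else nn.Identity()
        self.depthwise = ConvBnAct(mid, mid, spec.kernel, spec.stride, g=mid,
                                   act=spec.activation)
        self.project = ConvBnAct(mid, spec.out_channels, 1, act="identity")
        self.residual = spec.stride == 1 and spec.in_channels == spec.out_channels

    def forward(self, x):
        y = self.project(self.depthwise(self.attn(self.expand(x))))
        return x + y if self.residual else y


class C3Mobile(Module):
    """CSP-style block whose inner units are MobileNetV3 bottlenecks.

    One branch stacks ``n`` bottlenecks, the other is a 1x1 shortcut; the
    two halves are concatenated and fused by a 1x1 convolution.  Replaces
    the much heavier CSP1_N/CSP2_N blocks of the baseline.
    """

    def __init__(self, c1: int, c2: int, n: int = 1, expansion: float = 0.5,
                 inner_expand: float = 2.0, use_little_cbam: bool = True,
                 act: str = "hswish"):
        super().__init__()
        c_ = max(int(c2 * expansion), 1)
        self.cv1 = ConvBnAct(c1, c_, 1, act=act)
        self.cv2 = ConvBnAct(c1, c_, 1, act=act)
        self.m = Sequential(*[
            MobileNetV3Bottleneck(BlockSpec(
                c_, c_, max(int(c_ * inner_expand), 1),
                use_little_cbam=use_little_cbam, activation=act))
            for _ in range(n)])
        self.cv3 = ConvBnAct(2 * c_, c2, 1, act=act)

    def forward(self, x):
        return self.cv3(nn.concat([self.m(self.cv1(x)), self.cv2(x)], axis=1))


class Bottleneck(Module):
    """Standard YOLOv5 bottleneck (1x1 then 3x3, optional residual)."""

    def __init__(self, c1, c2, shortcut=True, e=0.5):
        super().__init__()
        c_ = int(c2 * e)
        self.cv1 = ConvBnAct(c1, c_, 1)
        self.cv2 = ConvBnAct(c_, c2, 3)
        self.add = shortcut and c1 == c2

    def forward(self, x):
        y = self.cv2(self.cv1(x))
        return x + y if self.add else y


class C3(Module):
    """YOLOv5 v6 C3 block (CSP with three 1x1 convs)."""

    def __init__(self, c1, c2, n=1, shortcut=True, e=0.5):
        super().__init__()
        c_ = int(c2 * e)
        self.cv1 = ConvBnAct(c1, c_, 1)
        self.cv2 = ConvBnAct(c1, c_, 1)
        self.cv3 = ConvBnAct(2 * c_, c2, 1)
        self.m = Sequential(*[Bottleneck(c_, c_, shortcut, e=1.0) for _ in range(n)])

    def forward(self, x):
        return self.cv3(nn.concat([self.m(self.cv1(x)), self.cv2(x)], axis=1))


class SPPF(Module):
    """Spatial pyramid pooling, fast variant (three chained 5x5 max pools)."""

    def __init__(self, c1, c2, k=5):
        super().__init__()
        c_ = c1 // 2
        self.cv1 = ConvBnAct(c1, c_, 1)
        self.cv2 = ConvBnAct(c_ * 4, c2, 1)
        self.pool = MaxPool2d(k, 1, k // 2)

    def forward(self, x):
        x = self.cv1(x)
        y1 = self.pool(x)
        y2 = self.pool(y1)
        y3 = self.pool(y2)
        return self.cv2(nn.concat([x, y1, y2, y3], axis=1))
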