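"""The five building blocks of the aggregation network.

* :class:`ResidualBlock` - conv-BN-ReLU-conv-BN plus an identity or 1x1
  projection shortcut (no activation after the addition, so a zeroed
  transform branch reduces the block to its shortcut exactly).
* :class:`DownFusionPyramid` - stride-2 convolution image pyramid whose
  levels are concatenated into the encoder as additional inputs.
* :class:`AttentionGate` - additive spatial attention on skip connections.
* :class:`DACBlock` / :class:`RMPBlock` - the bottleneck context extractor:
  parallel dilated-convolution branches summed residually, followed by
  multi-kernel max pooling.
* :class:`UpFusion` - dense decoder-to-decoder connections through chained
  stride-2 transposed convolutions.
"""

from __future__ import annotations

import numpy as np

from .engine import (BatchNorm2d, Conv2d, ConvTranspose2d, Identity, Module,
                     ModuleList, Sequential, Tensor, concat)
from .engine import functional as F
from .errors import InvalidInputError, InvalidSpecError
from .spec import NetworkSpec


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


class ConvBNReLU(Sequential):
    def __init__(self, cin: int, cout: int, kernel: int = 3, *, stride: int = 1):
        super().__init__(Conv2d(cin, cout, kernel, stride=stride, bias=False),
                         BatchNorm2d(cout))

    def forward(self, x: Tensor) -> Tensor:
        return super().forward(x).relu()


class DoubleConvBlock(Module):
    """Plain U-Net block: two 3x3 conv-BN-ReLU stages."""

    def __init__(self, cin: int, cout: int):
        super().__init__()
        if cout < 1:
            raise InvalidSpecError("out_channels must be positive")
        self.c1 = ConvBNReLU(cin, cout)
        self.c2 = ConvBNReLU(cout, cout)

    def forward(self, x: Tensor) -> Tensor:
        return self.c2(self.c1(_as_tensor(x)))


class ResidualBlock(Module):
    """Residual convolution block preserving spatial dims.

    The transform branch is conv3x3-BN-ReLU-conv3x3-BN; the shortcut is the
    identity when channel counts match, otherwise a 1x1 projection.
    """

    def __init__(self, cin: int, cout: int):
        super().__init__()
        if cout < 1:
            raise InvalidSpecError("out_channels must be positive")
        self.conv1 = Conv2d(cin, cout, 3, bias=False)
        self.bn1 = BatchNorm2d(cout)
        self.conv2 = Conv2d(cout, cout, 3, bias=False)
        self.bn2 = BatchNorm2d(cout)
        self.shortcut = Identity() if cin == cout else Conv2d(cin, cout, 1)

    @property
    def uses_identity_shortcut(self) -> bool:
        return isinstance(self.shortcut, Identity)

    def forward(self, x: Tensor) -> Tensor:
        x = _as_tensor(x)
        t = self.bn1(self.conv1(x)).relu()
        t = self.bn2(self.conv2(t))
        return t + self.shortcut(x)


class DownFusionPyramid(Module):
    """Stride-2 convolution pyramid over the raw input image.

    Level i (i = 1..4) has spatial dims input/2^i and ``base_width * 2^(i-1)``
    channels: the recurrence halves H and W and doubles C, with the channel
    seed aligned to the encoder's first-level width so the pyramid maps are
    comparable to the encoder maps they join.
    """

    def __init__(self, in_channels: int, base_width: int, depth: int = 4):
        super().__init__()
        widths = [base_width * (1 << i) for i in range(depth)]
        chans = [in_channels] + widths[:-1]
        self.levels = ModuleList(
            ConvBNReLU(cin, cout, 3, stride=2) for cin, cout in zip(chans, widths)
        )

    def forward(self, image: Tensor) -> list[Tensor]:
        image = _as_tensor(image)
        _, _, h, w = image.shape
        if h % 16 or w % 16 or h == 0 or w == 0:
            raise InvalidInputError(
                f"input dims must be divisible by 16 to survive 4 halvings, got {h}x{w}"
            )
        maps = []
        x = image
        for level in self.levels:
            x = level(x)
            maps.append(x)
        return maps


def down_fusion_pyramid(image, spec: NetworkSpec) -> list[Tensor]:
    """Build a fresh pyramid for ``spec`` and apply it to ``image`` (N,C,H,W)."""
    return DownFusionPyramid(spec.in_channels, spec.width, spec.depth)(image)


class AttentionGate(Module):
    """Additive attention over a skip connection.

    alpha = sigmoid(psi(relu(W_g * gate + W_x * strided(skip)))), computed at
    the gate's resolution and bilinearly upsampled; the output is the skip
    map weighted per pixel (broadcast over channels).
    """

    def __init__(self, skip_channels: int, gate_channels: int):
        super().__init__()
        inter = max(1, skip_channels // 2)
        self.w_x = Conv2d(skip_channels, inter, 1, stride=2)
        self.w_g = Conv2d(gate_channels, inter, 1)
        self.psi = Conv2d(inter, 1, 1)

    def attention_map(self, skip: Tensor, gate: Tensor) -> Tensor:
        skip, gate = _as_tensor(skip), _as_tensor(gate)
        _, _, hs, ws = skip.shape
        _, _, hg, wg = gate.shape
        if (hs, ws) != (2 * hg, 2 * wg):
            raise InvalidInputError(
                f"gate dims {hg}x{wg} must be half the skip dims {hs}x{ws}"
            )
        a = (self.w_x(skip) + self.w_g(gate)).relu()
        alpha = self.psi(a).sigmoid()
        return F.bilinear_resize(alpha, (hs, ws))

    def forward(self, skip: Tensor, gate: Tensor) -> Tensor:
        return _as_tensor(skip) * self.attention_map(skip, gate)


def attention_gate(skip, gate) -> Tensor:
    """Functional form building a fresh gate sized to its inputs."""
    skip, gate = _as_tensor(skip), _as_tensor(gate)
    return AttentionGate(skip.shape[1], gate.shape[1])(skip, gate)


class DACBlock(Module):
    """Dense atrous convolution: four parallel dilated branches summed onto x.

    Branch dilation sequences are {1}, {3}, {1,3}, {1,3,5}; multi-conv
    branches end in a 1x1 convolution.  All convolutions are same-padded, so
    spatial dims are preserved for any input size.
    """

    _BRANCHES = ((1,), (3,), (1, 3), (1, 3, 5))

    def __init__(self, channels: int):
        super().__init__()
        branches = []
        for dils in self._BRANCHES:
            convs = [Conv2d(channels, channels, 3, dilation=d) for d in dils]
            if len(dils) > 1:
                convs.append(Conv2d(channels, channels, 1))
            branches.append(ModuleList(convs))
        self.branches = ModuleList(branches)

    def forward(self, x: Tensor) -> Tensor:
        x = _as_tensor(x)
        out = x
        for branch in self.branches:
            b = x
            for conv in branch:
                b = conv(b).relu()
            out = out + b
        return out


def dac_block(x) -> Tensor:
    x = _as_tensor(x)
    return DACBlock(x.shape[1])(x)


class RMPBlock(Module):
    """Residual multi-kernel pooling with kernel sizes 2, 3, 4 and 6.

    Each branch max-pools, reduces to one channel with a 1x1 convolution and
    bilinearly upsamples back; the four maps are concatenated with the input
    (C+4 channels) and fused back to C channels by a 1x1 convolution.

    With ``clamp_kernels=False`` inputs smaller than the largest kernel are
    rejected; with clamping (used inside the assembled network so that small
    training patches remain usable) each kernel is reduced to
    ``min(kernel, H, W)``.
    """

    KERNELS = (2, 3, 4, 6)

    def __init__(self, channels: int, *, clamp_kernels: bool = False):
        super().__init__()
        self.clamp_kernels = clamp_kernels
        self.reducers = ModuleList(Conv2d(channels, 1, 1) for _ in self.KERNELS)
        self.fuse = Conv2d(channels + len(self.KERNELS), channels, 1)

    def forward(self, x: Tensor) -> Tensor:
        x = _as_tensor(x)
        _, _, h, w = x.shape
        if not self.clamp_kernels and min(h, w) < max(self.KERNELS):
            raise InvalidInputError(
                f"spatial dims {h}x{w} smaller than the largest pooling kernel "
                f"{max(self.KERNELS)}"
            )
        parts = [x]
        for k, reducer in zip(self.KERNELS, self.reducers):
            keff = min(k, h, w) if self.clamp_kernels else k
            pooled = F.max_pool2d(x, keff)
            parts.append(F.bilinear_resize(reducer(pooled), (h, w)))
        return self.fuse(concat(parts, axis=1))


def rmp_block(x) -> Tensor:
    x = _as_tensor(x)
    return RMPBlock(x.shape[1])(x)


class UpFusion(Module):
    """Dense decoder connections: every deeper decoder output is carried to
    each shallower level by chained stride-2 transposed convolutions
    (channel-preserving) and concatenated there.
    """

    def __init__(self, level_widths: list[int]):
        super().__init__()
        self.depth = len(level_widths)
        chains = {}
        for target in range(1, self.depth):
            for source in range(target + 1, self.depth + 1):
                w = level_widths[source - 1]
                chains[f"u{source}_{target}"] = Sequential(
                    *[ConvTranspose2d(w, w, 3) for _ in range(source - target)]
                )
        self.chains = ModuleList(chains.values())
        self._index = {k: i for i, k in enumerate(chains)}

    def chain(self, source: int, target: int) -> Sequential:
        return self.chains[self._index[f"u{source}_{target}"]]

    def forward(self, decoder_outputs: dict[int, Tensor], target: int) -> list[Tensor]:
        """Members U(depth, target) .. U(target+1, target), deepest first."""
        if target == self.depth:
            return []
        members = []
        for source in range(self.depth, target, -1):
            if source in decoder_outputs:
                members.append(self.chain(source, target)(decoder_outputs[source]))
        return members


def up_fusion(decoder_outputs: list[Tensor], target_level: int, depth: int = 4) -> Tensor | None:
    """Concatenate deeper decoder outputs at ``target_level`` resolution.

    ``decoder_outputs`` are ordered deepest-first (levels depth..target+1).
    Returns ``None`` for the deepest level (an empty bundle).
    """
    if not 1 <= target_level <= depth:
        raise InvalidInputError(f"target_level must be in 1..{depth}")
    if target_level == depth:
        return None
    outputs = {depth - i: _as_tensor(t) for i, t in enumerate(decoder_outputs)}
    widths = [0] * depth
    for lvl, t in outputs.items():
        widths[lvl - 1] = t.shape[1]
    # give undriven levels a placeholder width so chain construction succeeds
    widths = [w if w else 1 for w in widths]
    fusion = UpFusion(widths)
    members = fusion(outputs, target_level)
    return concat(members, axis=1)
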