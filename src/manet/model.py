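"""Assembly of the full segmentation network from its building blocks.

The network is a four-level U-Net encoder-decoder with sigmoid output.
Depending on the :class:`~manet.spec.NetworkSpec` flags it adds: residual
convolution blocks, a stride-2 convolution image pyramid concatenated into
the encoder, a dilated-convolution + multi-kernel-pooling context block at
the bottleneck, attention-gated skip connections, and dense up-sampling
fusion paths between decoder levels.
"""

from __future__ import annotations

import numpy as np

from .blocks import (AttentionGate, DACBlock, DoubleConvBlock, DownFusionPyramid,
                     RMPBlock, ResidualBlock, UpFusion)
from .engine import (Conv2d, ConvTranspose2d, Module, ModuleList, Tensor, concat,
                     seeded_init)
from .engine import functional as F
from .errors import InvalidInputError
from .spec import NetworkSpec


class MANet(Module):
    """Multifunctional aggregation network for binary semantic segmentation.

    ``forward`` maps (N, in_channels, H, W) with H, W divisible by 16 to
    per-pixel probabilities (N, out_channels, H, W) in [0, 1].
    """

    def __init__(self, spec: NetworkSpec):
        super().__init__()
        self.spec = spec
        widths = spec.level_widths()          # encoder levels 1..4
        bneck = spec.bottleneck_width
        Block = ResidualBlock if spec.use_residual else DoubleConvBlock

        df_extra = 1 if spec.use_down_fusion else 0
        self.down_fusion = (DownFusionPyramid(spec.in_channels, spec.width, spec.depth)
                            if spec.use_down_fusion else None)

        enc = [Block(spec.in_channels, widths[0])]
        for i in range(1, spec.depth):
            enc.append(Block(widths[i - 1] * (1 + df_extra), widths[i]))
        self.encoder = ModuleList(enc)
        self.bottleneck = Block(widths[-1] * (1 + df_extra), bneck)

        if spec.use_context_extractor:
            self.dac = DACBlock(bneck)
            self.rmp = RMPBlock(bneck, clamp_kernels=True)
        else:
            self.dac = self.rmp = None

        gates = []
        ups = []
        prev = bneck
        for i in range(spec.depth, 0, -1):        # decoder levels 4..1
            w = widths[i - 1]
            ups.append(ConvTranspose2d(prev, w, 3))
            gates.append(AttentionGate(w, prev) if spec.use_attention_gate else None)
            prev = w
        self.upconvs = ModuleList(ups)
        self.gates = ModuleList(g for g in gates if g is not None)
        self._gate_slots = [g is not None for g in gates]

        self.up_fusion = UpFusion(widths) if spec.use_up_fusion else None

        dec = []
        for i in range(spec.depth, 0, -1):
            w = widths[i - 1]
            cin = 2 * w
            if spec.use_up_fusion and i < spec.depth:
                cin += sum(widths[j - 1] for j in range(i + 1, spec.depth + 1))
            dec.append(Block(cin, w))
        self.decoder = ModuleList(dec)

        self.head = Conv2d(widths[0], spec.out_channels, 1)

    # ------------------------------------------------------------------
    def forward(self, x) -> Tensor:
        x = x if isinstance(x, Tensor) else Tensor(np.asarray(x))
        if x.ndim != 4 or x.shape[1] != self.spec.in_channels:
            raise InvalidInputError(
                f"expected (N,{self.spec.in_channels},H,W) input, got {x.shape}"
            )
        _, _, h, w = x.shape
        if h == 0 or w == 0 or h % 16 or w % 16:
            raise InvalidInputError(
                f"input dims must be divisible by 16, got {h}x{w}"
            )

        pyramid = self.down_fusion(x) if self.down_fusion is not None else None

        skips = []
        feat = x
        for i, block in enumerate(self.encoder):
            if i > 0:
                feat = F.max_pool2d(feat, 2)
                if pyramid is not None:
                    feat = concat([feat, pyramid[i - 1]], axis=1)
            feat = block(feat)
            skips.append(feat)
        feat = F.max_pool2d(feat, 2)
        if pyramid is not None:
            feat = concat([feat, pyramid[-1]], axis=1)
        feat = self.bottleneck(feat)
        if self.dac is not None:
            feat = self.rmp(self.dac(feat))

        decoder_outputs: dict[int, Tensor] = {}
        gate_iter = iter(self.gates)
        prev = feat
        for step, level in enumerate(range(self.spec.depth, 0, -1)):
            up = self.upconvs[step](prev)
            skip = skips[level - 1]
            if self._gate_slots[step]:
                skip = next(gate_iter)(skip, prev)
            parts = [up, skip]
            if self.up_fusion is not None:
                parts.extend(self.up_fusion(decoder_outputs, level))
            out = self.decoder[step](concat(parts, axis=1) if len(parts) > 1 else parts[0])
            decoder_outputs[level] = out
            prev = out

        return self.head(prev).sigmoid()


def build_network(spec: NetworkSpec, seed: int = 0) -> MANet:
    """Construct a network with reproducible weight initialization."""
    with seeded_init(seed):
        return MANet(spec)


def count_parameters(net: Module) -> int:
    """Exact number of trainable scalar parameters."""
    return sum(p.data.size for p in net.parameters())


def parameter_count_millions(net: Module) -> int:
    """Parameter count rounded to the nearest million (reporting convention)."""
    return int(round(count_parameters(net) / 1e6))
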