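"""Declarative network architecture description.

A :class:`NetworkSpec` fixes the U-Net backbone (first-layer width, four
down-samplings) and toggles the five aggregation modules independently, so
every row of the ablation study is expressible as a flag combination.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, replace

from .errors import InvalidSpecError


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture of the segmentation network.

    Parameters
    ----------
    base_width:
        Channels of the first encoder level (64 in the reference setup).
    depth:
        Number of down-samplings; the architecture is defined for 4.
    width_multiplier:
        Global channel scale; values < 1 give CPU-trainable test networks.
    use_residual:
        Replace plain double-conv blocks with residual blocks.
    use_attention_gate:
        Gate skip connections with additive spatial attention.
    use_context_extractor:
        Apply the dense-atrous-convolution + residual multi-kernel pooling
        context block at the bottleneck.
    use_down_fusion:
        Feed a stride-2 convolution image pyramid into the encoder levels.
    use_up_fusion:
        Densely concatenate upsampled deeper decoder outputs into each
        decoder level.
    """

    base_width: int = 64
    depth: int = 4
    width_multiplier: float = 1.0
    use_residual: bool = False
    use_attention_gate: bool = False
    use_context_extractor: bool = False
    use_down_fusion: bool = False
    use_up_fusion: bool = False
    in_channels: int = 3
    out_channels: int = 1

    def __post_init__(self):
        if self.base_width < 1:
            raise InvalidSpecError("base_width must be >= 1")
        if self.depth != 4:
            raise InvalidSpecError("the architecture is defined for depth 4")
        if not self.width_multiplier > 0:
            raise InvalidSpecError("width_multiplier must be positive")
        if self.in_channels < 1 or self.out_channels < 1:
            raise InvalidSpecError("channel counts must be >= 1")

    # -- derived quantities --------------------------------------------------
    @property
    def width(self) -> int:
        """Scaled first-level channel count (>= 1)."""
        return max(1, int(round(self.base_width * self.width_multiplier)))

    def level_widths(self) -> list[int]:
        """Channels of encoder levels 1..4 (doubling per level)."""
        return [self.width * (1 << i) for i in range(self.depth)]

    @property
    def bottleneck_width(self) -> int:
        return self.width * (1 << self.depth)

    # -- canonical configurations --------------------------------------------
    @classmethod
    def full(cls, **kw) -> "NetworkSpec":
        """All five modules enabled (the complete aggregation network)."""
        return cls(use_residual=True, use_attention_gate=True, use_context_extractor=True,
                   use_down_fusion=True, use_up_fusion=True, **kw)

    @classmethod
    def unet(cls, **kw) -> "NetworkSpec":
        """Vanilla U-Net topology (all flags off)."""
        return cls(**kw)

    _ABLATION_ROWS = {
        1: (),
        2: ("use_residual",),
        3: ("use_residual", "use_attention_gate"),
        4: ("use_residual", "use_context_extractor"),
        5: ("use_residual", "use_down_fusion", "use_up_fusion"),
        6: ("use_residual", "use_attention_gate", "use_context_extractor"),
        7: ("use_residual", "use_attention_gate", "use_down_fusion", "use_up_fusion"),
        8: ("use_residual", "use_context_extractor", "use_down_fusion", "use_up_fusion"),
        9: ("use_residual", "use_attention_gate", "use_context_extractor",
            "use_down_fusion", "use_up_fusion"),
    }

    @classmethod
    def ablation_row(cls, row: int, **kw) -> "NetworkSpec":
        """Spec for ablation configuration ``row`` (1 = plain U-Net, 9 = all modules).

        The sampling-fusion modules (down/up) always toggle jointly, as in
        the ablation study.
        """
        if row not in cls._ABLATION_ROWS:
            raise InvalidSpecError(f"ablation row must be 1..9, got {row}")
        flags = {name: True for name in cls._ABLATION_ROWS[row]}
        return cls(**flags, **kw)

    def with_multiplier(self, m: float) -> "NetworkSpec":
        return replace(self, width_multiplier=m)

    # -- serialization -------------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkSpec":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise InvalidSpecError(f"unknown network spec fields: {sorted(unknown)}")
        return cls(**d)

    def spec_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()
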