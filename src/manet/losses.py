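"""Composite BCE-Dice training objective.

The training loss is the convex combination

    L = beta * L_Dice + (1 - beta) * L_BCE,       beta = 0.75 by default,

where L_BCE is the pixel-mean binary cross entropy and L_Dice is one minus
the soft Dice coefficient.  The Dice term is smoothed with a small epsilon
in numerator and denominator so that an empty prediction of an empty mask
scores perfectly; the same epsilon clips probabilities before logarithms.

All functions accept numpy arrays or engine Tensors and return a scalar
Tensor (use ``float(...)`` for a plain number); gradients flow when the
prediction participates in an autodiff graph.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .engine import Tensor
from .errors import InvalidInputError, InvalidSpecError


@dataclass(frozen=True)
class LossConfig:
    beta: float = 0.75
    epsilon: float = 1e-7

    def __post_init__(self):
        if not 0.0 <= self.beta <= 1.0:
            raise InvalidSpecError("beta must lie in [0, 1]")
        if not self.epsilon > 0:
            raise InvalidSpecError("epsilon must be positive")


def _coerce_pair(p, g) -> tuple[Tensor, Tensor]:
    p = p if isinstance(p, Tensor) else Tensor(np.asarray(p, dtype=float))
    g = g if isinstance(g, Tensor) else Tensor(np.asarray(g, dtype=float))
    if p.shape != g.shape:
        raise InvalidInputError(
            f"prediction shape {p.shape} != ground-truth shape {g.shape}"
        )
    return p, g


def bce_loss(p, g, cfg: LossConfig = LossConfig()) -> Tensor:
    """Pixel-mean binary cross entropy, -(1/n) sum[g ln p + (1-g) ln(1-p)]."""
    p, g = _coerce_pair(p, g)
    pc = p.clip(cfg.epsilon, 1.0 - cfg.epsilon)
    return -(g * pc.log() + (1.0 - g) * (1.0 - pc).log()).mean()


def dice_loss(p, g, cfg: LossConfig = LossConfig()) -> Tensor:
    """Soft Dice loss, 1 - (2 sum(p*g) + eps) / (sum(p) + sum(g) + eps)."""
    p, g = _coerce_pair(p, g)
    num = 2.0 * (p * g).sum() + cfg.epsilon
    den = p.sum() + g.sum() + cfg.epsilon
    return 1.0 - num / den


def bce_dice_loss(p, g, cfg: LossConfig = LossConfig()) -> Tensor:
    """beta-weighted combination of the Dice and BCE losses."""
    return cfg.beta * dice_loss(p, g, cfg) + (1.0 - cfg.beta) * bce_loss(p, g, cfg)
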