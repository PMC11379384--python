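"""Run configuration, training loop, evaluation and prediction.

The training protocol: Adam at learning rate 1e-3 (multiplied by 0.1 once
after epoch 50 by default), batch size 4, no augmentation, composite
BCE-Dice loss with beta 0.75, 30% of the training pool held out for
validation, best checkpoint selected by validation Dice.
"""

from __future__ import annotations

import json
import platform
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .checkpoint import load_checkpoint, save_checkpoint
from .data import (ImageMaskPair, TilingSpec, load_pairs, stitch_patches, tile_array,
                   write_mask)
from .engine import Adam, no_grad
from .errors import ConfigError, InvalidInputError, InvalidSpecError
from .losses import LossConfig, bce_dice_loss
from .metrics import ConfusionCounts, MetricReport, confusion_counts, roc_auc, \
    segmentation_metrics
from .model import build_network
from .spec import NetworkSpec
from .data import validation_holdout


@dataclass(frozen=True)
class TrainConfig:
    network: NetworkSpec = field(default_factory=NetworkSpec.full)
    loss: LossConfig = field(default_factory=LossConfig)
    optimizer: str = "adam"
    learning_rate: float = 0.001
    lr_decay_factor: float = 0.1
    lr_decay_epoch: int = 50
    batch_size: int = 4
    epochs: int = 100
    val_fraction: float = 0.30
    seed: int = 0
    threshold: float = 0.5

    def __post_init__(self):
        if self.optimizer != "adam":
            raise ConfigError("optimizer", f"only 'adam' is supported, got {self.optimizer!r}")
        if self.batch_size < 1:
            raise ConfigError("batch_size", "must be >= 1")
        if self.epochs < 1:
            raise ConfigError("epochs", "must be >= 1")
        if not 0.0 < self.val_fraction < 1.0:
            raise ConfigError("val_fraction", "must lie strictly inside (0, 1)")
        if not self.learning_rate > 0:
            raise ConfigError("learning_rate", "must be positive")
        if not 0.0 < self.threshold < 1.0:
            raise ConfigError("threshold", "must lie strictly inside (0, 1)")

    def to_dict(self) -> dict:
        return {
            "network": self.network.to_dict(),
            "loss": {"beta": self.loss.beta, "epsilon": self.loss.epsilon},
            "optimizer": self.optimizer,
            "learning_rate": self.learning_rate,
            "lr_decay_factor": self.lr_decay_factor,
            "lr_decay_epoch": self.lr_decay_epoch,
            "batch_size": self.batch_size,
            "epochs": self.epochs,
            "val_fraction": self.val_fraction,
            "seed": self.seed,
            "threshold": self.threshold,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        d = dict(d)
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ConfigError(sorted(unknown)[0], "unknown configuration field")
        try:
            if "network" in d:
                d["network"] = NetworkSpec.from_dict(d["network"])
        except (InvalidSpecError, TypeError) as exc:
            raise ConfigError("network", str(exc)) from exc
        try:
            if "loss" in d:
                d["loss"] = LossConfig(**d["loss"])
        except (InvalidSpecError, TypeError) as exc:
            raise ConfigError("loss", str(exc)) from exc
        try:
            return cls(**d)
        except TypeError as exc:
            raise ConfigError("config", str(exc)) from exc

    @classmethod
    def from_yaml(cls, path) -> "TrainConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigError("config", "configuration file must be a mapping")
        return cls.from_dict(raw)

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        return path


def _pair_arrays(pair: ImageMaskPair) -> tuple[np.ndarray, np.ndarray]:
    x = pair.image.astype(np.float32) / 255.0
    return x.transpose(2, 0, 1), pair.mask.astype(np.float32)[None]


def _environment_stamp() -> dict:
    return {"package_version": __version__, "python": platform.python_version(),
            "numpy": np.__version__, "platform": platform.platform()}


def train(config: TrainConfig, manifest_path, out_dir, resume_from=None) -> dict:
    """Train per the protocol; writes checkpoints and a run log, returns the log.

    ``resume_from`` initializes weights from an existing checkpoint; the
    checkpoint is refused when its architecture hash differs from
    ``config.network``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pairs = load_pairs(manifest_path)
    if not pairs:
        raise InvalidInputError("manifest contains no training pairs")
    by_id = {p.identifier: p for p in pairs}
    train_ids, val_ids = validation_holdout(sorted(by_id), config.val_fraction,
                                            config.seed)
    xs = {i: _pair_arrays(by_id[i]) for i in by_id}

    if resume_from is not None:
        net, _, _ = load_checkpoint(resume_from, expected_spec=config.network)
    else:
        net = build_network(config.network, seed=config.seed)
    opt = Adam(net.parameters(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)

    records = []
    best_dice = -1.0
    best_path = out_dir / "checkpoint_best.npz"
    final_path = out_dir / "checkpoint_final.npz"
    for epoch in range(1, config.epochs + 1):
        opt.lr = config.learning_rate * (
            config.lr_decay_factor if epoch > config.lr_decay_epoch else 1.0
        )
        net.train()
        order = rng.permutation(train_ids)
        losses = []
        for start in range(0, len(order), config.batch_size):
            batch = order[start:start + config.batch_size]
            xb = np.stack([xs[i][0] for i in batch])
            yb = np.stack([xs[i][1] for i in batch])
            opt.zero_grad()
            pred = net(xb)
            loss = bce_dice_loss(pred, yb, config.loss)
            loss.backward()
            opt.step()
            losses.append(float(loss))
        train_loss = float(np.mean(losses)) if losses else float("nan")

        val_loss, val_dice = float("nan"), float("nan")
        if val_ids:
            net.eval()
            vlosses, counts = [], ConfusionCounts(0, 0, 0, 0)
            with no_grad():
                for i in val_ids:
                    xv, yv = xs[i]
                    pv = net(xv[None]).data[0]
                    vlosses.append(float(bce_dice_loss(pv, yv, config.loss)))
                    counts = counts + confusion_counts(pv, yv.astype(np.uint8),
                                                       config.threshold)
            val_loss = float(np.mean(vlosses))
            val_dice = segmentation_metrics(counts).dice
            if val_dice > best_dice:
                best_dice = val_dice
                save_checkpoint(net, best_path, seed=config.seed)
        records.append({"epoch": epoch, "train_loss": train_loss,
                        "val_loss": val_loss, "val_dice": val_dice})

    save_checkpoint(net, final_path, seed=config.seed)
    if not val_ids:
        save_checkpoint(net, best_path, seed=config.seed)
    run_log = {
        "config": config.to_dict(),
        "seed": config.seed,
        "environment": _environment_stamp(),
        "split": {"train": list(train_ids), "val": list(val_ids)},
        "epochs": records,
        "best_val_dice": None if best_dice < 0 else best_dice,
        "checkpoints": {"best": best_path.name, "final": final_path.name},
        "finished_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    (out_dir / "runlog.json").write_text(json.dumps(run_log, indent=2))
    return run_log


def evaluate(checkpoint_path, manifest_path, out_dir, threshold: float = 0.5
             ) -> MetricReport:
    """Run inference over a manifest, aggregate pixel counts globally, and
    write ``metrics.json`` plus the ROC curve CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    net, _, _ = load_checkpoint(checkpoint_path)
    net.eval()
    pairs = load_pairs(manifest_path)
    if not pairs:
        raise InvalidInputError("manifest contains no evaluation pairs")
    counts = ConfusionCounts(0, 0, 0, 0)
    probs, masks = [], []
    with no_grad():
        for pair in pairs:
            x, y = _pair_arrays(pair)
            p = net(x[None]).data[0, 0]
            counts = counts + confusion_counts(p, pair.mask, threshold)
            probs.append(p)
            masks.append(pair.mask)
    curve, auc = roc_auc(probs, masks)
    report = segmentation_metrics(counts, auc=auc)
    (out_dir / "metrics.json").write_text(json.dumps(report.to_dict(), indent=2))
    curve.to_csv(out_dir / "roc.csv")
    return report


def predict_image(checkpoint_path, image: np.ndarray, *, stitch: bool = False,
                  threshold: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Probability map and binary mask for one RGB image.

    Inputs with dims divisible by 16 run directly; 1000x1000 inputs with
    ``stitch`` are tiled, predicted per patch, and re-assembled.
    """
    net, _, _ = load_checkpoint(checkpoint_path)
    net.eval()
    h, w = image.shape[:2]
    spec = TilingSpec()
    with no_grad():
        if stitch:
            if (h, w) != (spec.source_size, spec.source_size):
                raise InvalidInputError(
                    f"--stitch expects a {spec.source_size}x{spec.source_size} image"
                )
            patches = []
            for tile in tile_array(image, spec):
                x = tile.astype(np.float32).transpose(2, 0, 1) / 255.0
                patches.append(net(x[None]).data[0, 0])
            prob = stitch_patches(patches, spec, kind="probability")
        else:
            if h % 16 or w % 16:
                raise InvalidInputError(
                    f"image dims {h}x{w} not divisible by 16; use --stitch for "
                    f"{spec.source_size}x{spec.source_size} whole images"
                )
            x = image.astype(np.float32).transpose(2, 0, 1) / 255.0
            prob = net(x[None]).data[0, 0]
    return prob, (prob >= threshold).astype(np.uint8)


def write_prediction(prob: np.ndarray, mask: np.ndarray, out_dir, stem: str
                     ) -> tuple[Path, Path]:
    """Write the 16-bit probability PNG and the 8-bit binary mask PNG."""
    import imageio.v3 as iio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    prob_path = out_dir / f"{stem}_prob.png"
    mask_path = out_dir / f"{stem}_mask.png"
    iio.imwrite(prob_path, np.clip(np.rint(prob * 65535), 0, 65535).astype(np.uint16))
    write_mask(mask, mask_path)
    return prob_path, mask_path
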