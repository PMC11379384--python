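"""Image/mask I/O and the preprocessing protocol.

Whole images of 1000x1000 are cut into a 2x2 grid of 500x500 tiles and
resized to 512x512 network inputs (bilinear for images, nearest-neighbour
for masks, which are re-binarized after any resize).  Splitting follows the
grouped-holdout scheme (one random image per group to the test set) and a
30% validation holdout from the remaining training pool.  For inference on
whole images, patch predictions are resized back and re-assembled at the
source geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.transform import resize

from .errors import InvalidInputError, InvalidSpecError

MANIFEST_COLUMNS = ["identifier", "image_path", "mask_path", "group"]


@dataclass
class ImageMaskPair:
    """An 8-bit RGB image with its binary nuclei mask ({0,1})."""

    image: np.ndarray
    mask: np.ndarray
    identifier: str
    group: str | None = None

    def __post_init__(self):
        self.image = np.asarray(self.image)
        self.mask = np.asarray(self.mask)
        if self.image.ndim != 3 or self.image.shape[2] != 3:
            raise InvalidInputError(f"image must be HxWx3, got {self.image.shape}")
        if self.mask.shape != self.image.shape[:2]:
            raise InvalidInputError(
                f"mask dims {self.mask.shape} != image dims {self.image.shape[:2]}"
            )
        self.mask = (self.mask > 0).astype(np.uint8)


@dataclass(frozen=True)
class TilingSpec:
    source_size: int = 1000
    tile_size: int = 500
    resize_to: int = 512

    def __post_init__(self):
        if self.tile_size * 2 != self.source_size:
            raise InvalidSpecError("tiles must cover the source exactly in a 2x2 grid")
        if self.resize_to < 16:
            raise InvalidSpecError("resize_to too small to be a network input")

    @property
    def offsets(self) -> list[tuple[int, int]]:
        t = self.tile_size
        return [(0, 0), (0, t), (t, 0), (t, t)]  # row-major q0..q3


@dataclass(frozen=True)
class DatasetSplit:
    train: list[str]
    val: list[str]
    test: list[str]
    seed: int

    def __post_init__(self):
        sets = [set(self.train), set(self.val), set(self.test)]
        if sum(len(s) for s in sets) != len(set().union(*sets)):
            raise InvalidInputError("split lists must be disjoint")


# ---------------------------------------------------------------------------
# resizing primitives
# ---------------------------------------------------------------------------

def _resize_image(img: np.ndarray, size: int) -> np.ndarray:
    out = resize(img.astype(np.float64), (size, size), order=1,
                 preserve_range=True, anti_aliasing=False)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def _resize_mask(mask: np.ndarray, size: int) -> np.ndarray:
    out = resize(mask.astype(np.float64), (size, size), order=0,
                 preserve_range=True, anti_aliasing=False)
    return (out > 0.5).astype(np.uint8)


def _resize_probability(p: np.ndarray, size: int) -> np.ndarray:
    return resize(p.astype(np.float64), (size, size), order=1,
                  preserve_range=True, anti_aliasing=False)


# ---------------------------------------------------------------------------
# tiling / stitching
# ---------------------------------------------------------------------------

def tile_image(pair: ImageMaskPair, spec: TilingSpec = TilingSpec()) -> list[ImageMaskPair]:
    """Cut a source-size pair into 4 resized quadrant pairs (_q0.._q3 row-major)."""
    h, w = pair.mask.shape
    if (h, w) != (spec.source_size, spec.source_size):
        raise InvalidInputError(
            f"expected a {spec.source_size}x{spec.source_size} pair, got {h}x{w}"
        )
    t = spec.tile_size
    out = []
    for q, (r, c) in enumerate(spec.offsets):
        img = _resize_image(pair.image[r:r + t, c:c + t], spec.resize_to)
        msk = _resize_mask(pair.mask[r:r + t, c:c + t], spec.resize_to)
        out.append(ImageMaskPair(img, msk, f"{pair.identifier}_q{q}", pair.group))
    return out


def tile_array(image: np.ndarray, spec: TilingSpec = TilingSpec()) -> list[np.ndarray]:
    """Tile a bare image array (inference path, no mask)."""
    if image.shape[:2] != (spec.source_size, spec.source_size):
        raise InvalidInputError(
            f"expected a {spec.source_size}x{spec.source_size} image, got {image.shape[:2]}"
        )
    t = spec.tile_size
    return [_resize_image(image[r:r + t, c:c + t], spec.resize_to)
            for r, c in spec.offsets]


def stitch_patches(patches: Sequence[np.ndarray], spec: TilingSpec = TilingSpec(),
                   kind: str = "probability") -> np.ndarray:
    """Re-assemble 4 patch predictions at source geometry (inverse of tiling).

    ``kind`` selects the interpolation when resizing each patch back to tile
    size: "probability" (bilinear) or "mask" (nearest, re-binarized).
    """
    if len(patches) != 4:
        raise InvalidInputError(f"expected exactly 4 patches, got {len(patches)}")
    if kind not in ("probability", "mask"):
        raise InvalidInputError("kind must be 'probability' or 'mask'")
    t = spec.tile_size
    out = np.zeros((spec.source_size, spec.source_size), dtype=float)
    for patch, (r, c) in zip(patches, spec.offsets):
        patch = np.asarray(patch, dtype=float)
        if patch.shape != (spec.resize_to, spec.resize_to):
            raise InvalidInputError(
                f"patch shape {patch.shape} != ({spec.resize_to}, {spec.resize_to})"
            )
        if kind == "mask":
            out[r:r + t, c:c + t] = _resize_mask(patch, t)
        else:
            out[r:r + t, c:c + t] = _resize_probability(patch, t)
    return out


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

def grouped_holdout_split(pairs: Sequence[ImageMaskPair], seed: int) -> DatasetSplit:
    """One seeded-uniform pick per group to test; the remainder is the train pool."""
    groups: dict[str, list[str]] = {}
    for pair in pairs:
        if not pair.group:
            raise InvalidInputError(f"pair '{pair.identifier}' has no group label")
        groups.setdefault(pair.group, []).append(pair.identifier)
    rng = np.random.default_rng(seed)
    test = []
    for name in sorted(groups):
        members = sorted(groups[name])
        test.append(members[rng.integers(len(members))])
    test_set = set(test)
    train = [p.identifier for p in pairs if p.identifier not in test_set]
    return DatasetSplit(train=train, val=[], test=sorted(test), seed=seed)


def validation_holdout(train_pool: Sequence[str], fraction: float = 0.30,
                       seed: int = 0) -> tuple[list[str], list[str]]:
    """Seeded shuffle; floor(fraction*n) identifiers go to validation."""
    ids = list(train_pool)
    if len(ids) == 0:
        raise InvalidInputError("cannot split an empty training pool")
    if not 0.0 < fraction < 1.0:
        raise InvalidInputError("fraction must lie strictly inside (0, 1)")
    rng = np.random.default_rng(seed)
    order = rng.permutation(sorted(ids))
    n_val = int(np.floor(fraction * len(ids)))
    val = sorted(order[:n_val].tolist())
    train = sorted(order[n_val:].tolist())
    return train, val


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def read_pair(image_path, mask_path, identifier: str | None = None,
              group: str | None = None) -> ImageMaskPair:
    """Load an RGB image and its mask; mask binarized by the >0 rule."""
    image = np.asarray(iio.imread(image_path))
    if image.ndim == 3 and image.shape[2] == 4:
        image = image[:, :, :3]
    if image.ndim != 3 or image.shape[2] != 3:
        raise InvalidInputError(f"{image_path}: expected an 8-bit RGB image")
    mask = np.asarray(iio.imread(mask_path))
    if mask.ndim == 3:
        mask = mask[..., 0]
    if mask.shape != image.shape[:2]:
        raise InvalidInputError(
            f"mask dims {mask.shape} do not match image dims {image.shape[:2]}"
        )
    if identifier is None:
        identifier = Path(image_path).stem
    return ImageMaskPair(image.astype(np.uint8), (mask > 0).astype(np.uint8),
                         identifier, group)


def write_mask(mask: np.ndarray, path) -> Path:
    """Write a binary mask as an 8-bit PNG with foreground 255."""
    path = Path(path)
    out = ((np.asarray(mask) > 0) * np.uint8(255))
    iio.imwrite(path, out)
    return path


def write_manifest(rows: Sequence[dict], path) -> Path:
    path = Path(path)
    df = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    df.to_csv(path, index=False)
    return path


def read_manifest(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise InvalidInputError(f"manifest {path} missing columns {sorted(missing)}")
    return df


def load_pairs(manifest_path) -> list[ImageMaskPair]:
    """Load every manifest entry; relative paths resolve against the manifest."""
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    df = read_manifest(manifest_path)
    pairs = []
    for row in df.itertuples(index=False):
        if not isinstance(row.mask_path, str) or not row.mask_path:
            raise InvalidInputError(f"manifest entry '{row.identifier}' has no mask")
        img = Path(row.image_path)
        msk = Path(row.mask_path)
        img = img if img.is_absolute() else base / img
        msk = msk if msk.is_absolute() else base / msk
        group = row.group if isinstance(row.group, str) and row.group else None
        pairs.append(read_pair(img, msk, identifier=row.identifier, group=group))
    return pairs
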