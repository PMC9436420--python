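"""HU ↔ unit-interval normalization and augmented patch extraction.

The networks operate on 2-D slices mapped to [0, 1] by the affine window
``I_nor = (I_ori + 1000) / 2800`` (equivalently window level 400 HU, window
width 2800 HU).  HU outside [−1000, 1800] are clipped — the map is recorded
so the inverse ``I_HU = I_nor * 2800 − 1000`` is exact inside the window.
Training patches are square random crops with optional k·90° rotation and
horizontal/vertical flips; domain-A and domain-B patches are always drawn
from independent random slices (unpaired sampling).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["NormalizedImage", "PatchBatch", "normalize_hu", "denormalize",
           "sample_patches", "DEFAULT_OFFSET", "DEFAULT_SCALE", "HU_MIN",
           "HU_MAX"]

DEFAULT_OFFSET = 1000.0   # HU
DEFAULT_SCALE = 2800.0    # HU
HU_MIN = -1000.0          # window lower edge (air)
HU_MAX = 1800.0           # window upper edge


@dataclass
class NormalizedImage:
    """A 2-D slice in the network's [0, 1] domain, with its inverse map."""

    pixels: np.ndarray
    offset: float = DEFAULT_OFFSET
    scale: float = DEFAULT_SCALE
    source: str = ""
    slice_index: int = -1

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(f"expected a 2-D slice, got rank {self.pixels.ndim}")
        if self.pixels.min() < -1e-9 or self.pixels.max() > 1 + 1e-9:
            raise ValueError("normalized pixels must lie in [0, 1]")


@dataclass
class PatchBatch:
    """A stack of normalized patches with provenance and augmentation record.

    ``augmentations[i] = (k, flip_h, flip_v)``: the crop was rotated by
    k·90° counter-clockwise, then flipped along the horizontal axis
    (left-right) if flip_h and the vertical axis (up-down) if flip_v —
    enough information to undo the transform.
    """

    patches: np.ndarray                 # (N, ps, ps)
    coordinates: list = field(default_factory=list)   # (row, col) in source
    augmentations: list = field(default_factory=list)  # (k, flip_h, flip_v)
    pad: int = 0                        # reflect-padding applied to the source

    def __post_init__(self):
        self.patches = np.asarray(self.patches, dtype=np.float64)
        if self.patches.ndim != 3 or self.patches.shape[0] < 1:
            raise ValueError("patches must be a non-empty (N, ps, ps) stack")

    def __len__(self):
        return self.patches.shape[0]


def normalize_hu(image: np.ndarray, offset: float = DEFAULT_OFFSET,
                 scale: float = DEFAULT_SCALE, source: str = "",
                 slice_index: int = -1) -> NormalizedImage:
    """Map an HU slice to [0, 1]; values outside the window are clipped."""
    if scale <= 0:
        raise ValueError(f"scale must be > 0, got {scale}")
    image = np.asarray(image, dtype=np.float64)
    pixels = np.clip((image + offset) / scale, 0.0, 1.0)
    return NormalizedImage(pixels=pixels, offset=offset, scale=scale,
                           source=source, slice_index=slice_index)


def denormalize(image: NormalizedImage) -> np.ndarray:
    """Invert the unit-interval map back to HU."""
    if image.offset is None or image.scale is None:
        raise ValueError("normalization constants are missing")
    return image.pixels * image.scale - image.offset


def _augment(patch: np.ndarray, k: int, flip_h: bool, flip_v: bool) -> np.ndarray:
    out = np.rot90(patch, k)
    if flip_h:
        out = np.fliplr(out)
    if flip_v:
        out = np.flipud(out)
    return out


def sample_patches(slice_img: NormalizedImage, patch_size: int, n: int,
                   augment: bool = True,
                   seed: int | np.random.Generator = 0) -> PatchBatch:
    """Draw ``n`` random square crops, optionally rotated/flipped.

    Crop positions are uniform over all fully in-bounds placements.  A slice
    smaller than the patch is reflect-padded up to the minimum size and the
    padding recorded.  Fully reproducible from ``seed``.
    """
    if n <= 0:
        raise ValueError(f"n must be positive, got {n}")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    img = slice_img.pixels
    pad = 0
    if img.shape[0] < patch_size or img.shape[1] < patch_size:
        pad = max(patch_size - img.shape[0], patch_size - img.shape[1])
        pad = (pad + 1) // 2
        img = np.pad(img, pad, mode="reflect")
        while img.shape[0] < patch_size or img.shape[1] < patch_size:
            img = np.pad(img, 1, mode="reflect")
            pad += 1
    rows = rng.integers(0, img.shape[0] - patch_size + 1, size=n)
    cols = rng.integers(0, img.shape[1] - patch_size + 1, size=n)
    patches, coords, augs = [], [], []
    for r, c in zip(rows, cols):
        crop = img[r:r + patch_size, c:c + patch_size]
        if augment:
            k = int(rng.integers(0, 4))
            flip_h = bool(rng.random() < 0.5)
            flip_v = bool(rng.random() < 0.5)
        else:
            k, flip_h, flip_v = 0, False, False
        patches.append(_augment(crop, k, flip_h, flip_v))
        coords.append((int(r), int(c)))
        augs.append((k, flip_h, flip_v))
    return PatchBatch(patches=np.stack(patches), coordinates=coords,
                      augmentations=augs, pad=pad)
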