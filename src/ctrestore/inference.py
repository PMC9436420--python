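"""Full-slice restoration by overlapped sliding-window prediction.

Slices are tiled with a fixed stride (default: half the tile, i.e. 50 %
overlap), each tile is pushed through the trained generator, and the tile
outputs are combined by a weighted average — uniform weights (plain mean
over covering tiles) by default, or a Gaussian centre-weighted profile.
The final tile position along each axis is clamped into bounds, so no
synthetic border content is ever fed to the network.  After assembly the
slice is clipped to [0, 1] and the unit-interval map inverted back to HU.
"""

from __future__ import annotations

import numpy as np

from .io import HUVolume, RunConfig
from .model import Generator, generator_forward
from .preprocess import NormalizedImage, denormalize, normalize_hu

__all__ = ["TileAccumulator", "tile_positions", "restore_slice",
           "restore_volume"]


def tile_positions(height: int, width: int, tile: int, stride: int):
    """Row-major list of top-left tile corners covering every pixel.

    Positions advance by `stride`; the last position on each axis is
    clamped so the tile stays in bounds.
    """
    if stride > tile:
        raise ValueError(f"stride {stride} exceeds tile {tile} (gaps would "
                         "leave pixels uncovered)")
    if stride <= 0:
        raise ValueError(f"stride must be positive, got {stride}")
    if tile > height or tile > width:
        raise ValueError(f"tile {tile} exceeds image {height}x{width}")

    def axis_positions(extent):
        pos = list(range(0, extent - tile + 1, stride))
        if pos[-1] != extent - tile:
            pos.append(extent - tile)
        return pos

    return [(r, c) for r in axis_positions(height) for c in axis_positions(width)]


def _weight_window(tile: int, profile: str) -> np.ndarray:
    if profile == "uniform":
        return np.ones((tile, tile))
    if profile == "gaussian":
        ax = np.arange(tile) - (tile - 1) / 2.0
        sigma = tile / 4.0
        g = np.exp(-(ax ** 2) / (2 * sigma ** 2))
        w = np.outer(g, g)
        return np.maximum(w, 1e-3)   # every pixel keeps positive weight
    raise ValueError(f"unknown weight profile {profile!r}")


class TileAccumulator:
    """Accumulates weighted tile outputs into a slice-sized buffer."""

    def __init__(self, height: int, width: int, tile: int, stride: int,
                 profile: str = "uniform"):
        self.tile, self.stride = tile, stride
        self.window = _weight_window(tile, profile)
        self.values = np.zeros((height, width))
        self.weights = np.zeros((height, width))

    def add(self, position, tile_output: np.ndarray):
        r, c = position
        self.values[r:r + self.tile, c:c + self.tile] += \
            self.window * tile_output
        self.weights[r:r + self.tile, c:c + self.tile] += self.window

    def finalize(self) -> np.ndarray:
        if not (self.weights > 0).all():
            raise RuntimeError("internal error: uncovered pixel in tiling")
        return self.values / self.weights


def restore_slice(G_A: Generator, slice_img: NormalizedImage, tile: int = 256,
                  stride: int = 128, profile: str = "uniform",
                  batch_tiles: int = 4) -> NormalizedImage:
    """Sliding-window restoration of one normalized slice."""
    img = slice_img.pixels
    H, W = img.shape
    pad_h = max(0, tile - H)
    pad_w = max(0, tile - W)
    if pad_h or pad_w:
        img = np.pad(img, [(0, pad_h), (0, pad_w)], mode="reflect")
    Hp, Wp = img.shape
    positions = tile_positions(Hp, Wp, tile, stride)
    acc = TileAccumulator(Hp, Wp, tile, stride, profile)
    for start in range(0, len(positions), batch_tiles):
        chunk = positions[start:start + batch_tiles]
        batch = np.stack([img[r:r + tile, c:c + tile] for r, c in chunk])
        outputs = generator_forward(G_A, batch)
        for pos, out in zip(chunk, outputs):
            acc.add(pos, out)
    restored = np.clip(acc.finalize()[:H, :W], 0.0, 1.0)
    return NormalizedImage(pixels=restored, offset=slice_img.offset,
                           scale=slice_img.scale, source=slice_img.source,
                           slice_index=slice_img.slice_index)


def restore_volume(G_A: Generator, vol: HUVolume,
                   config: RunConfig | None = None) -> HUVolume:
    """Normalize, restore and de-normalize every slice of a volume.

    Geometry (spacing, origin, orientation, slice count) is copied from the
    input; output HU lie within the normalization window [−1000, 1800].
    """
    cfg = config if config is not None else RunConfig()
    out = np.empty_like(vol.voxels)
    for k in range(vol.n_slices):
        norm = normalize_hu(vol.voxels[k], cfg.norm_offset, cfg.window_width,
                            slice_index=k)
        restored = restore_slice(G_A, norm, tile=cfg.patch_size,
                                 stride=cfg.stride,
                                 profile=cfg.weight_profile)
        out[k] = denormalize(restored)
    return HUVolume(voxels=out, spacing=vol.spacing, origin=vol.origin,
                    orientation=vol.orientation)
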