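"""Content-noise generators and PatchGAN discriminators.

The generator runs two branches in parallel on the same input slice:

* a *noise branch* — a residual encoder/decoder (7×7 stem, two stride-2
  3×3 downsamplers, 9 residual blocks, two stride-2 transposed-conv
  upsamplers, 7×7 head) that specializes in predicting the noise/artifact
  content;
* a *content branch* — a skip-connected encoder/decoder (U-Net) with a
  stride-2 4×4 stem, up to 7 stride-2 down/up units and a transposed-conv
  head, specializing in the underlying anatomy.

A fusion head reconstructs the output from the two branches with a 1×1
convolution over the concatenation of the *noise-corrected input* ``x − n̂``
and the content prediction ``ĉ``.  The fusion weights start at (1, 0) with
zero bias, so a freshly built generator is a near-identity map (the noise
branch initially predicts almost-zero noise) and training refines it toward
a denoiser — zeroing the content weight leaves a pure residual
noise-subtracting predictor, zeroing the noise weight leaves a pure
skip-connected content predictor.  The fusion output is linear (no
squashing); clipping to [0, 1] happens only at inference assembly.

The discriminator is the 70×70-receptive-field patch discriminator: three
stride-2 4×4 convolutions (64→128→256 channels), a stride-1 4×4 layer to
512 and a stride-1 4×4 projection to one channel, emitting a spatial map
of real/fake scores (30×30 for a 256×256 input).

Channel widths scale linearly with ``base_channels`` (64 reproduces the
published architecture; smaller bases give desk-scale variants with the
identical topology).  The content-branch depth is capped so the bottleneck
never collapses below one pixel for the configured patch size.
"""

from __future__ import annotations

import numpy as np

from .nn import (Conv2d, ConvTranspose2d, InstanceNorm2d, LeakyReLU,
                 Module, ReflectionPad2d, ReLU, Sequential, Tensor, concat,
                 no_grad)
from .preprocess import PatchBatch

__all__ = ["Generator", "Discriminator", "build_generator",
           "build_discriminator", "generator_forward", "discriminator_forward",
           "content_depth_for"]


def content_depth_for(patch_size: int, max_depth: int = 7) -> int:
    """Number of U-Net down units after the stride-2 stem.

    Capped so the bottleneck stays at least 1×1: the stem plus ``d`` down
    units shrink the side by 2^(d+1).
    """
    d = int(np.log2(patch_size)) - 1
    return max(1, min(max_depth, d))


class ResidualBlock(Module):
    def __init__(self, ch, *, rng, init_std):
        self.body = Sequential(
            ReflectionPad2d(1),
            Conv2d(ch, ch, 3, rng=rng, init_std=init_std),
            InstanceNorm2d(), ReLU(),
            ReflectionPad2d(1),
            Conv2d(ch, ch, 3, rng=rng, init_std=init_std),
            InstanceNorm2d(),
        )

    def forward(self, x):
        return x + self.body(x)


class NoiseBranch(Module):
    """Residual encoder/decoder specializing in the noise component."""

    def __init__(self, base, n_blocks, *, rng, init_std):
        b = base
        self.net = Sequential(
            ReflectionPad2d(3),
            Conv2d(1, b, 7, rng=rng, init_std=init_std),
            InstanceNorm2d(), ReLU(),
            Conv2d(b, b, 3, stride=2, padding=1, rng=rng, init_std=init_std),
            InstanceNorm2d(), ReLU(),
            Conv2d(b, 2 * b, 3, stride=2, padding=1, rng=rng, init_std=init_std),
            InstanceNorm2d(), ReLU(),
            *[ResidualBlock(2 * b, rng=rng, init_std=init_std)
              for _ in range(n_blocks)],
            ConvTranspose2d(2 * b, 4 * b, 3, stride=2, padding=1,
                            output_padding=1, rng=rng, init_std=init_std),
            InstanceNorm2d(), ReLU(),
            ConvTranspose2d(4 * b, 2 * b, 3, stride=2, padding=1,
                            output_padding=1, rng=rng, init_std=init_std),
            InstanceNorm2d(), ReLU(),
            ReflectionPad2d(3),
            Conv2d(2 * b, 1, 7, rng=rng, init_std=init_std),
        )

    def forward(self, x):
        return self.net(x)


class ContentBranch(Module):
    """Skip-connected encoder/decoder specializing in anatomy content."""

    def __init__(self, base, depth, *, rng, init_std):
        mults = [1, 2, 4, 8, 8, 8, 8, 8]
        chans = [base * m for m in mults[:depth + 1]]
        self.depth = depth
        self.stem = Conv2d(1, chans[0], 4, stride=2, padding=1,
                           rng=rng, init_std=init_std)
        self.downs, self.down_norms = [], []
        for i in range(depth):
            self.downs.append(Conv2d(chans[i], chans[i + 1], 4, stride=2,
                                     padding=1, rng=rng, init_std=init_std))
            # innermost feature map can be 1x1: spatial statistics degenerate
            self.down_norms.append(InstanceNorm2d() if i < depth - 1 else None)
        self.ups = []
        for i in range(depth):
            in_ch = chans[depth - i] if i == 0 else 2 * chans[depth - i]
            self.ups.append(ConvTranspose2d(in_ch, chans[depth - i - 1], 4,
                                            stride=2, padding=1,
                                            rng=rng, init_std=init_std))
        self.head = ConvTranspose2d(2 * chans[0], 1, 4, stride=2, padding=1,
                                    rng=rng, init_std=init_std)
        self.lrelu = LeakyReLU(0.2)
        self.relu = ReLU()
        self.norm = InstanceNorm2d()

    def forward(self, x):
        skips = [self.stem(x)]
        h = skips[0]
        for i, down in enumerate(self.downs):
            h = down(self.lrelu(h))
            if self.down_norms[i] is not None:
                h = self.norm(h)
            skips.append(h)
        h = skips[-1]
        for i, up in enumerate(self.ups):
            h = self.norm(up(self.relu(h)))
            h = concat([h, skips[self.depth - i - 1]], axis=1)
        return self.head(self.relu(h))


class Generator(Module):
    """Two-branch content-noise generator with a linear 1×1 fusion head."""

    def __init__(self, *, role: str = "A2B", base_channels: int = 64,
                 n_res_blocks: int = 9, patch_size: int = 256,
                 seed: int = 0, init_std: float = 0.02):
        if init_std <= 0:
            raise ValueError("init_std must be > 0")
        rng = np.random.default_rng(seed)
        self.role = role
        self.base_channels = base_channels
        self.depth = content_depth_for(patch_size)
        self.field = 2 ** (self.depth + 1)   # spatial divisibility requirement
        self.noise_branch = NoiseBranch(base_channels, n_res_blocks,
                                        rng=rng, init_std=init_std)
        self.content_branch = ContentBranch(base_channels, self.depth,
                                            rng=rng, init_std=init_std)
        self.fusion = Conv2d(2, 1, 1, rng=rng, init_std=init_std)
        # identity-at-start fusion: pass the noise-corrected input through
        self.fusion.weight.data[:] = 0.0
        self.fusion.weight.data[0, 0, 0, 0] = 1.0
        self.fusion.bias.data[:] = 0.0

    def forward(self, x: Tensor) -> Tensor:
        denoised = x - self.noise_branch(x)
        content = self.content_branch(x)
        return self.fusion(concat([denoised, content], axis=1))


class Discriminator(Module):
    """70×70-receptive-field patch discriminator emitting a score map."""

    def __init__(self, *, role: str = "D_B", base_channels: int = 64,
                 seed: int = 0, init_std: float = 0.02):
        if init_std <= 0:
            raise ValueError("init_std must be > 0")
        rng = np.random.default_rng(seed)
        self.role = role
        b = base_channels
        self.net = Sequential(
            Conv2d(1, b, 4, stride=2, padding=1, rng=rng, init_std=init_std),
            LeakyReLU(0.2),
            Conv2d(b, 2 * b, 4, stride=2, padding=1, rng=rng, init_std=init_std),
            InstanceNorm2d(), LeakyReLU(0.2),
            Conv2d(2 * b, 4 * b, 4, stride=2, padding=1, rng=rng,
                   init_std=init_std),
            InstanceNorm2d(), LeakyReLU(0.2),
            Conv2d(4 * b, 8 * b, 4, stride=1, padding=1, rng=rng,
                   init_std=init_std),
            InstanceNorm2d(), LeakyReLU(0.2),
            Conv2d(8 * b, 1, 4, stride=1, padding=1, rng=rng, init_std=init_std),
        )

    def forward(self, x: Tensor) -> Tensor:
        return self.net(x)


# ------------------------------------------------------------- functional API
def build_generator(seed: int = 0, init_std: float = 0.02, *,
                    role: str = "A2B", base_channels: int = 64,
                    n_res_blocks: int = 9, patch_size: int = 256) -> Generator:
    return Generator(role=role, base_channels=base_channels,
                     n_res_blocks=n_res_blocks, patch_size=patch_size,
                     seed=seed, init_std=init_std)


def build_discriminator(seed: int = 0, init_std: float = 0.02, *,
                        role: str = "D_B",
                        base_channels: int = 64) -> Discriminator:
    return Discriminator(role=role, base_channels=base_channels, seed=seed,
                         init_std=init_std)


def _as_nchw(batch) -> np.ndarray:
    if isinstance(batch, PatchBatch):
        arr = batch.patches
    else:
        arr = np.asarray(batch, dtype=np.float64)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim == 3:
        arr = arr[:, None]
    if arr.ndim != 4 or arr.shape[1] != 1:
        raise ValueError(f"expected single-channel batch, got shape {arr.shape}")
    return arr


def _padded_forward(net: Module, batch, field: int) -> np.ndarray:
    """Forward with reflect-padding to the net's divisibility requirement."""
    arr = _as_nchw(batch)
    H, W = arr.shape[2], arr.shape[3]
    ph = (-H) % field
    pw = (-W) % field
    with no_grad():
        if ph or pw:
            arr = np.pad(arr, [(0, 0), (0, 0), (0, ph), (0, pw)],
                         mode="reflect")
        out = net(Tensor(arr)).data
    return out[:, 0, :H, :W]


def generator_forward(G: Generator, batch) -> np.ndarray:
    """Deterministic forward of a patch stack; returns (N, H, W)."""
    return _padded_forward(G, batch, G.field)


def discriminator_forward(D: Discriminator, batch) -> np.ndarray:
    """Score map for a patch stack; (N, h, w) with h=w=30 for 256 inputs."""
    arr = _as_nchw(batch)
    with no_grad():
        return D(Tensor(arr)).data[:, 0]
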