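"""Four-term adversarial training for the generator/discriminator quartet.

The total generator objective is

    L = L_adv(G_A, D_B) + L_adv(G_B, D_A)
        + lambda_cyc  * L_cyc(G_A, G_B)
        + lambda_iden * L_iden(G_A, G_B)

with L_cyc the L1 cycle-consistency penalty (A→B→A and B→A→B round trips
must reproduce the input) and L_iden the L1 identity penalty (each
generator must leave images of its own target domain unchanged).  Defaults
lambda_cyc = 20, lambda_iden = 0.5.

Two adversarial variants are provided: the least-squares form (default,
the stabiliser standard for this architecture family) and the logistic
form matching the printed min-max objective, in its non-saturating
generator version.  Discriminator updates draw fakes from a replay pool
of previously generated images (size 50; 0 disables it).

Within an iteration the generators are updated first, then both
discriminators.  A single master seed derives independent streams for
weight init, patch sampling and the replay pool.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .io import RunConfig
from .model import Discriminator, Generator, build_discriminator, build_generator
from .nn import Adam, Tensor, concat
from .preprocess import NormalizedImage, sample_patches

__all__ = ["LossWeights", "TrainState", "ImagePool", "adversarial_loss",
           "cycle_loss", "identity_loss", "total_generator_loss",
           "learning_rate", "train", "save_checkpoint", "load_checkpoint"]

CHECKPOINT_VERSION = 1


@dataclass
class LossWeights:
    lambda_cyc: float = 20.0
    lambda_iden: float = 0.5

    def __post_init__(self):
        if self.lambda_cyc < 0 or self.lambda_iden < 0:
            raise ValueError("loss weights must be nonnegative")


@dataclass
class TrainState:
    """Mutable state of a training run; history holds per-epoch mean losses."""

    epoch: int = 0
    lr: float = 2e-4
    history: list = field(default_factory=list)


# ------------------------------------------------------------------- losses
def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def adversarial_loss(scores_real, scores_fake, variant: str = "lsgan"):
    """Discriminator and generator adversarial losses from two score maps.

    least-squares: d = mean((real−1)²) + mean(fake²), g = mean((fake−1)²),
    on raw scores.  log: d = −mean log σ(real) − mean log(1−σ(fake)),
    g = −mean log σ(fake) (non-saturating).
    """
    real, fake = _as_tensor(scores_real), _as_tensor(scores_fake)
    if real.shape != fake.shape:
        raise ValueError(f"score map shapes differ: {real.shape} vs {fake.shape}")
    if variant in ("lsgan", "least_squares"):
        d = ((real - 1.0) ** 2).mean() + (fake ** 2).mean()
        g = ((fake - 1.0) ** 2).mean()
    elif variant == "log":
        eps = 1e-12
        d = -(real.sigmoid() + eps).log().mean() \
            - (1.0 - fake.sigmoid() + eps).log().mean()
        g = -(fake.sigmoid() + eps).log().mean()
    else:
        raise ValueError(f"unknown adversarial variant {variant!r}")
    return d, g


def cycle_loss(I_A, I_B, G_A, G_B):
    """Mean-L1 round-trip penalty: |I_A − G_B(G_A(I_A))| + |I_B − G_A(G_B(I_B))|."""
    a, b = _as_tensor(I_A), _as_tensor(I_B)
    return (a - G_B(G_A(a))).abs().mean() + (b - G_A(G_B(b))).abs().mean()


def identity_loss(I_A, I_B, G_A, G_B):
    """Mean-L1 same-domain penalty: |I_B − G_A(I_B)| + |I_A − G_B(I_A)|."""
    a, b = _as_tensor(I_A), _as_tensor(I_B)
    return (b - G_A(b)).abs().mean() + (a - G_B(a)).abs().mean()


def total_generator_loss(components, weights: LossWeights = LossWeights()):
    """Combine (g_adv_A, g_adv_B, cyc, iden) with the configured weights."""
    g_adv_a, g_adv_b, cyc, iden = components
    return g_adv_a + g_adv_b + weights.lambda_cyc * cyc \
        + weights.lambda_iden * iden


def learning_rate(epoch: int, base: float = 2e-4, constant_epochs: int = 150,
                  total_epochs: int = 250) -> float:
    """Constant at `base`, then linear decay reaching exactly 0 at the end."""
    if epoch < constant_epochs:
        return base
    decay_span = total_epochs - constant_epochs
    if decay_span <= 0:
        return 0.0
    return base * max(0.0, total_epochs - epoch) / decay_span


# -------------------------------------------------------------- replay pool
class ImagePool:
    """Replay pool of previously generated fakes for discriminator updates.

    With probability 1/2 a query swaps a stored image for the incoming one;
    size 0 passes inputs straight through.
    """

    def __init__(self, size: int, rng: np.random.Generator):
        self.size = size
        self.rng = rng
        self.images: list[np.ndarray] = []

    def query(self, batch: np.ndarray) -> np.ndarray:
        if self.size <= 0:
            return batch
        out = []
        for img in batch:
            if len(self.images) < self.size:
                self.images.append(img.copy())
                out.append(img)
            elif self.rng.random() < 0.5:
                idx = int(self.rng.integers(len(self.images)))
                out.append(self.images[idx].copy())
                self.images[idx] = img.copy()
            else:
                out.append(img)
        return np.stack(out)


# ------------------------------------------------------------- checkpointing
def save_checkpoint(path, G_A: Generator, G_B: Generator, D_A: Discriminator,
                    D_B: Discriminator, config: RunConfig, seed: int,
                    epoch: int) -> None:
    import dataclasses

    meta = {"version": CHECKPOINT_VERSION, "seed": int(seed),
            "epoch": int(epoch), "config": dataclasses.asdict(config)}
    arrays = {}
    for tag, net in (("gA", G_A), ("gB", G_B), ("dA", D_A), ("dB", D_B)):
        for i, arr in enumerate(net.state_arrays()):
            arrays[f"{tag}_{i}"] = arr
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path):
    """Rebuild the four networks and config from a checkpoint archive."""
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        if meta.get("version") != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta.get('version')}")
        cfg = RunConfig(**meta["config"])
        nets = {}
        for tag in ("gA", "gB", "dA", "dB"):
            arrs = []
            i = 0
            while f"{tag}_{i}" in z:
                arrs.append(z[f"{tag}_{i}"])
                i += 1
            nets[tag] = arrs
    kw = dict(base_channels=cfg.base_channels, init_std=cfg.init_std)
    G_A = build_generator(role="A2B", patch_size=cfg.patch_size,
                          n_res_blocks=cfg.n_res_blocks, **kw)
    G_B = build_generator(role="B2A", patch_size=cfg.patch_size,
                          n_res_blocks=cfg.n_res_blocks, **kw)
    D_A = build_discriminator(role="D_A", base_channels=cfg.base_channels,
                              init_std=cfg.init_std)
    D_B = build_discriminator(role="D_B", base_channels=cfg.base_channels,
                              init_std=cfg.init_std)
    for net, tag in ((G_A, "gA"), (G_B, "gB"), (D_A, "dA"), (D_B, "dB")):
        net.load_state_arrays(nets[tag])
    return G_A, G_B, D_A, D_B, cfg, meta


# ------------------------------------------------------------ training loop
def _coerce_slices(slices):
    out = []
    for s in slices:
        if isinstance(s, NormalizedImage):
            out.append(s)
        else:
            out.append(NormalizedImage(pixels=np.asarray(s, dtype=np.float64)))
    return out


def _draw_batch(slices, n, patch_size, rng):
    idx = rng.integers(0, len(slices), size=n)
    patches = [sample_patches(slices[i], patch_size, 1, augment=True, seed=rng)
               .patches[0] for i in idx]
    return np.stack(patches)[:, None]   # (N, 1, ps, ps)


def train(domain_A_slices, domain_B_slices, config: RunConfig,
          out_dir=None, log=None):
    """Unpaired adversarial training of the G_A/G_B/D_A/D_B quartet.

    Returns ``(networks, state)`` where ``networks`` is the tuple
    (G_A, G_B, D_A, D_B) and ``state.history`` holds per-epoch mean loss
    components.  Fully reproducible from ``config.seed`` on fixed hardware
    and thread settings.
    """
    from pathlib import Path

    config.validate()
    A = _coerce_slices(domain_A_slices)
    B = _coerce_slices(domain_B_slices)
    if not A or not B:
        raise ValueError("both domains must be non-empty")

    ss = np.random.SeedSequence(config.seed)
    s_init_ga, s_init_gb, s_init_da, s_init_db, s_data, s_pool = \
        [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(6)]

    kw = dict(base_channels=config.base_channels, init_std=config.init_std)
    G_A = build_generator(seed=s_init_ga, role="A2B",
                          patch_size=config.patch_size,
                          n_res_blocks=config.n_res_blocks, **kw)
    G_B = build_generator(seed=s_init_gb, role="B2A",
                          patch_size=config.patch_size,
                          n_res_blocks=config.n_res_blocks, **kw)
    D_A = build_discriminator(seed=s_init_da, role="D_A",
                              base_channels=config.base_channels,
                              init_std=config.init_std)
    D_B = build_discriminator(seed=s_init_db, role="D_B",
                              base_channels=config.base_channels,
                              init_std=config.init_std)

    rng = np.random.default_rng(s_data)
    pool_A = ImagePool(config.replay_pool, np.random.default_rng(s_pool))
    pool_B = ImagePool(config.replay_pool, np.random.default_rng(s_pool + 1))

    weights = LossWeights(config.lambda_cyc, config.lambda_iden)
    opt_G = Adam(G_A.parameters() + G_B.parameters(), lr=config.base_lr)
    opt_D = Adam(D_A.parameters() + D_B.parameters(), lr=config.base_lr)

    n_iter = math.ceil(max(len(A), len(B)) * config.patches_per_slice
                       / config.batch_size)
    state = TrainState(lr=config.base_lr)
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    for epoch in range(config.epochs):
        lr = learning_rate(epoch, config.base_lr, config.constant_epochs,
                           config.epochs)
        opt_G.lr = opt_D.lr = lr
        sums = dict(adv_A=0.0, adv_B=0.0, cyc=0.0, iden=0.0,
                    d_A=0.0, d_B=0.0)
        for _ in range(n_iter):
            a = Tensor(_draw_batch(A, config.batch_size, config.patch_size, rng))
            b = Tensor(_draw_batch(B, config.batch_size, config.patch_size, rng))

            # -- generator step ------------------------------------------
            # batch same-generator applications: G_B on [b, a] gives the
            # fake LDCT and the A-side identity; G_A on [a, fake_A, b]
            # gives the fake NDCT, B-side reconstruction and identity
            n = config.batch_size
            gb_out = G_B(concat([b, a], axis=0))
            fake_A, idt_A = gb_out[:n], gb_out[n:]
            ga_out = G_A(concat([a, fake_A, b], axis=0))
            fake_B, rec_B, idt_B = ga_out[:n], ga_out[n:2 * n], ga_out[2 * n:]
            rec_A = G_B(fake_B)
            g_adv_A = _gen_adv(D_B(fake_B), config.gan_loss)
            g_adv_B = _gen_adv(D_A(fake_A), config.gan_loss)
            cyc = (a - rec_A).abs().mean() + (b - rec_B).abs().mean()
            iden = (b - idt_B).abs().mean() + (a - idt_A).abs().mean()
            loss_G = total_generator_loss((g_adv_A, g_adv_B, cyc, iden),
                                          weights)
            if not np.isfinite(loss_G.item()):
                _abort(out_dir, G_A, G_B, D_A, D_B, config, epoch, state)
            opt_G.zero_grad()
            loss_G.backward()
            opt_G.step()

            # -- discriminator step --------------------------------------
            fb = pool_B.query(fake_B.data)
            fa = pool_A.query(fake_A.data)
            d_B_loss, _ = adversarial_loss(D_B(b), D_B(Tensor(fb)),
                                           config.gan_loss)
            d_A_loss, _ = adversarial_loss(D_A(a), D_A(Tensor(fa)),
                                           config.gan_loss)
            loss_D = d_A_loss + d_B_loss
            if not np.isfinite(loss_D.item()):
                _abort(out_dir, G_A, G_B, D_A, D_B, config, epoch, state)
            opt_D.zero_grad()
            loss_D.backward()
            opt_D.step()

            sums["adv_A"] += g_adv_A.item()
            sums["adv_B"] += g_adv_B.item()
            sums["cyc"] += cyc.item()
            sums["iden"] += iden.item()
            sums["d_A"] += d_A_loss.item()
            sums["d_B"] += d_B_loss.item()

        record = {k: v / n_iter for k, v in sums.items()}
        record.update(epoch=epoch, lr=lr)
        state.history.append(record)
        state.epoch = epoch + 1
        state.lr = lr
        if log is not None:
            log.write(json.dumps(record) + "\n")
            log.flush()
        if out_dir is not None and (
                (epoch + 1) % config.checkpoint_every == 0
                or epoch + 1 == config.epochs):
            save_checkpoint(out_dir / "checkpoint.npz", G_A, G_B, D_A, D_B,
                            config, config.seed, epoch + 1)

    return (G_A, G_B, D_A, D_B), state


def _gen_adv(fake_scores: Tensor, variant: str) -> Tensor:
    if variant in ("lsgan", "least_squares"):
        return ((fake_scores - 1.0) ** 2).mean()
    if variant == "log":
        return -(fake_scores.sigmoid() + 1e-12).log().mean()
    raise ValueError(f"unknown adversarial variant {variant!r}")


def _abort(out_dir, G_A, G_B, D_A, D_B, config, epoch, state):
    if out_dir is not None:
        save_checkpoint(out_dir / "diagnostic.npz", G_A, G_B, D_A, D_B,
                        config, config.seed, epoch)
    raise FloatingPointError(
        f"non-finite loss at epoch {epoch}; diagnostic snapshot "
        f"{'written' if out_dir is not None else 'not requested'}")
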