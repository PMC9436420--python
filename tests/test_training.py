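"""Loss closed forms, schedule, replay pool, and training-loop contracts."""

import math

import numpy as np
import pytest

from ctrestore.io import RunConfig
from ctrestore.nn import Tensor
from ctrestore.training import (ImagePool, LossWeights, adversarial_loss,
                                cycle_loss, identity_loss, learning_rate,
                                load_checkpoint, save_checkpoint,
                                total_generator_loss, train)


class TestAdversarialLoss:
    def test_log_variant_at_maximal_confusion(self):
        # raw scores 0 -> sigmoid 0.5 on both maps
        zeros = np.zeros((2, 5, 5))
        d, g = adversarial_loss(zeros, zeros, variant="log")
        assert d.item() == pytest.approx(-2.0 * math.log(0.5), rel=1e-5)
        assert g.item() == pytest.approx(-math.log(0.5), rel=1e-5)

    def test_least_squares_perfect_discriminator(self):
        d, g = adversarial_loss(np.ones((3, 4, 4)), np.zeros((3, 4, 4)),
                                variant="lsgan")
        assert d.item() == 0.0
        assert g.item() == 1.0

    def test_log_generator_loss_monotone_in_fake_score(self):
        losses = [adversarial_loss(np.zeros((1, 2, 2)),
                                   np.full((1, 2, 2), s), "log")[1].item()
                  for s in np.linspace(-3, 3, 13)]
        assert all(a > b for a, b in zip(losses, losses[1:]))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            adversarial_loss(np.zeros((1, 4, 4)), np.zeros((1, 5, 5)))


class _Affine:
    """Scalar affine 'generator' used as a hand-computable stand-in."""

    def __init__(self, shift):
        self.shift = shift

    def __call__(self, t):
        return t + self.shift


class TestCycleAndIdentity:
    def test_identity_generators_give_zero_losses(self, rng):
        ident = _Affine(0.0)
        a = Tensor(rng.random((2, 1, 4, 4)))
        b = Tensor(rng.random((2, 1, 4, 4)))
        assert cycle_loss(a, b, ident, ident).item() == 0.0
        assert identity_loss(a, b, ident, ident).item() == 0.0

    def test_exact_inverse_pair_has_zero_cycle_loss(self):
        a = Tensor(np.full((1, 1, 1, 1), 0.2))
        b = Tensor(np.full((1, 1, 1, 1), 0.5))
        loss = cycle_loss(a, b, _Affine(0.1), _Affine(-0.1))
        assert loss.item() == pytest.approx(0.0, abs=1e-7)

    def test_non_inverse_pair_hand_computed(self):
        a = Tensor(np.full((1, 1, 1, 1), 0.2))
        b = Tensor(np.full((1, 1, 1, 1), 0.5))
        # G_A adds 0.1, G_B identity: |0.2-0.3| + |0.5-0.6| = 0.2
        loss = cycle_loss(a, b, _Affine(0.1), _Affine(0.0))
        assert loss.item() == pytest.approx(0.2, abs=1e-6)

    def test_identity_loss_hand_computed(self):
        a = Tensor(np.full((1, 1, 1, 1), 0.2))
        b = Tensor(np.full((1, 1, 1, 1), 0.5))
        loss = identity_loss(a, b, _Affine(0.1), _Affine(-0.1))
        assert loss.item() == pytest.approx(0.2, abs=1e-6)

    def test_identity_loss_invariant_to_sample_order(self, rng):
        a = rng.random((4, 1, 3, 3))
        b = rng.random((4, 1, 3, 3))
        g = _Affine(0.05)
        l1 = identity_loss(Tensor(a), Tensor(b), g, g).item()
        l2 = identity_loss(Tensor(a[::-1].copy()), Tensor(b[::-1].copy()),
                           g, g).item()
        assert l1 == pytest.approx(l2, rel=1e-6)


class TestTotalLoss:
    def test_zero_components_give_zero(self):
        assert total_generator_loss((0.0, 0.0, 0.0, 0.0)) == 0.0

    def test_default_weights_hand_computed(self):
        assert total_generator_loss((1.0, 1.0, 0.1, 0.2)) \
            == pytest.approx(4.1, rel=1e-9)

    def test_zero_weights_reduce_to_adversarial_sum(self):
        w = LossWeights(lambda_cyc=0.0, lambda_iden=0.0)
        assert total_generator_loss((0.7, 0.3, 5.0, 9.0), w) \
            == pytest.approx(1.0)

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            LossWeights(lambda_cyc=-1.0)


class TestLearningRate:
    @pytest.mark.parametrize("epoch,expected", [
        (0, 2e-4), (149, 2e-4), (200, 1e-4), (250, 0.0), (225, 0.5e-4),
    ])
    def test_published_schedule(self, epoch, expected):
        assert learning_rate(epoch, 2e-4, 150, 250) \
            == pytest.approx(expected, abs=1e-12)

    def test_decay_is_linear_and_monotone(self):
        lrs = [learning_rate(e, 2e-4, 150, 250) for e in range(150, 251)]
        diffs = np.diff(lrs)
        assert np.allclose(diffs, diffs[0])
        assert lrs[-1] == 0.0


class TestImagePool:
    def test_disabled_pool_passes_through(self, rng):
        pool = ImagePool(0, rng)
        batch = rng.random((4, 1, 8, 8))
        assert np.array_equal(pool.query(batch), batch)

    def test_pool_fills_then_swaps(self, rng):
        pool = ImagePool(2, np.random.default_rng(0))
        for _ in range(10):
            out = pool.query(rng.random((2, 1, 4, 4)))
            assert out.shape == (2, 1, 4, 4)
        assert len(pool.images) == 2


def _toy_domains(rng, n=8, side=64):
    base = rng.random((side, side)) * 0.5 + 0.25
    A = [np.clip(base + rng.normal(0, 0.08, (side, side)), 0, 1)
         for _ in range(n)]
    B = [np.clip(base + rng.normal(0, 0.01, (side, side)), 0, 1)
         for _ in range(n)]
    return A, B


class TestTrainLoop:
    def _config(self, **kw):
        defaults = dict(patch_size=64, stride=32, epochs=2, constant_epochs=1,
                        base_channels=8, n_res_blocks=2, batch_size=4, seed=3,
                        checkpoint_every=2)
        defaults.update(kw)
        return RunConfig(**defaults)

    def test_smoke_run_writes_checkpoint_and_history(self, tmp_path, rng):
        A, B = _toy_domains(rng)
        cfg = self._config()
        nets, state = train(A, B, cfg, out_dir=tmp_path)
        assert (tmp_path / "checkpoint.npz").exists()
        assert len(state.history) == 2
        for rec in state.history:
            for key in ("adv_A", "adv_B", "cyc", "iden", "d_A", "d_B"):
                assert np.isfinite(rec[key])
                assert rec[key] >= 0.0

    def test_same_seed_reproduces_losses(self, rng):
        A, B = _toy_domains(rng)
        cfg = self._config(epochs=1)
        _, s1 = train(A, B, cfg)
        _, s2 = train(A, B, cfg)
        assert s1.history[0] == s2.history[0]

    def test_empty_domain_rejected(self, rng):
        with pytest.raises(ValueError):
            train([], [np.zeros((64, 64))], self._config())

    def test_huge_identity_weight_drives_identity_loss_down(self, rng):
        A, B = _toy_domains(rng, n=4, side=32)
        cfg = self._config(patch_size=32, stride=16, epochs=6,
                           constant_epochs=6, lambda_iden=1e4, lambda_cyc=0.0,
                           base_channels=4, n_res_blocks=1)
        _, state = train(A, B, cfg)
        assert state.history[-1]["iden"] < state.history[0]["iden"]

    def test_checkpoint_round_trip(self, tmp_path, rng):
        A, B = _toy_domains(rng, n=4)
        cfg = self._config(epochs=1)
        (G_A, G_B, D_A, D_B), _ = train(A, B, cfg, out_dir=tmp_path)
        save_checkpoint(tmp_path / "ck.npz", G_A, G_B, D_A, D_B, cfg,
                        cfg.seed, 1)
        G_A2, G_B2, D_A2, D_B2, cfg2, meta = load_checkpoint(tmp_path / "ck.npz")
        assert meta["epoch"] == 1
        assert cfg2.patch_size == cfg.patch_size
        for net, net2 in ((G_A, G_A2), (G_B, G_B2), (D_A, D_A2), (D_B, D_B2)):
            assert all(np.array_equal(a, b) for a, b in
                       zip(net.state_arrays(), net2.state_arrays()))
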