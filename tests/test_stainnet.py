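"""GAN building blocks: activations, losses, schedule, shapes, tiling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from holostain import color, stainnet
from holostain.stainnet import (Discriminator, GANConfig, Generator,
                                discriminator_loss, generator_loss, lrelu,
                                stain_tiled, total_variation, v_schedule)


class TestLRelu:
    @pytest.mark.parametrize("x,expected", [(2.0, 2.0), (-1.0, -0.1), (0.0, 0.0)])
    def test_closed_form(self, x, expected):
        assert lrelu(x) == pytest.approx(expected)

    @given(st.floats(-1e6, 1e6, allow_nan=False))
    @settings(deadline=None, max_examples=50)
    def test_piecewise_definition(self, x):
        y = float(lrelu(x))
        assert y == (x if x > 0 else pytest.approx(0.1 * x))


class TestLosses:
    @pytest.mark.parametrize("d_fake,d_real,expected",
                             [(0.0, 1.0, 0.0), (0.5, 0.5, 0.5), (1.0, 0.0, 2.0)])
    def test_discriminator_loss_closed_form(self, d_fake, d_real, expected):
        assert discriminator_loss(d_fake, d_real) == pytest.approx(expected)

    def test_discriminator_loss_zero_iff_perfect(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            df, dr = rng.random(2)
            loss = discriminator_loss(df, dr)
            assert loss >= 0
            assert (loss == 0) == (df == 0 and dr == 1)

    def test_generator_loss_vanishes_for_perfect_output(self):
        cfg = GANConfig()
        img = np.full((1, 3, 8, 8), 0.5)
        total, comps = generator_loss(img, img.copy(), 1.0, cfg)
        assert total == 0.0
        assert comps["l1"] == comps["tv"] == comps["adv"] == 0.0

    def test_generator_loss_hand_evaluated(self):
        """2×2 ramp image against itself with d_fake = 0.5."""
        cfg = GANConfig()  # λ = 0.02, α = 2000 defaults
        img = np.array([[[[0.0, 1.0], [0.0, 1.0]]]], dtype=float)
        img3 = np.repeat(img, 3, axis=1)
        # brute-force anisotropic TV oracle: mean |dh| + mean |dv|
        dh = np.abs(np.diff(img3, axis=-1))
        dv = np.abs(np.diff(img3, axis=-2))
        tv_oracle = dh.mean() + dv.mean()
        total, comps = generator_loss(img3, img3.copy(), 0.5, cfg)
        assert comps["tv"] == pytest.approx(tv_oracle)
        assert total == pytest.approx(0.02 * tv_oracle + 2000 * 0.25)

    def test_loss_linear_in_lambda_and_alpha(self):
        rng = np.random.default_rng(1)
        out = rng.random((2, 3, 8, 8))
        tgt = rng.random((2, 3, 8, 8))
        t1, c1 = generator_loss(out, tgt, 0.3, GANConfig(lambda_tv=0.02,
                                                         alpha_adv=2000))
        t2, _ = generator_loss(out, tgt, 0.3, GANConfig(lambda_tv=0.04,
                                                        alpha_adv=4000))
        assert t2 - t1 == pytest.approx(0.02 * c1["tv"] + 2000 * c1["adv"])

    def test_total_variation_of_constant_is_zero(self):
        assert total_variation(np.full((4, 4), 3.0)) == 0.0


class TestSchedule:
    @pytest.mark.parametrize("profile,iteration,expected",
                             [("liver", 0, 7), ("skin", 0, 7),
                              ("liver", 2500, 5), ("kidney", 0, 6)])
    def test_printed_profiles(self, profile, iteration, expected):
        assert v_schedule(iteration, GANConfig.profile(profile)) == expected

    def test_non_increasing_and_bounded(self):
        cfg = GANConfig.profile("liver")
        vals = [v_schedule(i, cfg) for i in range(0, 20000, 100)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))
        assert min(vals) == cfg.v_floor


class TestArchitecture:
    def test_generator_shapes(self):
        gen = Generator(base_channels=16, rng=np.random.default_rng(0))
        x = np.zeros((2, 1, 32, 32), dtype=np.float32)
        y = gen.forward(x, train=False)
        assert y.shape == (2, 3, 32, 32)

    def test_generator_first_block_channels(self):
        gen = Generator(base_channels=64, rng=np.random.default_rng(0))
        assert gen.down[0].c1.cout == 64
        # down-path channel progression 1 -> 64 -> 128 -> 256 -> 512
        assert [b.c1.cin for b in gen.down] == [1, 64, 128, 256]
        assert [b.c3.cout for b in gen.down] == [64, 128, 256, 512]

    def test_generator_rejects_indivisible_sizes(self):
        gen = Generator(base_channels=16, rng=np.random.default_rng(0))
        with pytest.raises(ValueError):
            gen.forward(np.zeros((1, 1, 24, 24), dtype=np.float32))

    def test_level4_feature_map_16x_smaller(self):
        gen = Generator(base_channels=16, rng=np.random.default_rng(0))
        x = np.random.default_rng(1).random((1, 1, 32, 32)).astype(np.float32)
        gen.forward(x, train=True)
        # bridge input spatial size = 32 / 2^4
        assert gen.bridge._xshape[2:] == (2, 2)

    def test_discriminator_output_and_pool_width(self):
        disc = Discriminator(base_channels=64, blocks=5,
                             rng=np.random.default_rng(0))
        assert disc.pooled_width == 64 * 2 ** 5 == 2048
        small = Discriminator(base_channels=4, blocks=3,
                              rng=np.random.default_rng(0))
        img = np.random.default_rng(1).random((3, 3, 32, 32)).astype(np.float32)
        p = small.forward(img, train=False)
        assert p.shape == (3, 1)
        assert np.all((p > 0) & (p < 1))

    def test_discriminator_rejects_wrong_channels(self):
        disc = Discriminator(base_channels=4, blocks=3,
                             rng=np.random.default_rng(0))
        with pytest.raises(ValueError):
            disc.forward(np.zeros((1, 1, 32, 32), dtype=np.float32))


class TestGradients:
    """Finite-difference directional checks of the hand-written backprop."""

    def test_generator_gradient(self):
        gen = Generator(base_channels=2, rng=np.random.default_rng(1))
        rng = np.random.default_rng(0)
        x = rng.standard_normal((2, 1, 16, 16)).astype(np.float32)
        tgt = rng.random((2, 3, 16, 16)).astype(np.float32)

        def loss():
            out = gen.forward(x, train=True)
            return float(np.mean((out - tgt) ** 2))

        for _, g in gen.params():
            g[...] = 0
        out = gen.forward(x, train=True)
        gen.backward((2 * (out - tgt) / tgt.size).astype(np.float32))
        params = gen.params()
        gnorm2 = sum(float((g ** 2).sum()) for _, g in params)
        eps = 1e-2 / np.sqrt(gnorm2)
        saved = [p.copy() for p, _ in params]
        for p, g in params:
            p += (eps * g).astype(np.float32)
        lp = loss()
        for (p, g), s in zip(params, saved):
            p[...] = s - (eps * g).astype(np.float32)
        lm = loss()
        for (p, _), s in zip(params, saved):
            p[...] = s
        assert (lp - lm) / (2 * eps) == pytest.approx(gnorm2, rel=0.02)

    def test_discriminator_gradient(self):
        disc = Discriminator(base_channels=4, blocks=3,
                             rng=np.random.default_rng(3))
        rng = np.random.default_rng(0)
        img = rng.standard_normal((2, 3, 16, 16)).astype(np.float32)

        def loss():
            d = disc.forward(img, train=True)
            return float(np.mean(d ** 2))

        for _, g in disc.params():
            g[...] = 0
        d = disc.forward(img, train=True)
        disc.backward((2 * d / len(d)).astype(np.float32))
        params = disc.params()
        gnorm2 = sum(float((g ** 2).sum()) for _, g in params)
        eps = 1e-2 / np.sqrt(gnorm2)
        saved = [p.copy() for p, _ in params]
        for p, g in params:
            p += (eps * g).astype(np.float32)
        lp = loss()
        for (p, g), s in zip(params, saved):
            p[...] = s - (eps * g).astype(np.float32)
        lm = loss()
        for (p, _), s in zip(params, saved):
            p[...] = s
        assert (lp - lm) / (2 * eps) == pytest.approx(gnorm2, rel=0.05)


class TestTraining:
    def test_fixed_seed_reproducible(self):
        from holostain import synthdata
        x, y = synthdata.make_gan_patches(12, patch=32, size=64, seed=7)
        cfg = GANConfig.profile("toy", seed=3, max_iter=8, eval_every=4)
        _, _, h1 = stainnet.train(x[:10], y[:10], x[10:], y[10:], cfg)
        _, _, h2 = stainnet.train(x[:10], y[:10], x[10:], y[10:], cfg)
        assert h1["gen_total"] == h2["gen_total"]
        assert h1["val_l1"] == h2["val_l1"]

    def test_empty_dataset_rejected(self):
        cfg = GANConfig.profile("toy")
        empty = np.zeros((0, 1, 32, 32), dtype=np.float32)
        with pytest.raises(ValueError):
            stainnet.train(empty, np.zeros((0, 3, 32, 32), dtype=np.float32),
                           empty, empty, cfg)


class TestTiling:
    @staticmethod
    def _stub(patch):
        return np.dstack([np.full_like(patch, 0.6),
                          np.full_like(patch, 0.5),
                          np.full_like(patch, 0.5)])

    def test_four_tiles_stitch_to_3456(self):
        phase = np.zeros((3584, 3584), dtype=np.float32)
        out = stain_tiled(phase, self._stub, tile=1792, overlap=128)
        assert out.shape == (3456, 3456, 3)

    def test_constant_model_blends_exactly(self):
        phase = np.random.default_rng(0).random((3584, 3584)).astype(np.float32)
        out = stain_tiled(phase, self._stub, tile=1792, overlap=128)
        np.testing.assert_allclose(out[..., 0], 0.6, atol=1e-12)

    def test_single_tile_equals_direct_pass(self):
        gen = Generator(base_channels=16, rng=np.random.default_rng(2))
        phase = np.random.default_rng(1).random((64, 64)).astype(np.float32)
        tiled = stain_tiled(phase, gen, tile=64, overlap=16)
        direct = stainnet.generator_forward(phase.astype(np.float32), gen)
        np.testing.assert_allclose(tiled, direct, atol=1e-6)

    def test_small_image_falls_back_to_whole_pass(self):
        gen = Generator(base_channels=16, rng=np.random.default_rng(2))
        phase = np.random.default_rng(1).random((100, 100)).astype(np.float32)
        out = stain_tiled(phase, gen, tile=1792, overlap=128)
        assert out.shape == (100, 100, 3)


class TestColorRoundTrip:
    def test_rgb_ycbcr_round_trip_within_one_level(self):
        rng = np.random.default_rng(0)
        rgb = rng.integers(0, 256, size=(16, 16, 3)).astype(np.uint8)
        back = color.ycbcr_to_rgb8(color.rgb8_to_ycbcr(rgb))
        assert np.abs(back.astype(int) - rgb.astype(int)).max() <= 1
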