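"""Four-step cross-modality registration."""

import numpy as np
import pytest
from skimage.transform import rotate

from holostain import registration, stainnet, synthdata
from holostain.registration import (NoMatchError, coarse_match, crop_border,
                                    elastic_register, rotation_align,
                                    train_rough_network)


@pytest.fixture(scope="module")
def scene():
    cfg = synthdata.SynthConfig(size=320, seed=11, texture_scale=6.0)
    phi = synthdata.make_phase_object(cfg)
    stain = synthdata.make_stain_target(phi, cfg.phase_max)
    return phi, stain


class TestCrop:
    def test_step1_crop_4096_to_3584(self):
        img = np.zeros((4096, 4096), dtype=np.uint8)
        assert crop_border(img, 256).shape == (3584, 3584)

    def test_step2_crop_3584_to_3456(self):
        img = np.zeros((3584, 3584), dtype=np.uint8)
        assert crop_border(img, 64).shape == (3456, 3456)

    def test_oversized_crop_rejected(self):
        with pytest.raises(ValueError):
            crop_border(np.zeros((64, 64)), 40)


class TestCoarseMatch:
    def test_exact_copy_found_exactly(self, scene):
        phi, stain = scene
        pair = synthdata.make_misregistered_pair(
            phi, stain, offset=(40, 25), angle_deg=0.0, warp_amp=0.0,
            margin=96, seed=5)
        _, off, score = coarse_match(phi, pair.wsi, crop_px=32)
        truth = pair.true_map(np.array([[160.0, 160.0]]))[0] - 128
        assert np.allclose(off, truth, atol=0.51)
        assert score > 0.05

    def test_rotated_recolored_embedding_within_20px(self, scene):
        phi, stain = scene
        pair = synthdata.make_misregistered_pair(
            phi, stain, offset=(40, 25), angle_deg=10.0, warp_amp=0.0,
            margin=96, seed=5)
        _, off, _ = coarse_match(phi, pair.wsi, crop_px=32)
        truth = pair.true_map(np.array([[160.0, 160.0]]))[0] - 128
        assert np.hypot(*(np.array(off) - truth)) < 20.0

    def test_unrelated_wsi_raises_no_match(self, scene):
        phi, _ = scene
        flat = np.full((512, 512, 3), 230, dtype=np.uint8)
        with pytest.raises(NoMatchError):
            coarse_match(phi, flat, crop_px=32)


class TestRotationAlign:
    def test_already_aligned_pair_recovers_identity(self, scene):
        phi, stain = scene
        phase_t = crop_border(phi, 32)
        bf = crop_border(stain.astype(float), 32)
        _, _, _, info = rotation_align(phase_t, bf, crop_px=16)
        assert abs(info["angle_deg"]) < 0.05

    def test_known_rotation_recovered_within_a_tenth_degree(self, scene):
        phi, stain = scene
        phase_t = crop_border(phi, 32)
        bf = crop_border(stain.astype(float), 32)
        bf_rot = np.stack([rotate(bf[..., i], 2.0, preserve_range=True,
                                  mode="edge") for i in range(3)], axis=-1)
        _, _, _, info = rotation_align(phase_t, bf_rot, crop_px=16)
        assert abs(info["angle_deg"]) == pytest.approx(2.0, abs=0.1)

    def test_crop_sizes(self, scene):
        phi, stain = scene
        phase_t = crop_border(phi, 32)
        A, phase_c, bf_c, _ = rotation_align(phase_t,
                                             crop_border(stain.astype(float), 32),
                                             crop_px=16)
        assert phase_c.shape == (224, 224)
        assert bf_c.shape == (224, 224, 3)
        assert A.shape == (2, 3)


class TestRoughNetwork:
    def test_iteration_count_honored_and_three_channels(self, scene):
        phi, stain = scene
        gen, hist = train_rough_network([(phi, stain)], n_iter=30)
        assert hist["stopped_at"] == 30
        out = stainnet.generator_forward(
            phi[:64, :64].astype(np.float32), gen)
        assert out.shape == (64, 64, 3)

    def test_rough_output_correlates_with_target(self, toy_gan, scene):
        """A briefly trained generator already tracks target luminance."""
        from holostain.color import luminance, rgb8_to_ycbcr, ycbcr_to_rgb8

        phi, stain = scene
        gen, hist = train_rough_network([(phi, stain)], n_iter=150)
        out = stainnet.stain_tiled(phi, gen, tile=336, overlap=16,
                                   phase_range=(0.0, 1.0))
        lum_out = luminance(ycbcr_to_rgb8(out).astype(float))
        lum_tgt = luminance(stain.astype(float))
        r = np.corrcoef(lum_out.ravel(), lum_tgt.ravel())[0, 1]
        assert r > 0.5

    def test_no_pairs_rejected(self):
        with pytest.raises(ValueError):
            train_rough_network([], n_iter=10)


class TestElastic:
    def test_identical_images_give_zero_field(self, scene):
        _, stain = scene
        img = stain.astype(float)
        disp, warped = elastic_register(img, img, block=64, search=8)
        assert np.abs(disp).max() < 0.1
        # sub-0.01-px residual shifts only perturb values via interpolation
        np.testing.assert_allclose(warped, img, atol=0.5)

    def test_smooth_warp_recovered(self, scene):
        phi, stain = scene
        pair = synthdata.make_misregistered_pair(
            phi, stain, offset=(0, 0), angle_deg=0.0, warp_amp=4.0,
            margin=0, seed=9)
        disp, _ = elastic_register(pair.wsi.astype(float),
                                   stain.astype(float), block=64, search=8)
        # truth: content of fixed pixel p sits at p + E(p) in the moving
        truth = pair.disp_field
        err = np.linalg.norm(disp - truth, axis=-1)
        assert err.mean() < 1.0

    def test_constant_image_gets_zero_displacement(self):
        flat = np.full((128, 128), 50.0)
        disp, _ = elastic_register(flat, flat, block=64, search=8)
        np.testing.assert_allclose(disp, 0.0, atol=1e-9)

    def test_block_larger_than_image_rejected(self):
        with pytest.raises(ValueError):
            elastic_register(np.zeros((32, 32)), np.zeros((32, 32)),
                             block=64, search=8)


class TestFullPipeline:
    def test_known_corruption_recovered_below_one_pixel(self, registration_result):
        _, _, residual = registration_result
        assert residual.mean() < 1.0

    def test_aligned_pair_shapes_consistent(self, registration_result):
        _, aligned, _ = registration_result
        assert aligned.phase.shape == aligned.brightfield.shape[:2]
        assert aligned.displacement.shape == aligned.phase.shape + (2,)
        assert np.all(np.isfinite(aligned.displacement))
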