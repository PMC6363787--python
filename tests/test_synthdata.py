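"""Contracts of the synthetic-data generators."""

import numpy as np
import pytest

from holostain import synthdata
from holostain.synthdata import (SynthConfig, make_gan_patches,
                                 make_hologram_stack, make_misregistered_pair,
                                 make_phase_object, make_psr_frames,
                                 make_stain_target)


class TestPhaseObject:
    def test_range_clamped_to_phase_max(self):
        cfg = SynthConfig(size=128, phase_max=1.0, seed=0)
        phi = make_phase_object(cfg)
        assert phi.min() >= 0.0
        assert phi.max() <= 1.0

    def test_fixed_seed_deterministic(self):
        cfg = SynthConfig(size=96, seed=4)
        np.testing.assert_array_equal(make_phase_object(cfg),
                                      make_phase_object(cfg))

    @pytest.mark.parametrize("ts", [6.0, 8.0, 12.0])
    def test_autocorrelation_width_tracks_texture_scale(self, ts):
        cfg = SynthConfig(size=256, seed=5, texture_scale=ts)
        phi = make_phase_object(cfg)
        p = phi - phi.mean()
        ac = np.fft.ifft2(np.abs(np.fft.fft2(p)) ** 2).real
        ac /= ac[0, 0]
        width = int(np.argmax(ac[0, :128] < 1 / np.e))
        assert abs(width - ts) / ts < 0.3

    def test_phase_max_validated(self):
        with pytest.raises(ValueError):
            SynthConfig(phase_max=4.0)


class TestStainTarget:
    def test_zero_phase_is_white(self):
        rgb = make_stain_target(np.zeros((32, 32)))
        assert np.all(rgb == 255)

    def test_deterministic(self):
        phi = make_phase_object(SynthConfig(size=64, seed=1))
        np.testing.assert_array_equal(make_stain_target(phi),
                                      make_stain_target(phi))

    def test_channel_means_decrease_with_phase_strength(self):
        base = make_phase_object(SynthConfig(size=128, seed=3, phase_max=1.0))
        means = []
        for scale in (0.25, 0.5, 1.0):
            rgb = make_stain_target(base * scale)
            means.append(rgb.mean(axis=(0, 1)))
        means = np.array(means)
        assert np.all(np.diff(means, axis=0) < 0)


class TestHologramStack:
    def test_zero_phase_gives_unit_intensity(self):
        cfg = SynthConfig(size=64, seed=0)
        stack = make_hologram_stack(np.zeros((64, 64)), cfg)
        for holo in stack.intensities:
            np.testing.assert_allclose(holo, 1.0, atol=1e-9)

    def test_deterministic_without_noise(self):
        cfg = SynthConfig(size=64, seed=2, noise_sigma=0.0)
        phi = make_phase_object(cfg)
        a = make_hologram_stack(phi, cfg)
        b = make_hologram_stack(phi, cfg)
        for x, y in zip(a.intensities, b.intensities):
            np.testing.assert_array_equal(x, y)

    def test_configured_geometry(self):
        cfg = SynthConfig(size=64, seed=0, n_heights=8, z2_start=800.0,
                          z2_step=15.0)
        stack = make_hologram_stack(make_phase_object(cfg), cfg)
        assert len(stack.intensities) == 8
        np.testing.assert_allclose(np.diff(stack.z2_list), 15.0)
        assert stack.optics.pixel_pitch == pytest.approx(1.12 / 3)


class TestPsrFrames:
    def test_grid_produces_36_frames(self):
        cfg = SynthConfig(size=96, seed=1)
        frames, _ = make_psr_frames(make_phase_object(cfg), cfg)
        assert len(frames) == 36

    def test_zero_offset_frame_is_plain_downsampling(self):
        cfg = SynthConfig(size=96, seed=1)
        frames, hr = make_psr_frames(make_phase_object(cfg), cfg)
        plain = hr.reshape(32, 3, 32, 3).mean(axis=(1, 3))
        np.testing.assert_allclose(frames.frames[0], plain)

    def test_deterministic(self):
        cfg = SynthConfig(size=96, seed=6)
        phi = make_phase_object(cfg)
        a, _ = make_psr_frames(phi, cfg)
        b, _ = make_psr_frames(phi, cfg)
        np.testing.assert_array_equal(a.frames[7], b.frames[7])


class TestMisregisteredPair:
    def test_fixture_deterministic(self):
        phi = make_phase_object(SynthConfig(size=96, seed=2))
        stain = make_stain_target(phi)
        a = make_misregistered_pair(phi, stain, seed=3)
        b = make_misregistered_pair(phi, stain, seed=3)
        np.testing.assert_array_equal(a.wsi, b.wsi)

    def test_true_map_identity_when_untransformed(self):
        phi = make_phase_object(SynthConfig(size=96, seed=2))
        stain = make_stain_target(phi)
        pair = make_misregistered_pair(phi, stain, offset=(0, 0), angle_deg=0.0,
                                       warp_amp=0.0, margin=32, seed=1)
        pts = np.array([[10.0, 20.0], [50.0, 70.0]])
        np.testing.assert_allclose(pair.true_map(pts), pts + 32.0, atol=1e-9)

    def test_warp_amplitude_bounded(self):
        phi = make_phase_object(SynthConfig(size=96, seed=2))
        stain = make_stain_target(phi)
        pair = make_misregistered_pair(phi, stain, warp_amp=4.0, seed=8)
        mag = np.linalg.norm(pair.disp_field, axis=-1)
        assert mag.max() == pytest.approx(4.0, rel=1e-6)

    def test_out_of_range_transform_warns(self):
        phi = make_phase_object(SynthConfig(size=64, seed=2))
        stain = make_stain_target(phi)
        with pytest.warns(UserWarning):
            make_misregistered_pair(phi, stain, offset=(0, 0), angle_deg=15.0,
                                    margin=32, seed=1)


class TestGanPatches:
    def test_counts_shapes_and_range(self):
        x, y = make_gan_patches(20, patch=32, size=64, seed=0)
        assert x.shape == (20, 1, 32, 32)
        assert y.shape == (20, 3, 32, 32)
        assert 0 <= x.min() and x.max() <= 1.0
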