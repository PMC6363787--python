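"""Shared fixtures.

Heavy artifacts (the trained desk-scale staining GAN, the simulated
hologram stacks) are session-scoped so the expensive computations run
once per test session.
"""

from __future__ import annotations

import numpy as np
import pytest

from holostain import phase_recovery, stainnet, synthdata


@pytest.fixture(scope="session")
def phase_object():
    """A 256² weak-phase object with the default study conditions."""
    cfg = synthdata.SynthConfig(size=256, seed=17)
    return cfg, synthdata.make_phase_object(cfg)


@pytest.fixture(scope="session")
def hologram_stack(phase_object):
    cfg, phi = phase_object
    return synthdata.make_hologram_stack(phi, cfg)


@pytest.fixture(scope="session")
def recovery(hologram_stack):
    return phase_recovery.multiheight_recover(hologram_stack, n_iter=30)


@pytest.fixture(scope="session")
def gan_data():
    """500 training + 100 held-out forward-model patch pairs."""
    x, y = synthdata.make_gan_patches(600, seed=100)
    return x[:500], y[:500], x[500:], y[500:]


@pytest.fixture(scope="session")
def toy_gan(gan_data):
    """The desk-scale staining GAN trained to its stopping rule."""
    xt, yt, xv, yv = gan_data
    cfg = stainnet.GANConfig.profile("toy", seed=1)
    gen, disc, hist = stainnet.train(xt, yt, xv[:20], yv[:20], cfg)
    return gen, disc, hist


@pytest.fixture(scope="session")
def misregistered_scene():
    """A phase image and the corrupted WSI hiding its stained twin."""
    cfg = synthdata.SynthConfig(size=448, seed=21, texture_scale=8.0)
    phi = synthdata.make_phase_object(cfg)
    stain = synthdata.make_stain_target(phi, cfg.phase_max)
    pair = synthdata.make_misregistered_pair(
        phi, stain, offset=(40.0, 25.0), angle_deg=2.0, warp_amp=4.0,
        margin=96, seed=5)
    return pair


@pytest.fixture(scope="session")
def registration_result(misregistered_scene, toy_gan):
    """Full 4-step pipeline run with the desk-scale rough model."""
    from holostain import registration

    gen, _, _ = toy_gan
    pair = misregistered_scene
    aligned = registration.register_pair(
        pair.phase, pair.wsi, phase_max=1.0, crop1=32, crop2=16,
        block=64, search=12, rough_model=gen)
    h, w = aligned.phase.shape
    rr, cc = np.meshgrid(np.arange(h, dtype=float),
                         np.arange(w, dtype=float), indexing="ij")
    full = np.stack([rr + 32 + 16, cc + 32 + 16], axis=-1).reshape(-1, 2)
    truth = pair.true_map(full).reshape(h, w, 2)
    residual = np.linalg.norm(aligned.coord_map - truth, axis=-1)
    return pair, aligned, residual


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
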