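"""Seeded synthetic-data generators for the whole pipeline.

Real inputs would be holograms of unstained tissue sections and whole
slide scans of the same sections after histochemical staining.  At desk
scale these are emulated by:

* weak-phase tissue-like objects — smooth periodic random textures plus
  sparse nucleus-like blobs, phase in [0, phase_max] radians with
  phase_max < π so no wrapping can occur;
* their in-line holograms at multiple sample-to-sensor distances and the
  subpixel-shifted low-resolution frame sets of the pixel
  super-resolution step;
* a deterministic phase → stain color forward model (Beer–Lambert
  absorption of two pseudo-chromophores derived from band-pass
  decompositions of the phase), giving GAN training an exactly known
  target;
* mis-registered pairs (offset + rotation + smooth elastic warp of the
  stained image embedded in a larger synthetic whole-slide canvas) with a
  closed-form ground-truth coordinate map for scoring the registration
  pipeline.

Textures are periodic (filtering wraps around), which makes unpadded FFT
propagation an exact forward model.  Every generator is a pure function
of its configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import ndimage

from .holography import ComplexField, OpticalConfig, propagate
from .phase_recovery import HologramStack
from .psr import LowResFrameSet

__all__ = ["SynthConfig", "make_phase_object", "make_stain_target",
           "make_hologram_stack", "make_psr_frames", "aperture_reference",
           "make_misregistered_pair", "MisregisteredPair"]


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the synthetic pipeline inputs.

    Defaults mirror the imaging conditions of the emulated instrument:
    eight heights 15 µm apart starting ~800 µm from the sensor, a 6×6
    subpixel shift grid on a 1.12 µm sensor with 3× super-resolution, and
    weak-phase objects bounded by 1 rad.
    """

    size: int = 256
    phase_max: float = 1.0
    texture_scale: float = 8.0
    n_heights: int = 8
    z2_start: float = 800.0
    z2_step: float = 15.0
    psr_grid: int = 6
    sensor_pitch: float = 1.12
    upsample_factor: int = 3
    wavelength: float = 0.550
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.phase_max < np.pi):
            raise ValueError("phase_max must lie in (0, π) to avoid wrapping")
        if self.n_heights < 2:
            raise ValueError("need at least two heights")

    @property
    def recon_pitch(self) -> float:
        return self.sensor_pitch / self.upsample_factor

    @property
    def z2_list(self) -> list[float]:
        return [self.z2_start + i * self.z2_step for i in range(self.n_heights)]

    @property
    def optics(self) -> OpticalConfig:
        return OpticalConfig(wavelength=self.wavelength,
                             pixel_pitch=self.recon_pitch,
                             z2_list=tuple(self.z2_list),
                             z2_step=self.z2_step)


def make_phase_object(cfg: SynthConfig) -> np.ndarray:
    """Weak-phase tissue-like object, radians in [0, phase_max].

    The object is edge-sparse, like a thin tissue section: a
    low-amplitude smooth periodic random background plus sparse
    nucleus-like discs with ~1 px sigmoid rims.  The sharp sparse rims
    are what holographic autofocusing keys on; a dense Gaussian texture
    has a scale-invariant gradient histogram and carries almost no focus
    information.  The overall correlation length tracks
    ``texture_scale`` (1/e half-width of the autocorrelation).
    """
    rng = np.random.default_rng(cfg.seed)
    sigma = cfg.texture_scale / 2.0
    base = ndimage.gaussian_filter(rng.standard_normal((cfg.size, cfg.size)),
                                   cfg.texture_scale, mode="wrap")
    n_blobs = max(6, (cfg.size // 24) ** 2)
    rows = np.arange(cfg.size)
    blob = np.zeros_like(base)
    for _ in range(n_blobs):
        cy, cx = rng.uniform(0, cfg.size, 2)
        radius = rng.uniform(0.8, 1.6) * sigma
        # periodic distance keeps the texture wrap-around smooth
        dy = np.minimum(np.abs(rows - cy), cfg.size - np.abs(rows - cy))
        dx = np.minimum(np.abs(rows - cx), cfg.size - np.abs(rows - cx))
        r = np.sqrt(dy[:, None] ** 2 + dx[None, :] ** 2)
        blob += 1.0 / (1.0 + np.exp((r - radius) / 0.7))
    phi = (0.25 * base / (np.abs(base).max() + 1e-12)
           + np.clip(blob, 0.0, 1.2))
    phi -= phi.min()
    phi *= cfg.phase_max / phi.max()
    return phi


# Beer–Lambert absorption vectors of the two pseudo-chromophores (per RGB
# channel): a hematoxylin-like stain absorbing green/red and an eosin-like
# counterstain.  Fixed constants so the mapping is deterministic.
_ABS_1 = np.array([0.55, 1.00, 0.30])
_ABS_2 = np.array([0.10, 0.80, 0.45])


def _chromophores(phi: np.ndarray, phase_max: float) -> tuple[np.ndarray, np.ndarray]:
    # short-range reflect-mode filters: the stain of an image region is
    # fully determined by that region (plus a few pixels of margin), and
    # the resulting color maps are smooth — both properties keep the
    # patch-wise learning problem well-posed at reduced network capacity
    phi_n = np.asarray(phi, dtype=np.float64) / phase_max
    c1 = ndimage.gaussian_filter(phi_n, 2.0, mode="reflect")
    band = phi_n - ndimage.gaussian_filter(phi_n, 3.0, mode="reflect")
    c2 = ndimage.gaussian_filter(np.abs(band), 2.0, mode="reflect") * 1.5
    return c1, c2


def make_stain_target(phi: np.ndarray, phase_max: float = 1.0) -> np.ndarray:
    """Deterministic ground-truth virtual stain of a phase image.

    Optical density per channel is a fixed linear combination of two
    pseudo-chromophore maps derived from the phase; transmitted light
    decays exponentially from a white background.  Zero phase gives pure
    white; larger phase gives darker, stain-colored output.  Returns
    (H, W, 3) uint8 RGB.
    """
    c1, c2 = _chromophores(phi, phase_max)
    od = c1[..., None] * _ABS_1 + c2[..., None] * _ABS_2
    rgb = np.exp(-1.6 * od)
    return np.clip(np.rint(rgb * 255.0), 0, 255).astype(np.uint8)


def make_hologram_stack(phi: np.ndarray, cfg: SynthConfig) -> HologramStack:
    """In-line holograms of exp(iφ) at each configured height.

    Optional additive Gaussian intensity noise (std ``noise_sigma``),
    clipped at zero.  Periodic propagation (no padding) is exact for the
    periodic synthetic textures.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    optics = cfg.optics
    fld = ComplexField(np.exp(1j * np.asarray(phi, dtype=np.float64)),
                       optics.pixel_pitch, optics.wavelength)
    intensities = []
    for z2 in cfg.z2_list:
        holo = propagate(fld, z2, pad=False).intensity
        if cfg.noise_sigma > 0:
            holo = np.clip(holo + rng.normal(0, cfg.noise_sigma, holo.shape),
                           0.0, None)
        intensities.append(holo)
    return HologramStack(intensities=intensities, z2_list=cfg.z2_list,
                         optics=optics)


def make_psr_frames(phi: np.ndarray, cfg: SynthConfig,
                    z2: float | None = None
                    ) -> tuple[LowResFrameSet, np.ndarray]:
    """Shifted low-resolution hologram frames plus the high-res source.

    The fine-pitch hologram is computed on the reconstruction grid, the
    content is shifted for every position of the ``psr_grid`` ×
    ``psr_grid`` stage pattern (subpixel spacing 1/upsample_factor sensor
    pixels), and each shifted hologram is box-averaged over
    upsample_factor² pixel blocks — emulating G1-pixel integration on the
    Bayer sensor.  Returns the frame set (with ground-truth shifts as
    nominal_shifts) and the high-resolution hologram.
    """
    k = cfg.upsample_factor
    if phi.shape[0] % k or phi.shape[1] % k:
        raise ValueError("phase size must be divisible by upsample_factor")
    optics = cfg.optics
    fld = ComplexField(np.exp(1j * np.asarray(phi, dtype=np.float64)),
                       optics.pixel_pitch, optics.wavelength)
    hr = propagate(fld, z2 if z2 is not None else cfg.z2_start, pad=False).intensity
    frames, shifts = [], []
    ny, nx = hr.shape[0] // k, hr.shape[1] // k
    for i in range(cfg.psr_grid):
        for j in range(cfg.psr_grid):
            shifted = np.roll(hr, shift=(i, j), axis=(0, 1))
            lr = shifted.reshape(ny, k, nx, k).mean(axis=(1, 3))
            frames.append(lr)
            shifts.append((i / k, j / k))
    return (LowResFrameSet(frames=frames, nominal_shifts=shifts,
                           pitch=cfg.sensor_pitch, upsample_factor=k), hr)


def aperture_reference(hr: np.ndarray, k: int = 3) -> np.ndarray:
    """High-res image seen through the k×k sensor pixel aperture.

    Shift-and-add fusion of box-integrated frames recovers the source
    convolved with the pixel aperture; this is the exact oracle for the
    fused output.
    """
    return ndimage.uniform_filter(np.asarray(hr, dtype=np.float64), size=k,
                                  mode="wrap")


def make_gan_patches(n: int, patch: int = 32, size: int = 256,
                     phase_max: float = 1.0, texture_scale: float = 8.0,
                     seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Paired (phase, YCbCr stain) patches for staining-network training.

    Phase objects are generated (seeds ``seed``, ``seed+1``, …) and cut
    into non-overlapping ``patch``-sized tiles; the ground-truth stain is
    computed per tile (the forward model is local, so a tile fully
    determines its own stain).  Returns x (n, 1, patch, patch) in [0, 1]
    and y (n, 3, patch, patch) YCbCr in [0, 1], float32.
    """
    from .color import rgb8_to_ycbcr

    xs, ys = [], []
    k = 0
    while len(xs) < n:
        cfg = SynthConfig(size=size, phase_max=phase_max,
                          texture_scale=texture_scale, seed=seed + k)
        k += 1
        phi = make_phase_object(cfg)
        for r in range(0, size - patch + 1, patch):
            for c in range(0, size - patch + 1, patch):
                if len(xs) >= n:
                    break
                tile = phi[r:r + patch, c:c + patch]
                ycc = rgb8_to_ycbcr(make_stain_target(tile, phase_max))
                xs.append(tile / phase_max)
                ys.append(np.moveaxis(ycc, -1, 0))
    x = np.asarray(xs, dtype=np.float32)[:, None]
    y = np.asarray(ys, dtype=np.float32)
    return x, y


# ---------------------------------------------------------------------------
# mis-registered pair fixture


def _rotation(angle_deg: float, center: np.ndarray):
    th = np.deg2rad(angle_deg)
    M = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])

    def fwd(p_rc: np.ndarray) -> np.ndarray:
        return (p_rc - center) @ M.T + center

    def inv(q_rc: np.ndarray) -> np.ndarray:
        return (q_rc - center) @ M + center

    return fwd, inv


@dataclass
class MisregisteredPair:
    """Synthetic phase/WSI pair with known corruption transforms.

    ``true_map`` sends full-frame phase-pixel coordinates (row, col) to
    the whole-slide-image coordinates where the matching stained content
    sits: q = Rot(p + offset) + E(p + offset), with E the smooth elastic
    displacement field.
    """

    phase: np.ndarray
    stain: np.ndarray
    wsi: np.ndarray
    offset: tuple[float, float]
    angle_deg: float
    warp_amp: float
    disp_field: np.ndarray  # (H, W, 2) on the canvas grid
    canvas_center: np.ndarray
    true_map: Callable[[np.ndarray], np.ndarray] = field(repr=False, default=None)


def make_misregistered_pair(phi: np.ndarray, stain: np.ndarray,
                            offset: tuple[float, float] = (40.0, 25.0),
                            angle_deg: float = 2.0, warp_amp: float = 4.0,
                            margin: int = 96, seed: int = 0,
                            warp_scale: float | None = None) -> MisregisteredPair:
    """Embed a stained image in a larger warped canvas with known truth.

    The stained image is pasted at ``offset`` into a canvas filled with
    stain-textured background (emulating surrounding tissue on the
    slide), which is then rotated by ``angle_deg`` about its center and
    elastically warped by a smooth random displacement field of maximum
    magnitude ``warp_amp`` px.  The forward coordinate map is closed-form
    (see :class:`MisregisteredPair`); the warped canvas itself is built
    by numerically inverting that map, so interpolation error affects
    only pixel values, never the ground-truth coordinates.
    """
    if abs(angle_deg) > 10 or warp_amp > 8:
        import warnings
        warnings.warn("transforms outside the registration capture range",
                      stacklevel=2)
    stain = np.asarray(stain)
    h, w = stain.shape[:2]
    H, W = h + 2 * margin, w + 2 * margin
    # background: stained texture of an unrelated phase object, so the
    # canvas looks like surrounding tissue rather than bare glass
    bg_size = int(np.ceil(max(H, W) / 2.0) * 2)
    bg_phi = make_phase_object(SynthConfig(size=bg_size, seed=seed + 10_001))
    canvas = make_stain_target(bg_phi)[:H, :W].astype(np.float64)
    # the paste grid is integer; the effective offset is the rounded one
    r0, c0 = int(round(offset[0])) + margin, int(round(offset[1])) + margin
    offset = (float(r0 - margin), float(c0 - margin))
    if r0 < 0 or c0 < 0 or r0 + h > H or c0 + w > W:
        raise ValueError("offset places the stained image outside the canvas")
    canvas[r0:r0 + h, c0:c0 + w] = stain

    rng = np.random.default_rng(seed)
    sig = warp_scale if warp_scale is not None else H / 8.0
    E = np.stack([ndimage.gaussian_filter(rng.standard_normal((H, W)), sig)
                  for _ in range(2)], axis=-1)
    mag = np.linalg.norm(E, axis=-1).max()
    if mag > 0 and warp_amp > 0:
        E *= warp_amp / mag
    else:
        E[...] = 0.0

    center = np.array([(H - 1) / 2.0, (W - 1) / 2.0])
    rot_fwd, rot_inv = _rotation(angle_deg, center)

    def interp_E(pts: np.ndarray) -> np.ndarray:
        return np.stack([ndimage.map_coordinates(E[..., i], pts.T, order=1,
                                                 mode="nearest")
                         for i in range(2)], axis=-1)

    def true_map(p_full: np.ndarray) -> np.ndarray:
        """Full-frame phase coords (N, 2) -> WSI coords (N, 2)."""
        c = np.atleast_2d(np.asarray(p_full, dtype=np.float64)) + \
            np.array([offset[0] + margin, offset[1] + margin])
        return rot_fwd(c) + interp_E(c)

    # build the WSI by inverting q = rot(c) + E(c) pointwise (fixed point)
    qq = np.stack(np.meshgrid(np.arange(H), np.arange(W), indexing="ij"),
                  axis=-1).reshape(-1, 2).astype(np.float64)
    c_est = rot_inv(qq)
    for _ in range(6):
        c_est = rot_inv(qq - interp_E(c_est))
    wsi = np.stack([ndimage.map_coordinates(canvas[..., i], c_est.T, order=1,
                                            mode="nearest").reshape(H, W)
                    for i in range(3)], axis=-1)
    wsi = np.clip(np.rint(wsi), 0, 255).astype(np.uint8)
    return MisregisteredPair(phase=np.asarray(phi, dtype=np.float64),
                             stain=stain, wsi=wsi,
                             offset=(float(offset[0]), float(offset[1])),
                             angle_deg=float(angle_deg),
                             warp_amp=float(warp_amp), disp_field=E,
                             canvas_center=center, true_map=true_map)
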