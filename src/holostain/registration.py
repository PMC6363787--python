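"""Four-step cross-modality registration of phase images to stained WSIs.

Training the staining network needs pixel-accurate pairs of a quantitative
phase image and the brightfield image of the same tissue after staining.
The two are acquired on different instruments, so alignment proceeds in
four steps:

1. **Coarse matching** — the whole-slide image (WSI) is bicubically
   downsampled to the phase pixel pitch, the phase image is cropped of its
   reconstruction padding (256 px per side: 4096² → 3584²), both are Canny
   edge-extracted, and normalized cross-correlation of the edge maps
   locates the matching WSI window.
2. **Rotation/affine alignment** — mutual-information-driven similarity
   registration (phase rescaled to 8-bit vs. brightfield luminance) gives
   an affine applied to the brightfield; both are cropped a further 64 px
   per side to absorb rotation margins.
3. **Rough staining network** — a generator with the staining
   architecture is trained briefly (~2000 iterations) on the globally
   aligned pairs; its output converts the phase image into the stain
   modality so the final step can compare like with like.
4. **Elastic registration** — block-wise normalized cross-correlation
   between the rough network output and the brightfield, with subpixel
   peak refinement and Gaussian smoothing, yields a dense displacement
   field that warps the brightfield onto the phase geometry.

Coordinates are 0-based (row, col), origin top-left; transforms map the
phase (fixed) grid into the moving image.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import SimpleITK as sitk
from scipy import ndimage
from skimage import feature, transform
from skimage.feature import match_template

from . import stainnet
from .color import luminance, rgb8_to_ycbcr, ycbcr_to_rgb8

__all__ = ["NoMatchError", "RegistrationFailureError", "AlignedPair",
           "crop_border", "coarse_match", "rotation_align",
           "train_rough_network", "elastic_register", "register_pair"]


class NoMatchError(RuntimeError):
    """Coarse matching found no window above the correlation threshold."""


class RegistrationFailureError(RuntimeError):
    """The intensity-based registration optimizer failed to converge."""


@dataclass
class AlignedPair:
    """A registered (phase, brightfield) training pair.

    ``brightfield`` is warped onto the phase grid; ``affine`` is the 2×3
    (row, col) matrix of step 2 mapping phase coordinates into the
    coarse-matched window; ``displacement`` the dense elastic field of
    step 4; ``coord_map`` the composite map sending each phase pixel of
    the final cropped grid to its (row, col) position in the
    pitch-matched WSI.
    """

    phase: np.ndarray
    brightfield: np.ndarray
    affine: np.ndarray
    displacement: np.ndarray
    coord_map: np.ndarray
    info: dict


def crop_border(img: np.ndarray, px: int) -> np.ndarray:
    """Symmetric border crop: a 4096² image with px=256 becomes 3584²."""
    if px == 0:
        return img
    if 2 * px >= min(img.shape[:2]):
        raise ValueError("crop larger than image")
    return img[px:-px, px:-px]


def _to_u8(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=np.float64)
    lo, hi = img.min(), img.max()
    if hi <= lo:
        return np.zeros(img.shape, dtype=np.uint8)
    return np.clip(np.rint((img - lo) / (hi - lo) * 255.0), 0, 255).astype(np.uint8)


def _canny(img_u8: np.ndarray, sigma: float = 2.0) -> np.ndarray:
    """Canny edges with median-based double thresholds."""
    g = ndimage.gaussian_filter(img_u8.astype(np.float64), sigma)
    med = np.median(np.abs(np.gradient(g)))
    lo, hi = 0.66 * med, 1.33 * med
    return feature.canny(img_u8.astype(np.float64), sigma=sigma,
                         low_threshold=lo, high_threshold=hi)


def coarse_match(phase: np.ndarray, wsi: np.ndarray,
                 wsi_pitch: float | None = None,
                 phase_pitch: float | None = None,
                 crop_px: int = 256, threshold: float = 0.05
                 ) -> tuple[np.ndarray, tuple[int, int], float]:
    """Locate the phase FOV inside the whole-slide image.

    Returns the matching WSI window (same size as the cropped phase
    image), its (row, col) offset in the pitch-matched WSI, and the peak
    normalized cross-correlation of the edge maps.
    """
    phase_t = crop_border(np.asarray(phase, dtype=np.float64), crop_px)
    if wsi_pitch is not None and phase_pitch is not None and wsi_pitch != phase_pitch:
        scale = wsi_pitch / phase_pitch
        wsi = transform.rescale(np.asarray(wsi, dtype=np.float64) / 255.0,
                                scale, order=3, channel_axis=-1,
                                anti_aliasing=scale < 1)
        wsi = np.clip(wsi * 255.0, 0, 255)
    lum = luminance(wsi)
    if lum.shape[0] < phase_t.shape[0] or lum.shape[1] < phase_t.shape[1]:
        raise ValueError("WSI smaller than the phase field of view")
    # smoothing the binary edge maps makes the correlation tolerant to the
    # small residual rotation that step 2 will remove
    e_phase = ndimage.gaussian_filter(_canny(_to_u8(phase_t)).astype(np.float64), 3.0)
    e_wsi = ndimage.gaussian_filter(_canny(_to_u8(lum)).astype(np.float64), 3.0)
    # small trial rotations of the template absorb residual slide rotation
    best = (-np.inf, 0, 0)
    for trial in (0.0, -5.0, 5.0, -10.0, 10.0):
        tmpl = e_phase if trial == 0 else transform.rotate(
            e_phase, trial, preserve_range=True, mode="edge")
        corr = match_template(e_wsi, tmpl)
        sc = float(corr.max())
        if sc > best[0]:
            rr, cc = np.unravel_index(int(corr.argmax()), corr.shape)
            best = (sc, int(rr), int(cc))
    score, r0, c0 = best
    if not np.isfinite(score) or score < threshold:
        raise NoMatchError(f"peak edge correlation {score:.3f} below "
                           f"threshold {threshold}")
    window = np.asarray(wsi)[r0:r0 + phase_t.shape[0], c0:c0 + phase_t.shape[1]]
    return window, (int(r0), int(c0)), score


def _sitk_affine_to_rc(tx: sitk.Transform) -> np.ndarray:
    """2×3 (row, col) matrix of a SimpleITK 2-D transform (index coords)."""
    o = np.array(tx.TransformPoint((0.0, 0.0)))
    ex = np.array(tx.TransformPoint((1.0, 0.0))) - o
    ey = np.array(tx.TransformPoint((0.0, 1.0))) - o
    # sitk points are (x, y) = (col, row); build the (row, col) form
    A = np.array([[ey[1], ex[1], o[1]],
                  [ey[0], ex[0], o[0]]])
    return A


def rotation_align(phase: np.ndarray, bf: np.ndarray, crop_px: int = 64,
                   full_affine: bool = False, n_iter: int = 300
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray, dict]:
    """Mutual-information similarity registration of a coarse-matched pair.

    Fixed image: the phase map rescaled to 8-bit; moving image: the
    brightfield luminance.  Mattes mutual information is optimized over a
    similarity transform (rotation + scale + translation; ``full_affine``
    unlocks shear) by regular-step gradient descent on a 3-level pyramid.
    The transform is applied to all brightfield channels, and both images
    are cropped ``crop_px`` per side (3584² → 3456² with the default 64).

    Returns (affine 2×3 row/col, phase cropped, warped brightfield
    cropped, info) where info carries the recovered rotation angle and
    the final metric value.
    """
    phase_u8 = _to_u8(phase)
    bf = np.asarray(bf, dtype=np.float64)
    lum_u8 = _to_u8(luminance(bf))
    fixed = sitk.GetImageFromArray(phase_u8.astype(np.float32))
    moving = sitk.GetImageFromArray(lum_u8.astype(np.float32))
    base = sitk.AffineTransform(2) if full_affine else sitk.Similarity2DTransform()
    init = sitk.CenteredTransformInitializer(
        fixed, moving, base, sitk.CenteredTransformInitializerFilter.GEOMETRY)
    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=50)
    reg.SetMetricSamplingStrategy(reg.NONE)  # dense and deterministic
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=1.0, minStep=1e-5, numberOfIterations=n_iter,
        relaxationFactor=0.6, gradientMagnitudeTolerance=1e-7)
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetShrinkFactorsPerLevel([4, 2, 1])
    reg.SetSmoothingSigmasPerLevel([2.0, 1.0, 0.0])
    reg.SetInitialTransform(init, inPlace=False)
    try:
        tx = reg.Execute(fixed, moving)
    except RuntimeError as exc:  # pragma: no cover - optimizer blow-up
        raise RegistrationFailureError(str(exc)) from exc

    A = _sitk_affine_to_rc(tx)
    angle = float(np.rad2deg(np.arctan2(A[1, 0] - 0.0, A[1, 1])))
    # resample every channel of the brightfield onto the phase grid
    chans = []
    for i in range(bf.shape[-1]):
        mv = sitk.GetImageFromArray(bf[..., i].astype(np.float32))
        res = sitk.Resample(mv, fixed, tx, sitk.sitkLinear, 255.0)
        chans.append(sitk.GetArrayFromImage(res))
    warped = np.stack(chans, axis=-1)
    info = {"angle_deg": angle,
            "metric": float(reg.GetMetricValue()),
            "stop": reg.GetOptimizerStopConditionDescription()}
    return (A, crop_border(np.asarray(phase, dtype=np.float64), crop_px),
            crop_border(warped, crop_px), info)


def train_rough_network(pairs: Sequence[tuple[np.ndarray, np.ndarray]],
                        n_iter: int = 2000,
                        cfg: stainnet.GANConfig | None = None
                        ) -> tuple[stainnet.Generator, dict]:
    """Train the staining generator briefly on globally aligned pairs.

    ``pairs`` holds (normalized phase in [0, 1], RGB uint8 brightfield)
    images.  Architecture and losses are those of the staining GAN;
    training runs for exactly ``n_iter`` iterations (early stopping
    disabled) so the network learns the coarse modality transfer without
    structurally altering content.
    """
    if len(pairs) < 1:
        raise ValueError("need at least one aligned pair")
    cfg = cfg or stainnet.GANConfig.profile("toy")
    cfg = replace(cfg, max_iter=n_iter, patience=n_iter + 1)
    xs, ys = [], []
    p = cfg.patch
    for phase, bf in pairs:
        ycc = rgb8_to_ycbcr(bf)
        h, w = phase.shape
        for r in range(0, h - p + 1, p // 2):
            for c in range(0, w - p + 1, p // 2):
                xs.append(phase[r:r + p, c:c + p])
                ys.append(np.moveaxis(ycc[r:r + p, c:c + p], -1, 0))
    x = np.asarray(xs, dtype=np.float32)[:, None]
    y = np.asarray(ys, dtype=np.float32)
    rng = np.random.default_rng(cfg.seed)
    n_val = max(1, len(x) // 10)
    idx = rng.permutation(len(x))
    gen, _, hist = stainnet.train(x[idx[n_val:]], y[idx[n_val:]],
                                  x[idx[:n_val]], y[idx[:n_val]], cfg)
    return gen, hist


def elastic_register(moving: np.ndarray, fixed: np.ndarray,
                     block: int = 128, search: int = 16,
                     smooth_sigma: float | None = None
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Block-matching elastic registration of same-modality images.

    For each ``block``×``block`` tile of ``fixed``, the best-matching
    position of the corresponding ``moving`` region is found by
    normalized cross-correlation within ±``search`` px and refined to
    subpixel precision by quadratic peak interpolation.  Degenerate
    (flat) tiles contribute zero displacement.  The sparse field is
    Gaussian-smoothed (σ = block/2 by default) and bilinearly
    interpolated to a dense per-pixel field d such that
    ``warped[p] = moving[p + d(p)]``.

    Returns (dense displacement field (H, W, 2), warped moving image).
    """
    moving = np.asarray(moving, dtype=np.float64)
    fixed = np.asarray(fixed, dtype=np.float64)
    if moving.shape[:2] != fixed.shape[:2]:
        raise ValueError("moving and fixed must share spatial shape")
    h, w = fixed.shape[:2]
    if block > min(h, w):
        raise ValueError("block larger than image")
    lum_m = luminance(moving) if moving.ndim == 3 else moving
    lum_f = luminance(fixed) if fixed.ndim == 3 else fixed
    pad = search + block
    lum_m_p = np.pad(lum_m, pad, mode="edge")

    centers_r = np.arange(block // 2, h - block // 2 + 1, block)
    centers_c = np.arange(block // 2, w - block // 2 + 1, block)
    disp = np.zeros((len(centers_r), len(centers_c), 2))
    b2 = block // 2
    for i, rr in enumerate(centers_r):
        for j, cc in enumerate(centers_c):
            tile = lum_f[rr - b2:rr + b2, cc - b2:cc + b2]
            if tile.std() < 1e-8:
                continue
            region = lum_m_p[rr - b2 - search + pad:rr + b2 + search + pad,
                             cc - b2 - search + pad:cc + b2 + search + pad]
            corr = match_template(region, tile)
            k = np.unravel_index(int(corr.argmax()), corr.shape)
            d = np.array(k, dtype=np.float64) - search
            for ax in range(2):
                kk = list(k)
                if 0 < k[ax] < corr.shape[ax] - 1:
                    kk[ax] = k[ax] - 1
                    cm = corr[tuple(kk)]
                    kk[ax] = k[ax] + 1
                    cp = corr[tuple(kk)]
                    c0 = corr[k]
                    den = cm - 2 * c0 + cp
                    if den < 0:
                        d[ax] += 0.5 * (cm - cp) / den
            disp[i, j] = d
    sigma = 0.5 if smooth_sigma is None else smooth_sigma / block
    if disp.shape[0] > 1 or disp.shape[1] > 1:
        for ax in range(2):
            disp[..., ax] = ndimage.gaussian_filter(disp[..., ax], sigma,
                                                    mode="nearest")
    # bilinear interpolation of the block grid to a dense field
    dense = np.empty((h, w, 2))
    rows = np.arange(h)
    cols = np.arange(w)
    gi = np.clip((rows - centers_r[0]) / block, 0, len(centers_r) - 1)
    gj = np.clip((cols - centers_c[0]) / block, 0, len(centers_c) - 1)
    GI, GJ = np.meshgrid(gi, gj, indexing="ij")
    for ax in range(2):
        dense[..., ax] = ndimage.map_coordinates(disp[..., ax],
                                                 [GI, GJ], order=1,
                                                 mode="nearest")
    RR, CC = np.meshgrid(rows.astype(np.float64), cols.astype(np.float64),
                         indexing="ij")
    coords = [RR + dense[..., 0], CC + dense[..., 1]]
    if moving.ndim == 3:
        warped = np.stack([ndimage.map_coordinates(moving[..., i], coords,
                                                   order=1, mode="nearest")
                           for i in range(moving.shape[-1])], axis=-1)
    else:
        warped = ndimage.map_coordinates(moving, coords, order=1, mode="nearest")
    return dense, warped


def register_pair(phase: np.ndarray, wsi: np.ndarray, *,
                  phase_max: float = 1.0, crop1: int = 256, crop2: int = 64,
                  block: int = 64, search: int = 12,
                  rough_model: stainnet.Generator | None = None,
                  rough_iters: int = 2000,
                  rough_cfg: stainnet.GANConfig | None = None,
                  wsi_pitch: float | None = None,
                  phase_pitch: float | None = None,
                  threshold: float = 0.05) -> AlignedPair:
    """Run the full four-step registration pipeline.

    Produces the brightfield image warped onto the (twice-cropped) phase
    grid together with the composite coordinate map used to audit the
    registration accuracy.  A pre-trained ``rough_model`` (e.g. a
    desk-scale staining generator) can stand in for step 3 to skip its
    training.
    """
    window, (r0, c0), score = coarse_match(phase, wsi, wsi_pitch, phase_pitch,
                                           crop_px=crop1, threshold=threshold)
    phase_t = crop_border(np.asarray(phase, dtype=np.float64), crop1)
    A, phase_c, bf_c, info = rotation_align(phase_t, window, crop_px=crop2)
    info.update({"coarse_offset": (r0, c0), "coarse_score": score})

    if rough_model is None:
        rough_model, _ = train_rough_network(
            [(phase_c / phase_max, bf_c.astype(np.uint8))],
            n_iter=rough_iters, cfg=rough_cfg)
    rough_ycc = stainnet.stain_tiled(phase_c, rough_model,
                                     tile=max(phase_c.shape) + 16,
                                     phase_range=(0.0, phase_max))
    rough_rgb = ycbcr_to_rgb8(rough_ycc)

    disp, bf_aligned = elastic_register(bf_c, rough_rgb.astype(np.float64),
                                        block=block, search=search)

    h, w = phase_c.shape
    RR, CC = np.meshgrid(np.arange(h, dtype=np.float64),
                         np.arange(w, dtype=np.float64), indexing="ij")
    pr = RR + crop2 + disp[..., 0]
    pc = CC + crop2 + disp[..., 1]
    wr = A[0, 0] * pr + A[0, 1] * pc + A[0, 2] + r0
    wc = A[1, 0] * pr + A[1, 1] * pc + A[1, 2] + c0
    coord_map = np.stack([wr, wc], axis=-1)
    return AlignedPair(phase=phase_c, brightfield=bf_aligned, affine=A,
                       displacement=disp, coord_map=coord_map, info=info)
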