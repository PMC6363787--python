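"""Evaluation: 3-channel SSIM and the spatially correlated phase-noise study.

The structural similarity index is computed per RGB channel with the
standard local-window product form and averaged over the three channels.
The noise study perturbs a quantitative phase image with Gaussian-smoothed
white noise,

    φ̃(m,n) = φ(m,n) + β · [r ⊛ G_L](m,n),   r ~ N(0,1) i.i.d.,

where G_L(m,n) = exp(−(m²+n²)/(2L²)) / (2πL²) is the printed smoothing
kernel (the pixel pitch Δ cancels inside the exponent), β the perturbation
coefficient and L the kernel width in pixels.  Pairs (β, L) chosen at
fixed phase SNR probe how the spatial scale of phase noise, rather than
its power, degrades the staining network's inference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage
from skimage.metrics import structural_similarity

__all__ = ["SSIMConstants", "NoiseParams", "ssim_color", "gaussian_kernel",
           "kernel_l2_norm", "add_phase_noise", "fixed_snr_pairs",
           "noise_robustness_study"]


@dataclass(frozen=True)
class SSIMConstants:
    """Stabilization constants c1 = (k1·L)², c2 = (k2·L)²."""

    k1: float = 0.01
    k2: float = 0.03
    data_range: float = 255.0

    @property
    def c1(self) -> float:
        return (self.k1 * self.data_range) ** 2

    @property
    def c2(self) -> float:
        return (self.k2 * self.data_range) ** 2


@dataclass(frozen=True)
class NoiseParams:
    """Phase-noise parameters: δφ = β · (r ⊛ G_L)."""

    beta: float
    L: float
    delta: float = 1.12 / 3  # pixel pitch, µm (cancels in the kernel)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError("beta must be non-negative")
        if self.L < 1:
            raise ValueError("L must be >= 1 pixel")
        if self.delta <= 0:
            raise ValueError("delta must be positive")


def ssim_color(u1: np.ndarray, u2: np.ndarray,
               consts: SSIMConstants | None = None,
               formula: str = "standard") -> float:
    """Mean SSIM over the three color channels of two images.

    Uses the standard product-form SSIM with local 11×11 Gaussian windows
    (σ = 1.5) per channel; ``formula="as_printed"`` instead evaluates the
    single-fraction variant (2μ₁μ₂ + 2σ₁₂ + c₂) / [(μ₁²+μ₂²+c₁)(σ₁²+σ₂²+c₂)]
    with the same windowing, kept for comparison only — it does not equal
    1 for identical images.
    """
    consts = consts or SSIMConstants()
    u1 = np.asarray(u1, dtype=np.float64)
    u2 = np.asarray(u2, dtype=np.float64)
    if u1.shape != u2.shape or u1.ndim != 3 or u1.shape[-1] != 3:
        raise ValueError("inputs must be identically shaped (H, W, 3) images")
    win = min(11, min(u1.shape[:2]))
    win -= 1 - win % 2  # largest odd window fitting the image
    if formula == "standard":
        vals = [structural_similarity(
            u1[..., i], u2[..., i], data_range=consts.data_range,
            gaussian_weights=True, sigma=1.5, win_size=win,
            use_sample_covariance=False, K1=consts.k1, K2=consts.k2)
            for i in range(3)]
        return float(np.mean(vals))
    if formula != "as_printed":
        raise ValueError("formula must be 'standard' or 'as_printed'")

    def smooth(img):
        return ndimage.gaussian_filter(img, sigma=1.5, truncate=3.5)

    c1, c2 = consts.c1, consts.c2
    vals = []
    for i in range(3):
        a, b = u1[..., i], u2[..., i]
        mu1, mu2 = smooth(a), smooth(b)
        s11 = smooth(a * a) - mu1 * mu1
        s22 = smooth(b * b) - mu2 * mu2
        s12 = smooth(a * b) - mu1 * mu2
        num = 2 * mu1 * mu2 + 2 * s12 + c2
        den = (mu1 ** 2 + mu2 ** 2 + c1) * (s11 + s22 + c2)
        vals.append(np.mean(num / den))
    return float(np.mean(vals))


def gaussian_kernel(L: float, truncate: float = 4.0) -> np.ndarray:
    """Discrete smoothing kernel exp(−(m²+n²)/(2L²)) / (2πL²), radius 4L.

    For L ≳ 1 the discrete sum approximates the unit continuous integral.
    """
    r = int(np.ceil(truncate * L))
    m = np.arange(-r, r + 1)
    g = np.exp(-(m[:, None] ** 2 + m[None, :] ** 2) / (2.0 * L ** 2))
    return g / (2.0 * np.pi * L ** 2)


def kernel_l2_norm(L: float) -> float:
    """ℓ2 norm of the discrete kernel: std of filtered unit white noise."""
    k = gaussian_kernel(L)
    return float(np.sqrt(np.sum(k ** 2)))


def add_phase_noise(phi: np.ndarray, params: NoiseParams,
                    rng: np.random.Generator | None = None) -> np.ndarray:
    """Return φ + β·(r ⊛ G_L) with i.i.d. standard-normal r.

    Raises if the perturbed phase would wrap (|φ̃| ≥ π), mirroring the
    no-wrapping guarantee of the study protocol.  With a fixed seed the
    perturbation is bit-reproducible.
    """
    phi = np.asarray(phi, dtype=np.float64)
    if not np.all(np.isfinite(phi)):
        raise ValueError("phase image must be finite")
    if params.beta == 0:
        return phi.copy()
    rng = rng or np.random.default_rng(params.seed)
    r = rng.standard_normal(phi.shape)
    dphi = params.beta * ndimage.convolve(r, gaussian_kernel(params.L),
                                          mode="wrap")
    out = phi + dphi
    if np.max(np.abs(out)) >= np.pi:
        raise ValueError("perturbation would cause phase wrapping (|φ̃| ≥ π)")
    return out


def fixed_snr_pairs(phi: np.ndarray, target_snr: float,
                    L_list: Sequence[float]) -> list[tuple[float, float]]:
    """Solve β for each L so that std(φ)/std(δφ) equals ``target_snr``.

    Uses the analytic relation std(δφ) = β·‖G_L‖₂ for filtered white
    noise.  ``target_snr = inf`` gives β = 0.
    """
    if len(L_list) == 0:
        raise ValueError("L_list must be non-empty")
    s = float(np.std(np.asarray(phi, dtype=np.float64)))
    if s == 0:
        raise ValueError("constant phase image has undefined SNR")
    out = []
    for L in L_list:
        if np.isinf(target_snr):
            out.append((0.0, float(L)))
        else:
            out.append((s / (target_snr * kernel_l2_norm(L)), float(L)))
    return out


def noise_robustness_study(phi: np.ndarray,
                           stain: Callable[[np.ndarray], np.ndarray],
                           pairs: Sequence[tuple[float, float]],
                           n_real: int = 10, seed: int = 0,
                           consts: SSIMConstants | None = None) -> list[dict]:
    """SSIM of the stained noisy phase against the stained clean phase.

    ``stain`` maps a phase image (radians) to an (H, W, 3) color image.
    For each (β, L) pair, ``n_real`` noise realizations are drawn, stained
    and compared (SSIM) with the clean-input output.  Returns one record
    per pair with mean and standard deviation of the SSIM and the measured
    phase SNR.
    """
    consts = consts or SSIMConstants(data_range=1.0)
    phi = np.asarray(phi, dtype=np.float64)
    ref = np.asarray(stain(phi), dtype=np.float64)
    s_phi = float(np.std(phi))
    rng = np.random.default_rng(seed)
    rows = []
    for beta, L in pairs:
        ssims, snrs = [], []
        for _ in range(n_real):
            noisy = add_phase_noise(phi, NoiseParams(beta=beta, L=L), rng=rng)
            snrs.append(np.inf if beta == 0 else s_phi / float(np.std(noisy - phi)))
            out = np.asarray(stain(noisy), dtype=np.float64)
            ssims.append(ssim_color(out, ref, consts))
        rows.append({"beta": float(beta), "L": float(L),
                     "ssim_mean": float(np.mean(ssims)),
                     "ssim_std": float(np.std(ssims)),
                     "snr_mean": float(np.mean(snrs)),
                     "ssim_values": [float(v) for v in ssims]})
    return rows
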