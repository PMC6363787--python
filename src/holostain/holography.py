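"""Scalar coherent optics: free-space propagation and in-line hologram formation.

The imaging model is an on-chip lensfree holographic microscope: a
quasi-plane wave illuminates a weakly scattering object (e.g. an unstained
thin tissue section) and the diffracted field is recorded by a bare CMOS
sensor a millimetre or two downstream.  Propagation between planes uses the
angular-spectrum (transfer function of free space) method, which is exact
for scalar diffraction on a sampled band-limited field.

All lengths are micrometres internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = ["OpticalConfig", "ComplexField", "propagate", "form_hologram"]


@dataclass(frozen=True)
class OpticalConfig:
    """Geometry and illumination of the lensfree setup.

    Parameters
    ----------
    wavelength:
        Illumination center wavelength in µm (default 0.550, green).
    pixel_pitch:
        Reconstruction-grid pitch in µm.  The physical sensor pitch is
        1.12 µm; pixel super-resolution synthesizes an effective pitch of
        1.12/3 ≈ 0.3733 µm, which is the default here.
    z2_list:
        Sample-to-sensor distances in µm, strictly increasing.
    z2_step:
        Nominal axial spacing between successive heights in µm.
    """

    wavelength: float = 0.550
    pixel_pitch: float = 1.12 / 3
    z2_list: tuple[float, ...] = field(default_factory=tuple)
    z2_step: float = 15.0

    SENSOR_PITCH: float = 1.12  # physical Bayer G1 pitch, µm

    def __post_init__(self) -> None:
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be positive")
        z2 = np.asarray(self.z2_list, dtype=float)
        if z2.size and np.any(np.diff(z2) <= 0):
            raise ValueError("z2_list must be strictly increasing")

    def with_heights(self, z2_list: Sequence[float]) -> "OpticalConfig":
        return replace(self, z2_list=tuple(float(z) for z in z2_list))


@dataclass
class ComplexField:
    """A sampled 2-D complex optical field with its grid metadata.

    ``values`` is dimensionless field amplitude (unit-amplitude plane-wave
    illumination convention), ``pitch`` and ``wavelength`` in µm.
    """

    values: np.ndarray
    pitch: float
    wavelength: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.complex128)
        if self.values.ndim != 2:
            raise ValueError("field must be 2-D")
        if any(s % 2 for s in self.values.shape):
            raise ValueError("field dimensions must be even (FFT-friendly)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("field contains non-finite values")
        if self.pitch is None or self.pitch <= 0:
            raise ValueError("pitch must be set and positive")
        if self.wavelength is None or self.wavelength <= 0:
            raise ValueError("wavelength must be set and positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def intensity(self) -> np.ndarray:
        return np.abs(self.values) ** 2

    @property
    def phase(self) -> np.ndarray:
        return np.angle(self.values)


def _transfer_function(shape: tuple[int, int], pitch: float, wavelength: float,
                       distance: float) -> np.ndarray:
    """Angular-spectrum transfer function with hard evanescent cutoff."""
    fy = np.fft.fftfreq(shape[0], d=pitch)
    fx = np.fft.fftfreq(shape[1], d=pitch)
    fx2 = (wavelength * fx[np.newaxis, :]) ** 2
    fy2 = (wavelength * fy[:, np.newaxis]) ** 2
    arg = 1.0 - fx2 - fy2
    prop = arg > 0.0  # evanescent components (fx²+fy² > 1/λ²) are dropped
    kz = np.sqrt(np.where(prop, arg, 0.0))
    H = np.exp(2j * np.pi / wavelength * distance * kz)
    return np.where(prop, H, 0.0)


def propagate(field: ComplexField, distance: float, *, pad: bool = True) -> ComplexField:
    """Propagate a field by a signed axial ``distance`` (µm).

    Uses the angular-spectrum method: FFT, multiply by the free-space
    transfer function exp(i 2π z √(1/λ² − fx² − fy²)), inverse FFT.
    Spatial frequencies beyond 1/λ (evanescent waves) are zeroed.  By
    default the field is zero-padded 2× per side before the transform to
    suppress periodic wrap-around, and cropped back afterwards.

    ``propagate(f, 0)`` returns a copy of ``f``;
    ``propagate(propagate(f, z), -z)`` recovers ``f`` for band-limited input.
    """
    if not np.isfinite(distance):
        raise ValueError("propagation distance must be finite")
    if distance == 0:
        return ComplexField(field.values.copy(), field.pitch, field.wavelength)
    v = field.values
    ny, nx = v.shape
    if pad:
        # edge padding avoids both periodic wrap-around and the spurious
        # aperture diffraction a zero border would introduce
        py, px = ny // 2, nx // 2
        v = np.pad(v, ((py, py), (px, px)), mode="edge")
    H = _transfer_function(v.shape, field.pitch, field.wavelength, distance)
    out = np.fft.ifft2(np.fft.fft2(v) * H)
    if pad:
        out = out[py:py + ny, px:px + nx]
    return ComplexField(out, field.pitch, field.wavelength)


def form_hologram(object_field: ComplexField, z2: float, *, pad: bool = True) -> np.ndarray:
    """In-line hologram intensity |P_z2{t}|² of a transmitted object field.

    ``object_field`` is the field just after the sample (unit plane wave
    times the object transmittance); ``z2`` is the sample-to-sensor
    distance in µm and must be positive.
    """
    if not np.isfinite(z2) or z2 <= 0:
        raise ValueError("z2 must be positive and finite")
    sensor = propagate(object_field, z2, pad=pad)
    return sensor.intensity
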