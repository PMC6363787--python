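"""Image and sidecar persistence: float/RGB TIFF plus JSON metadata."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .holography import ComplexField, OpticalConfig
from .phase_recovery import HologramStack
from .psr import LowResFrameSet

__all__ = ["write_phase", "read_phase", "write_rgb", "read_rgb",
           "write_stack", "read_stack", "write_frames", "read_frames",
           "write_field", "read_field", "write_json", "read_json"]


def write_json(path: str | Path, obj: dict) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True))


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def write_phase(path: str | Path, phase: np.ndarray) -> None:
    """Phase map (radians) as single-channel 32-bit float TIFF."""
    tifffile.imwrite(str(path), np.asarray(phase, dtype=np.float32))


def read_phase(path: str | Path) -> np.ndarray:
    return tifffile.imread(str(path)).astype(np.float64)


def write_rgb(path: str | Path, rgb8: np.ndarray) -> None:
    tifffile.imwrite(str(path), np.asarray(rgb8, dtype=np.uint8))


def read_rgb(path: str | Path) -> np.ndarray:
    return tifffile.imread(str(path))


def write_field(dirpath: str | Path, field: ComplexField,
                representation: str = "reim") -> None:
    """Complex field as paired 32-bit float TIFFs plus a JSON sidecar.

    ``representation`` selects real/imaginary ("reim") or
    amplitude/phase ("amp_phase") pairs.
    """
    if representation not in ("reim", "amp_phase"):
        raise ValueError("representation must be 'reim' or 'amp_phase'")
    dirpath = Path(dirpath)
    dirpath.mkdir(parents=True, exist_ok=True)
    if representation == "reim":
        a, b = field.values.real, field.values.imag
        names = ("real.tif", "imag.tif")
    else:
        a, b = np.abs(field.values), np.angle(field.values)
        names = ("amplitude.tif", "phase.tif")
    tifffile.imwrite(str(dirpath / names[0]), a.astype(np.float32))
    tifffile.imwrite(str(dirpath / names[1]), b.astype(np.float32))
    write_json(dirpath / "field.json", {
        "representation": representation,
        "pitch_um": field.pitch, "wavelength_um": field.wavelength})


def read_field(dirpath: str | Path) -> ComplexField:
    dirpath = Path(dirpath)
    meta = read_json(dirpath / "field.json")
    if meta["representation"] == "reim":
        v = (tifffile.imread(str(dirpath / "real.tif")).astype(np.float64)
             + 1j * tifffile.imread(str(dirpath / "imag.tif")).astype(np.float64))
    else:
        amp = tifffile.imread(str(dirpath / "amplitude.tif")).astype(np.float64)
        ph = tifffile.imread(str(dirpath / "phase.tif")).astype(np.float64)
        v = amp * np.exp(1j * ph)
    return ComplexField(v, meta["pitch_um"], meta["wavelength_um"])


def write_stack(dirpath: str | Path, stack: HologramStack) -> None:
    """Multi-page float TIFF of hologram intensities + JSON sidecar."""
    dirpath = Path(dirpath)
    dirpath.mkdir(parents=True, exist_ok=True)
    pages = np.stack([i.astype(np.float32) for i in stack.intensities])
    tifffile.imwrite(str(dirpath / "stack.tif"), pages)
    write_json(dirpath / "stack.json", {
        "z2_list_um": list(map(float, stack.z2_list)),
        "wavelength_um": stack.optics.wavelength,
        "pixel_pitch_um": stack.optics.pixel_pitch,
    })


def read_stack(dirpath: str | Path) -> HologramStack:
    dirpath = Path(dirpath)
    pages = tifffile.imread(str(dirpath / "stack.tif"))
    meta = read_json(dirpath / "stack.json")
    optics = OpticalConfig(wavelength=meta["wavelength_um"],
                           pixel_pitch=meta["pixel_pitch_um"],
                           z2_list=tuple(meta["z2_list_um"]))
    return HologramStack(intensities=[p.astype(np.float64) for p in pages],
                         z2_list=list(meta["z2_list_um"]), optics=optics)


def write_frames(dirpath: str | Path, frames: LowResFrameSet) -> None:
    """PSR frame set as multi-page TIFF + JSON shifts sidecar."""
    dirpath = Path(dirpath)
    dirpath.mkdir(parents=True, exist_ok=True)
    pages = np.stack([f.astype(np.float32) for f in frames.frames])
    tifffile.imwrite(str(dirpath / "frames.tif"), pages)
    write_json(dirpath / "frames.json", {
        "nominal_shifts_px": [list(map(float, s)) for s in frames.nominal_shifts],
        "pitch_um": frames.pitch,
        "upsample_factor": frames.upsample_factor,
    })


def read_frames(dirpath: str | Path) -> LowResFrameSet:
    dirpath = Path(dirpath)
    pages = tifffile.imread(str(dirpath / "frames.tif"))
    meta = read_json(dirpath / "frames.json")
    return LowResFrameSet(
        frames=[p.astype(np.float64) for p in pages],
        nominal_shifts=[tuple(s) for s in meta["nominal_shifts_px"]],
        pitch=meta["pitch_um"], upsample_factor=meta["upsample_factor"])
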