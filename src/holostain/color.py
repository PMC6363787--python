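"""RGB <-> YCbCr conversion (BT.601 full-range).

The staining network works in YCbCr (luma + two chroma channels); RGB is
used only at the I/O boundaries.  Channels are floats in [0, 1]; chroma is
stored offset by +0.5 so the working range stays [0, 1].
"""

from __future__ import annotations

import numpy as np

_FWD = np.array([[0.299, 0.587, 0.114],
                 [-0.168736, -0.331264, 0.5],
                 [0.5, -0.418688, -0.081312]])
_OFF = np.array([0.0, 0.5, 0.5])
_INV = np.linalg.inv(_FWD)


def rgb_to_ycbcr(rgb: np.ndarray) -> np.ndarray:
    """(..., 3) RGB in [0, 1] -> (..., 3) YCbCr in [0, 1]."""
    return np.asarray(rgb, dtype=np.float64) @ _FWD.T + _OFF


def ycbcr_to_rgb(ycc: np.ndarray) -> np.ndarray:
    """(..., 3) YCbCr in [0, 1] -> (..., 3) RGB (not clipped)."""
    return (np.asarray(ycc, dtype=np.float64) - _OFF) @ _INV.T


def rgb8_to_ycbcr(rgb8: np.ndarray) -> np.ndarray:
    """uint8 RGB image -> float YCbCr in [0, 1]."""
    return rgb_to_ycbcr(np.asarray(rgb8, dtype=np.float64) / 255.0)


def ycbcr_to_rgb8(ycc: np.ndarray) -> np.ndarray:
    """float YCbCr in [0, 1] -> uint8 RGB, clipped and rounded."""
    rgb = ycbcr_to_rgb(ycc)
    return np.clip(np.rint(rgb * 255.0), 0, 255).astype(np.uint8)


def luminance(rgb: np.ndarray) -> np.ndarray:
    """Luma channel of an RGB image in its native scale."""
    return np.asarray(rgb, dtype=np.float64) @ _FWD[0]
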