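"""Reconstruction quality metrics.

SSIM follows the original windowed formulation: an 11x11 Gaussian window
(sigma 1.5), K1 = 0.01, K2 = 0.03, dynamic range 255, no sample-covariance
correction, averaged over the valid (un-padded) window positions. Colour
images are compared on their luma plane.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .codec import EncoderParams, compression_ratio, deserialize, encode_image, serialize
from .raster_io import rgb_to_ycbcr
from .reconstruct import decode

__all__ = ["QualityReport", "ssim", "evaluate"]

_SIGMA = 1.5
_TRUNCATE = 3.5  # radius 5 -> 11x11 window
_K1, _K2 = 0.01, 0.03
_L = 255.0


@dataclass(frozen=True)
class QualityReport:
    ssim: float
    cr: float
    n_bytes: int


def _luma(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim == 3:
        return rgb_to_ycbcr(img)[0]
    return img


def ssim(a: np.ndarray, b: np.ndarray) -> float:
    """Mean structural similarity between two equally sized images."""
    a, b = _luma(a), _luma(b)
    if a.shape != b.shape:
        raise ValueError(f"image shapes differ: {a.shape} vs {b.shape}")
    pad = int(_TRUNCATE * _SIGMA + 0.5)
    if min(a.shape) < 2 * pad + 1:
        raise ValueError("images smaller than the 11x11 SSIM window")
    x = a.astype(np.float64)
    y = b.astype(np.float64)

    def f(img):
        return ndimage.gaussian_filter(img, sigma=_SIGMA, truncate=_TRUNCATE)

    ux, uy = f(x), f(y)
    uxx, uyy, uxy = f(x * x), f(y * y), f(x * y)
    vx = uxx - ux * ux
    vy = uyy - uy * uy
    vxy = uxy - ux * uy
    c1 = (_K1 * _L) ** 2
    c2 = (_K2 * _L) ** 2
    s = ((2 * ux * uy + c1) * (2 * vxy + c2)) / (
        (ux * ux + uy * uy + c1) * (vx + vy + c2)
    )
    return float(s[pad:-pad, pad:-pad].mean())


def evaluate(img: np.ndarray, params: EncoderParams | None = None) -> QualityReport:
    """Full round trip: encode, serialise, decode, measure SSIM and CR."""
    encoded = encode_image(img, params)
    blob = serialize(encoded)
    recon = decode(
        deserialize(blob),
        interpolation=params.interpolation if params is not None else True,
    )
    return QualityReport(
        ssim=ssim(img, recon), cr=compression_ratio(img, blob), n_bytes=len(blob)
    )
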