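"""Raster image input/output and RGB <-> YCbCr conversion.

Images are plain numpy ``uint8`` arrays: ``(h, w)`` for grayscale and
``(h, w, 3)`` for RGB. Pixel coordinates are ``(x, y)`` with x rightward,
y downward and origin at the top-left pixel centre; arrays are indexed
``[y, x]``. All modules in this package inherit these conventions.

The colour transform is full-range BT.601 YCbCr (the variant JPEG uses),
rounded half-up and clamped to [0, 255]. The integer round trip
RGB -> YCbCr -> RGB is then correct to within one level per channel.
"""

from __future__ import annotations

import numpy as np
from PIL import Image

__all__ = [
    "read_image",
    "write_image",
    "rgb_to_ycbcr",
    "ycbcr_to_rgb",
]

# Full-range BT.601 (rows: Y, Cb, Cr).
_RGB2YCC = np.array(
    [
        [0.299, 0.587, 0.114],
        [-0.168736, -0.331264, 0.5],
        [0.5, -0.418688, -0.081312],
    ]
)
_YCC2RGB = np.array(
    [
        [1.0, 0.0, 1.402],
        [1.0, -0.344136, -0.714136],
        [1.0, 1.772, 0.0],
    ]
)


def _round_half_up(x: np.ndarray) -> np.ndarray:
    # np.round ties to even; the codec needs a fixed, platform-stable rule.
    return np.floor(x + 0.5)


def _to_uint8(arr: np.ndarray) -> np.ndarray:
    if arr.dtype == np.uint8:
        return arr
    if arr.dtype == np.uint16:
        return _round_half_up(arr.astype(np.float64) * (255.0 / 65535.0)).astype(np.uint8)
    if np.issubdtype(arr.dtype, np.integer):
        info = np.iinfo(arr.dtype)
        scaled = arr.astype(np.float64) * (255.0 / info.max)
        return _round_half_up(scaled).astype(np.uint8)
    raise IOError(f"unsupported pixel dtype {arr.dtype}")


def read_image(path) -> np.ndarray:
    """Read a PNG/PPM/BMP raster file as an 8-bit image array.

    16-bit inputs are rescaled to 8 bits (round half-up); alpha is
    composited over white; palette images are expanded to RGB.
    Returns ``(h, w)`` uint8 for grayscale, ``(h, w, 3)`` uint8 for colour.
    """
    try:
        with Image.open(path) as im:
            im.load()
            if im.mode == "P":
                im = im.convert("RGBA" if "transparency" in im.info else "RGB")
            if im.mode in ("LA", "RGBA"):
                base = Image.new("RGBA", im.size, (255, 255, 255, 255))
                im = Image.alpha_composite(base, im.convert("RGBA")).convert("RGB")
            if im.mode in ("I", "I;16", "I;16B", "I;16L"):
                arr = np.asarray(im)
                return _to_uint8(arr.astype(np.uint16))
            if im.mode == "1":
                im = im.convert("L")
            if im.mode not in ("L", "RGB"):
                im = im.convert("RGB")
            arr = np.asarray(im)
    except (OSError, ValueError) as exc:
        raise IOError(f"cannot read raster image {path!r}: {exc}") from exc
    return _to_uint8(arr)


def write_image(img: np.ndarray, path) -> None:
    """Write an image array as a lossless PNG (grayscale L or true-colour RGB)."""
    img = np.asarray(img)
    if img.dtype != np.uint8 or img.ndim not in (2, 3):
        raise ValueError("expected a uint8 array of shape (h, w) or (h, w, 3)")
    mode = "L" if img.ndim == 2 else "RGB"
    try:
        Image.fromarray(img, mode=mode).save(path, format="PNG")
    except OSError as exc:
        raise IOError(f"cannot write PNG {path!r}: {exc}") from exc


def rgb_to_ycbcr(img: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split an RGB image into full-range BT.601 (Y, Cb, Cr) planes."""
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("rgb_to_ycbcr expects an (h, w, 3) RGB image")
    rgb = img.astype(np.float64)
    ycc = rgb @ _RGB2YCC.T
    ycc[..., 1:] += 128.0
    ycc = np.clip(_round_half_up(ycc), 0, 255).astype(np.uint8)
    return ycc[..., 0], ycc[..., 1], ycc[..., 2]


def ycbcr_to_rgb(y: np.ndarray, cb: np.ndarray, cr: np.ndarray) -> np.ndarray:
    """Merge (Y, Cb, Cr) planes back to an RGB image (inverse of rgb_to_ycbcr)."""
    y, cb, cr = (np.asarray(p) for p in (y, cb, cr))
    if not (y.shape == cb.shape == cr.shape) or y.ndim != 2:
        raise ValueError("ycbcr_to_rgb expects three equally sized 2-D planes")
    ycc = np.stack(
        [y.astype(np.float64), cb.astype(np.float64) - 128.0, cr.astype(np.float64) - 128.0],
        axis=-1,
    )
    rgb = ycc @ _YCC2RGB.T
    return np.clip(_round_half_up(rgb), 0, 255).astype(np.uint8)
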