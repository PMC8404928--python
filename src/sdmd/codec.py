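"""Encoder orchestration and the .sdmd binary container.

Encoding a channel: select up to L layer intensities, threshold at each,
clean islands, (optionally) extend the canvas with semi-discs to suppress
border Y-structures, skeletonise, prune by saliency, clip back to the
frame, trace branches and fit each with B-splines. With adaptive polarity
every layer is encoded both as an upper set {I >= i} and as a lower set
{I <= i-1} (whose complement is exactly the upper set) and the cheaper of
the two — fewer total control points — is stored, with a flag bit marking
flipped layers.

Colour images are encoded as full-resolution Y, Cb, Cr planes. Chroma is
compressed harder than luma by scaling the parameter set: Cb/Cr use
(round(n1*L), min(1, n2*eps), n3*sigma, n4*gamma), exploiting the lower
chromatic acuity of human vision. Defaults n1=0.5, n2=5, n3=2, n4=1.

Container layout (little-endian, counts as unsigned LEB128 varints)::

    magic "SDMD" | u8 version=1 | u16 w | u16 h | u8 colormode (0 gray, 1 ycbcr)
    per channel:  varint layer count
    per layer:    u8 intensity | u8 flags (bit0 flip, bit1 empty, bit2 full)
                  varint spline count
    per spline:   u8 degree | varint control point count | per point 3 x u16

Control point x is quantised to 16 bits over [-w, 2w], y over [-h, 2h]
(border extension may leave the frame), and the radius over
[-2, diag] — the small negative headroom absorbs least-squares overshoot
of radius control points near thin structures (a negative radius stamps
nothing at decode).

The compression ratio is the raw bitmap size w*h*channels divided by the
encoded byte size.
"""

from __future__ import annotations

import math
import struct
from dataclasses import dataclass, field, replace

import numpy as np

from .layering import SalientMap, remove_islands, select_layers, threshold
from .mat import (
    Branch,
    clip_mat,
    compute_mat,
    regularize,
    semi_disc_extend,
    spur_threshold,
    trace_branches,
)
from .raster_io import rgb_to_ycbcr
from .spline import BSplineBranch, fit_branch

__all__ = [
    "EncoderParams",
    "EncodedLayer",
    "SDMDFile",
    "SdmdFormatError",
    "encode_layer",
    "choose_polarity",
    "encode_image",
    "serialize",
    "deserialize",
    "compression_ratio",
    "save",
    "load",
]

MAGIC = b"SDMD"
VERSION = 1
_R_LO = -2.0  # low end of the radius quantisation range


class SdmdFormatError(ValueError):
    """Malformed .sdmd stream (bad magic/version, truncation, bad values)."""


@dataclass(frozen=True)
class EncoderParams:
    """Quality/compression trade-off knobs.

    L: number of threshold layers per channel (luma, for colour input).
    eps: island threshold as a fraction of the layer's foreground size.
    sigma: saliency threshold pruning skeleton branches (boundary px per
        radius px); larger smooths isophotes more.
    gamma: spline fitting tolerance as a fraction of the image diagonal.
    n1..n4: chroma multipliers applied to (L, eps, sigma, gamma).
    """

    L: int = 18
    eps: float = 0.01
    sigma: float = 1.0
    gamma: float = 0.002
    n1: float = 0.5
    n2: float = 5.0
    n3: float = 2.0
    n4: float = 1.0
    adaptive_polarity: bool = True
    y_structure_removal: bool = True
    interpolation: bool = True
    layer_strategy: str = "histogram"

    def __post_init__(self):
        if not 1 <= self.L <= 256:
            raise ValueError("L must be in [1, 256]")
        if not 0.0 <= self.eps <= 1.0:
            raise ValueError("eps must be in [0, 1]")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")

    def chroma(self) -> "EncoderParams":
        """Parameter set for the Cb/Cr channels."""
        return replace(
            self,
            L=max(1, int(math.floor(self.n1 * self.L + 0.5))),
            eps=min(1.0, self.n2 * self.eps),
            sigma=self.n3 * self.sigma,
            gamma=self.n4 * self.gamma,
        )


@dataclass(eq=False)
class EncodedLayer:
    """One encoded threshold layer: intensity, flip flag and its splines."""

    intensity: int
    flipped: bool
    marker: str = "normal"  # "normal" | "empty" | "full"
    splines: list[BSplineBranch] = field(default_factory=list)
    # encoder diagnostics (not serialised)
    fit_max_err: float = 0.0
    n_upper: int | None = None
    n_lower: int | None = None

    @property
    def n_control_points(self) -> int:
        return sum(len(s) for s in self.splines)


@dataclass(eq=False)
class SDMDFile:
    """In-memory form of one encoded image."""

    w: int
    h: int
    color_mode: str  # "gray" | "ycbcr"
    channels: list[list[EncodedLayer]]
    params: EncoderParams | None = None  # not serialised

    @property
    def n_control_points(self) -> int:
        return sum(l.n_control_points for ch in self.channels for l in ch)


def _trim_outside_tails(branch: Branch, w: int, h: int) -> Branch:
    s = branch.samples
    inside = (s[:, 0] >= 0) & (s[:, 0] < w) & (s[:, 1] >= 0) & (s[:, 1] < h)
    if not inside.any() or inside.all():
        return branch
    i0 = int(inside.argmax())
    i1 = len(s) - int(inside[::-1].argmax())
    flags = list(branch.end_flags)
    if i0 > 0:
        flags[0] = "border-touch"
    if i1 < len(s):
        flags[1] = "border-touch"
    return Branch(samples=s[i0:i1], end_flags=(flags[0], flags[1]))


def encode_layer(
    channel: np.ndarray,
    i: int,
    polarity: str,
    params: EncoderParams,
    salient: SalientMap | None = None,
) -> EncodedLayer:
    """Encode one threshold set of a channel as a set of B-splines.

    A lower-polarity layer for intensity ``i`` thresholds at ``i - 1`` so
    that the complement of the stored set is exactly the upper set
    ``{I >= i}`` recovered at decode time.
    """
    h, w = channel.shape
    flipped = polarity == "lower"
    if flipped and i == 0:
        return EncodedLayer(intensity=i, flipped=True, marker="empty")
    layer = threshold(channel, i - 1 if flipped else i, polarity)
    if not layer.mask.any():
        return EncodedLayer(intensity=i, flipped=flipped, marker="empty")
    if layer.mask.all():
        return EncodedLayer(intensity=i, flipped=flipped, marker="full")
    layer = remove_islands(layer, params.eps, salient)
    if not layer.mask.any():
        return EncodedLayer(intensity=i, flipped=flipped, marker="empty")
    if layer.mask.all():
        return EncodedLayer(intensity=i, flipped=flipped, marker="full")

    band = 0
    if params.y_structure_removal:
        layer, band = semi_disc_extend(layer)
    spur = spur_threshold(math.hypot(w, h))
    ma = regularize(compute_mat(layer, spur=spur), params.sigma)
    if band:
        ma = clip_mat(ma.translate(-band, -band), (w, h), keep_tangent=True)
    branches = trace_branches(ma)
    if band:
        # out-of-frame tails of frame-crossing branches are recreated by the
        # decoder's linear prolongation; only branches lying entirely outside
        # (whose discs still reach the image) must be stored as-is
        branches = [_trim_outside_tails(b, w, h) for b in branches]
    diag = math.hypot(w, h)
    bbox = (-w, 2 * w, -h, 2 * h)
    splines: list[BSplineBranch] = []
    max_err = 0.0
    for br in branches:
        fr = fit_branch(br, params.gamma, diag, bbox=bbox)
        for sp in fr.splines:
            # negative-radius lobes stamp no discs at decode; flattening
            # them to the container floor is reconstruction-lossless
            if sp.ctrl[:, 2].min() < _R_LO:
                sp = BSplineBranch(sp.degree, np.column_stack(
                    [sp.ctrl[:, :2], np.maximum(sp.ctrl[:, 2], _R_LO)]))
            splines.append(sp)
        max_err = max(max_err, fr.max_err)
    return EncodedLayer(
        intensity=i, flipped=flipped, splines=splines, fit_max_err=max_err
    )


def choose_polarity(
    channel: np.ndarray,
    i: int,
    params: EncoderParams,
    salient: SalientMap | None = None,
) -> EncodedLayer:
    """Encode both polarities of layer i and keep the cheaper one.

    Cost is the total number of B-spline control points; ties go to the
    upper encoding (flag bit unset). With adaptive polarity disabled the
    upper encoding is returned unconditionally.
    """
    upper = encode_layer(channel, i, "upper", params, salient)
    if not params.adaptive_polarity:
        return upper
    lower = encode_layer(channel, i, "lower", params, salient)
    nu, nl = upper.n_control_points, lower.n_control_points
    chosen = lower if nl < nu else upper
    chosen.n_upper, chosen.n_lower = nu, nl
    return chosen


def _encode_channel(
    channel: np.ndarray, params: EncoderParams, salient: SalientMap | None
) -> list[EncodedLayer]:
    intensities = select_layers(channel, params.L, params.layer_strategy)
    return [choose_polarity(channel, i, params, salient) for i in intensities]


def encode_image(
    img: np.ndarray,
    params: EncoderParams | None = None,
    salient: SalientMap | None = None,
) -> SDMDFile:
    """Encode a grayscale or RGB image.

    Colour images are converted to YCbCr; the Y plane uses ``params`` and
    the chroma planes the scaled set from :meth:`EncoderParams.chroma`.
    """
    if params is None:
        params = EncoderParams()
    img = np.asarray(img)
    if img.ndim == 2:
        h, w = img.shape
        channels = [_encode_channel(img, params, salient)]
        mode = "gray"
    elif img.ndim == 3 and img.shape[2] == 3:
        h, w = img.shape[:2]
        y, cb, cr = rgb_to_ycbcr(img)
        cp = params.chroma()
        channels = [
            _encode_channel(y, params, salient),
            _encode_channel(cb, cp, salient),
            _encode_channel(cr, cp, salient),
        ]
        mode = "ycbcr"
    else:
        raise ValueError("expected (h, w) or (h, w, 3) uint8 image")
    return SDMDFile(w=w, h=h, color_mode=mode, channels=channels, params=params)


# ---------------------------------------------------------------------------
# container


def _write_varint(buf: bytearray, value: int) -> None:
    if value < 0:
        raise SdmdFormatError(f"varint cannot encode negative value {value}")
    while True:
        b = value & 0x7F
        value >>= 7
        if value:
            buf.append(b | 0x80)
        else:
            buf.append(b)
            return


def _quantize(v: float, lo: float, hi: float, what: str) -> int:
    if not lo <= v <= hi:
        raise SdmdFormatError(f"{what} value {v} outside quantisation range [{lo}, {hi}]")
    return int(round((v - lo) / (hi - lo) * 65535))


def _dequantize(q: int, lo: float, hi: float) -> float:
    return lo + q / 65535.0 * (hi - lo)


def serialize(file: SDMDFile) -> bytes:
    """Deterministic binary encoding of an :class:`SDMDFile`."""
    w, h = file.w, file.h
    if not (1 <= w <= 65535 and 1 <= h <= 65535):
        raise SdmdFormatError(f"image size {w}x{h} not representable")
    diag = math.hypot(w, h)
    buf = bytearray()
    buf += MAGIC
    buf.append(VERSION)
    buf += struct.pack("<HH", w, h)
    if file.color_mode == "gray":
        buf.append(0)
    elif file.color_mode == "ycbcr":
        buf.append(1)
    else:
        raise SdmdFormatError(f"unknown color mode {file.color_mode!r}")
    expected = 1 if file.color_mode == "gray" else 3
    if len(file.channels) != expected:
        raise SdmdFormatError(
            f"{file.color_mode} file must have {expected} channels, got {len(file.channels)}"
        )
    for layers in file.channels:
        ints = [l.intensity for l in layers]
        if any(b <= a for a, b in zip(ints, ints[1:])):
            raise SdmdFormatError("layers must be strictly increasing in intensity")
        _write_varint(buf, len(layers))
        for layer in layers:
            if not 0 <= layer.intensity <= 255:
                raise SdmdFormatError(f"intensity {layer.intensity} outside [0, 255]")
            flags = int(layer.flipped)
            if layer.marker == "empty":
                flags |= 2
            elif layer.marker == "full":
                flags |= 4
            elif layer.marker != "normal":
                raise SdmdFormatError(f"unknown marker {layer.marker!r}")
            buf.append(layer.intensity)
            buf.append(flags)
            splines = [] if layer.marker != "normal" else layer.splines
            _write_varint(buf, len(splines))
            for sp in splines:
                buf.append(sp.degree)
                _write_varint(buf, len(sp.ctrl))
                for x, y, r in sp.ctrl:
                    buf += struct.pack(
                        "<HHH",
                        _quantize(x, -w, 2 * w, "x"),
                        _quantize(y, -h, 2 * h, "y"),
                        _quantize(r, _R_LO, diag, "radius"),
                    )
    return bytes(buf)


class _Reader:
    def __init__(self, data: bytes):
        self.data = data
        self.pos = 0

    def take(self, n: int) -> bytes:
        if self.pos + n > len(self.data):
            raise SdmdFormatError(f"truncated stream at offset {self.pos}")
        out = self.data[self.pos : self.pos + n]
        self.pos += n
        return out

    def u8(self) -> int:
        return self.take(1)[0]

    def u16(self) -> int:
        return struct.unpack("<H", self.take(2))[0]

    def varint(self) -> int:
        shift, value = 0, 0
        while True:
            b = self.u8()
            value |= (b & 0x7F) << shift
            if not b & 0x80:
                return value
            shift += 7
            if shift > 35:
                raise SdmdFormatError(f"varint too long at offset {self.pos}")


def deserialize(data: bytes) -> SDMDFile:
    """Inverse of :func:`serialize` (exact up to coordinate quantisation)."""
    r = _Reader(data)
    if r.take(4) != MAGIC:
        raise SdmdFormatError("bad magic at offset 0 (not an .sdmd stream)")
    version = r.u8()
    if version != VERSION:
        raise SdmdFormatError(f"unsupported version {version} at offset 4")
    w, h = r.u16(), r.u16()
    if w < 1 or h < 1:
        raise SdmdFormatError(f"invalid size {w}x{h} at offset 5")
    mode_byte = r.u8()
    if mode_byte not in (0, 1):
        raise SdmdFormatError(f"unknown color mode {mode_byte} at offset 9")
    mode = "gray" if mode_byte == 0 else "ycbcr"
    diag = math.hypot(w, h)
    channels = []
    for _ in range(1 if mode == "gray" else 3):
        n_layers = r.varint()
        layers = []
        prev = -1
        for _ in range(n_layers):
            intensity = r.u8()
            if intensity <= prev:
                raise SdmdFormatError(
                    f"layer intensities not strictly increasing at offset {r.pos}"
                )
            prev = intensity
            flags = r.u8()
            marker = "empty" if flags & 2 else "full" if flags & 4 else "normal"
            n_splines = r.varint()
            splines = []
            for _ in range(n_splines):
                degree = r.u8()
                if not 1 <= degree <= 3:
                    raise SdmdFormatError(f"bad spline degree {degree} at offset {r.pos}")
                n_cp = r.varint()
                if n_cp < degree + 1:
                    raise SdmdFormatError(
                        f"spline with {n_cp} control points (< degree+1) at offset {r.pos}"
                    )
                ctrl = np.empty((n_cp, 3))
                for k in range(n_cp):
                    qx, qy, qr = struct.unpack("<HHH", r.take(6))
                    ctrl[k] = (
                        _dequantize(qx, -w, 2 * w),
                        _dequantize(qy, -h, 2 * h),
                        _dequantize(qr, _R_LO, diag),
                    )
                splines.append(BSplineBranch(degree=degree, ctrl=ctrl))
            layers.append(
                EncodedLayer(
                    intensity=intensity,
                    flipped=bool(flags & 1),
                    marker=marker,
                    splines=splines,
                )
            )
        channels.append(layers)
    return SDMDFile(w=w, h=h, color_mode=mode, channels=channels)


def compression_ratio(img: np.ndarray, encoded: bytes) -> float:
    """Raw bitmap byte size (w*h*channels) over encoded byte size."""
    if len(encoded) == 0:
        raise ValueError("empty encoding")
    img = np.asarray(img)
    raw = img.shape[0] * img.shape[1] * (1 if img.ndim == 2 else img.shape[2])
    return raw / len(encoded)


def save(file: SDMDFile, path) -> None:
    with open(path, "wb") as fh:
        fh.write(serialize(file))


def load(path) -> SDMDFile:
    with open(path, "rb") as fh:
        return deserialize(fh.read())
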