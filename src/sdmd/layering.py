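"""Threshold-set decomposition of a channel into binary layers.

A channel ``I`` is decomposed into *threshold sets*: the upper set
``T_i = {x | I(x) >= i}`` or the lower set ``T_i = {x | I(x) <= i}``.
The codec selects ``L`` representative intensities, thresholds the
channel at each, and cleans every layer by removing small islands
before skeletonisation.

Connectivity follows the standard digital-topology pairing: foreground
components are 8-connected, background components 4-connected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "BinaryLayer",
    "SalientMap",
    "threshold",
    "select_layers",
    "remove_islands",
]

_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True, eq=False)
class BinaryLayer:
    """One threshold set: intensity, polarity and its boolean foreground mask."""

    intensity: int
    polarity: str  # "upper" ({I >= i}) or "lower" ({I <= i})
    mask: np.ndarray  # (h, w) bool, True = foreground to be skeletonised

    def __post_init__(self):
        if self.polarity not in ("upper", "lower"):
            raise ValueError(f"polarity must be 'upper' or 'lower', got {self.polarity!r}")


@dataclass(frozen=True, eq=False)
class SalientMap:
    """Region-of-interest mask with separate island thresholds.

    Components whose majority of pixels fall in the salient region are
    filtered with ``eps_salient`` (keep more detail); all others with
    ``eps_background``.
    """

    mask: np.ndarray  # (h, w) bool, True = salient
    eps_salient: float
    eps_background: float

    def __post_init__(self):
        if not (0.0 <= self.eps_salient <= self.eps_background <= 1.0):
            raise ValueError("need 0 <= eps_salient <= eps_background <= 1")


def threshold(channel: np.ndarray, i: int, polarity: str = "upper") -> BinaryLayer:
    """Threshold a channel at intensity ``i`` with the given polarity."""
    if not 0 <= i <= 255:
        raise ValueError(f"intensity {i} outside [0, 255]")
    channel = np.asarray(channel)
    if polarity == "upper":
        mask = channel >= i
    elif polarity == "lower":
        mask = channel <= i
    else:
        raise ValueError(f"unknown polarity {polarity!r}")
    return BinaryLayer(intensity=i, polarity=polarity, mask=mask)


def _quantization_error(hist: np.ndarray, selected: np.ndarray) -> float:
    """Total abs error of quantising every pixel down to the largest
    selected intensity <= its value (selected must be sorted, contain min)."""
    values = np.arange(256)
    idx = np.searchsorted(selected, values, side="right") - 1
    idx = np.clip(idx, 0, len(selected) - 1)
    q = selected[idx]
    return float(np.sum(hist * np.abs(values - q)))


def select_layers(channel: np.ndarray, L: int, strategy: str = "histogram") -> list[int]:
    """Pick up to ``L`` strictly increasing layer intensities for a channel.

    The channel minimum (base layer) is always included.

    strategy="uniform": L intensities evenly spaced over [min, max] of the
    channel, both ends included.

    strategy="histogram" (default): greedy selection that repeatedly adds
    the intensity whose inclusion most reduces the total per-pixel
    quantization error sum_x |I(x) - q(x)|, where q maps each pixel to the
    largest selected intensity <= its value. Stops early once no candidate
    reduces the error (e.g. all distinct values already selected).
    """
    if L < 1:
        raise ValueError(f"L must be >= 1, got {L}")
    if L > 256:
        raise ValueError(f"L must be <= 256, got {L}")
    channel = np.asarray(channel)
    lo, hi = int(channel.min()), int(channel.max())
    if strategy == "uniform":
        levels = np.unique(np.floor(np.linspace(lo, hi, min(L, hi - lo + 1)) + 0.5).astype(int))
        return [int(v) for v in levels]
    if strategy != "histogram":
        raise ValueError(f"unknown strategy {strategy!r}")

    hist = np.bincount(channel.ravel(), minlength=256).astype(np.float64)
    present = np.flatnonzero(hist)
    selected = [lo]
    err = _quantization_error(hist, np.array(selected))
    while len(selected) < L:
        best_v, best_err = None, err
        for v in present:
            v = int(v)
            if v in selected:
                continue
            cand = np.array(sorted(selected + [v]))
            e = _quantization_error(hist, cand)
            if e < best_err:  # strict: ties keep the smallest candidate (scanned first)
                best_v, best_err = v, e
        if best_v is None:
            break
        selected.append(best_v)
        selected.sort()
        err = best_err
    return selected


def remove_islands(
    layer: BinaryLayer, eps: float, salient: SalientMap | None = None
) -> BinaryLayer:
    """Remove small foreground islands from a layer.

    An 8-connected foreground component is removed when its pixel count is
    below ``eps * |T_i|``, with ``|T_i|`` the foreground count of the
    *input* layer. Background holes are deliberately left alone: a hole is
    an island of the opposite polarity and is filtered there when that
    polarity is encoded, whereas filling holes against the (typically much
    larger) upper-set size erases legitimate thin dark detail such as
    outlines or glyphs. With a :class:`SalientMap`, a component whose
    pixels are majority-salient uses ``eps_salient`` instead of
    ``eps_background`` (and plain ``eps`` is ignored).
    """
    if not 0.0 <= eps <= 1.0:
        raise ValueError(f"eps must be in [0, 1], got {eps}")
    mask = layer.mask.copy()
    total = int(mask.sum())
    if total == 0 or (eps == 0.0 and salient is None):
        return BinaryLayer(layer.intensity, layer.polarity, mask)

    def limits(labels: np.ndarray, n: int) -> np.ndarray:
        if salient is None:
            return np.full(n + 1, eps * total)
        sizes = np.bincount(labels.ravel(), minlength=n + 1).astype(np.float64)
        sal = np.bincount(labels.ravel(), weights=salient.mask.ravel(), minlength=n + 1)
        majority = sal > 0.5 * np.maximum(sizes, 1)
        e = np.where(majority, salient.eps_salient, salient.eps_background)
        return e * total

    labels, n = ndimage.label(mask, structure=_STRUCT8)
    if n:
        sizes = np.bincount(labels.ravel(), minlength=n + 1)
        small = sizes < limits(labels, n)
        small[0] = False
        mask[small[labels]] = False

    return BinaryLayer(layer.intensity, layer.polarity, mask)
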