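"""Deterministic synthetic test images.

Medial-descriptor codecs are aimed at imagery made of sizeable shapes on
smooth backgrounds — scientific visualisation, medical scans, graphics
art, cartoons. The generators here emulate those classes procedurally so
the test suite ships no binary assets:

- ``spiral``        black Archimedean spiral stroke leaving the frame
                    (exercises border Y-structures and thin shapes);
- ``treemap``       nested rectangles with parabolic luminance cushions
                    (smooth shading, sharp rectangle edges);
- ``gradient_disc`` anti-aliased flat discs over a colour gradient
                    (smooth background, curved boundaries);
- ``border_stripes`` colour bands crossing the full frame (maximal border
                    contact);
- ``cartoon``       flat-colour blobs with thin dark outlines (the case
                    where lower-polarity encoding wins);
- ``text``          rows of glyph-like black strokes (many thin details).

Geometry is expressed in unit coordinates scaled by ``size``, so the same
(kind, seed) at two sizes depicts the same scene — which is what makes
resolution-sweep experiments meaningful.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["make_fixture", "FIXTURE_KINDS"]

FIXTURE_KINDS = ("spiral", "treemap", "gradient_disc", "border_stripes", "cartoon", "text")

_KIND_STREAM = {k: i for i, k in enumerate(FIXTURE_KINDS)}


def make_fixture(kind: str, size: int, seed: int) -> np.ndarray:
    """Generate a deterministic test image of the given kind and size."""
    if kind not in _KIND_STREAM:
        raise ValueError(f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}")
    if size < 64:
        raise ValueError("size must be >= 64")
    rng = np.random.default_rng([int(seed), _KIND_STREAM[kind]])
    return _GENERATORS[kind](size, rng)


def _stamp_stroke(canvas: np.ndarray, pts: np.ndarray, radius: float, value: int) -> None:
    """Paint discs of `radius` px at each point of a polyline (px coords)."""
    H, W = canvas.shape[:2]
    r = max(radius, 0.8)
    for x, y in pts:
        x0, x1 = max(int(x - r), 0), min(int(x + r) + 1, W)
        y0, y1 = max(int(y - r), 0), min(int(y + r) + 1, H)
        if x0 >= x1 or y0 >= y1:
            continue
        d2 = (np.arange(x0, x1)[None, :] - x) ** 2 + (np.arange(y0, y1)[:, None] - y) ** 2
        canvas[y0:y1, x0:x1][d2 <= r * r] = value


def _spiral(size: int, rng: np.random.Generator) -> np.ndarray:
    img = np.full((size, size), 255, dtype=np.uint8)
    phase = rng.uniform(0, 2 * math.pi)
    turns = 5.0
    theta_max = 2 * math.pi * turns
    b = 0.60 / theta_max  # max radius 0.60 > 0.5: the stroke exits the frame
    stroke = 0.016 * size
    pts = []
    theta = 0.1
    while theta < theta_max:
        r = b * theta
        pts.append(
            (
                (0.5 + r * math.cos(theta + phase)) * size,
                (0.5 + r * math.sin(theta + phase)) * size,
            )
        )
        speed = size * math.hypot(b, r)  # |d(pos)/d(theta)| in px
        theta += 0.5 / max(speed, 1e-6)
    _stamp_stroke(img, np.array(pts), stroke, 0)
    return img


def _split_rects(rng: np.random.Generator, depth: int = 3):
    rects = [(0.0, 0.0, 1.0, 1.0)]
    for _ in range(depth):
        out = []
        for (x0, y0, x1, y1) in rects:
            f = rng.uniform(0.35, 0.65)
            if (x1 - x0) >= (y1 - y0):
                xm = x0 + f * (x1 - x0)
                out += [(x0, y0, xm, y1), (xm, y0, x1, y1)]
            else:
                ym = y0 + f * (y1 - y0)
                out += [(x0, y0, x1, ym), (x0, ym, x1, y1)]
        rects = out
    return rects


def _random_color(rng: np.random.Generator) -> np.ndarray:
    import colorsys

    h = rng.uniform(0, 1)
    s = rng.uniform(0.55, 0.95)
    v = rng.uniform(0.65, 1.0)
    return np.array(colorsys.hsv_to_rgb(h, s, v)) * 255.0


def _treemap(size: int, rng: np.random.Generator) -> np.ndarray:
    img = np.zeros((size, size, 3), dtype=np.float64)
    for (x0, y0, x1, y1) in _split_rects(rng):
        c = _random_color(rng)
        ix0, ix1 = int(x0 * size), max(int(x1 * size), int(x0 * size) + 1)
        iy0, iy1 = int(y0 * size), max(int(y1 * size), int(y0 * size) + 1)
        u = (np.arange(ix0, ix1) + 0.5 - ix0) / max(ix1 - ix0, 1)
        v = (np.arange(iy0, iy1) + 0.5 - iy0) / max(iy1 - iy0, 1)
        cushion = (4 * u * (1 - u))[None, :] * (4 * v * (1 - v))[:, None]
        shade = 0.45 + 0.55 * cushion ** 0.7
        img[iy0:iy1, ix0:ix1] = shade[:, :, None] * c[None, None, :]
    return np.clip(np.floor(img + 0.5), 0, 255).astype(np.uint8)


def _gradient_disc(size: int, rng: np.random.Generator) -> np.ndarray:
    c0, c1 = _random_color(rng), _random_color(rng)
    phi = rng.uniform(0, 2 * math.pi)
    yy, xx = np.mgrid[0:size, 0:size]
    t = ((xx / size - 0.5) * math.cos(phi) + (yy / size - 0.5) * math.sin(phi)) + 0.5
    t = np.clip(t, 0, 1)[:, :, None]
    img = (1 - t) * c0[None, None, :] + t * c1[None, None, :]
    for _ in range(6):
        cx, cy = rng.uniform(0.15, 0.85, size=2)
        rad = rng.uniform(0.06, 0.16)
        col = _random_color(rng)
        d = np.hypot(xx - cx * size, yy - cy * size)
        alpha = np.clip(rad * size - d + 0.5, 0, 1)[:, :, None]  # 1-px anti-aliased rim
        img = (1 - alpha) * img + alpha * col[None, None, :]
    return np.clip(np.floor(img + 0.5), 0, 255).astype(np.uint8)


def _border_stripes(size: int, rng: np.random.Generator) -> np.ndarray:
    img = np.empty((size, size, 3), dtype=np.uint8)
    n = 8
    cuts = np.sort(rng.uniform(0.06, 0.94, size=n - 1))
    bounds = np.concatenate([[0.0], cuts, [1.0]])
    for k in range(n):
        c = np.clip(np.floor(_random_color(rng) + 0.5), 0, 255).astype(np.uint8)
        x0, x1 = int(bounds[k] * size), int(bounds[k + 1] * size)
        img[:, x0:max(x1, x0 + 1)] = c
    return img


def _cartoon(size: int, rng: np.random.Generator) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    # comic-style backdrop: a saturated vertical colour gradient
    c0 = 255 - 0.7 * _random_color(rng)
    c1 = 255 - 0.7 * _random_color(rng)
    t = (yy / size)[:, :, None]
    img = np.clip(np.floor((1 - t) * c0 + t * c1 + 0.5), 0, 255).astype(np.uint8)
    outline = np.array([25, 22, 28], dtype=np.uint8)
    for _ in range(9):
        cx, cy = rng.uniform(0.15, 0.85, size=2)
        a = rng.uniform(0.05, 0.16)
        bax = rng.uniform(0.04, 0.12)
        ang = rng.uniform(0, math.pi)
        col = np.clip(np.floor(_random_color(rng) + 0.5), 0, 255).astype(np.uint8)
        dx = xx / size - cx
        dy = yy / size - cy
        p = dx * math.cos(ang) + dy * math.sin(ang)
        q = -dx * math.sin(ang) + dy * math.cos(ang)
        f = np.sqrt((p / a) ** 2 + (q / bax) ** 2)
        # approximate signed distance (px) to the ellipse boundary
        d = (f - 1.0) * min(a, bax) * size
        img[d <= -1.0] = col
        img[(d > -1.0) & (d <= 1.0)] = outline
    return img


_GLYPH_STROKES = (
    ((0.2, 0.1), (0.2, 0.9)),  # vertical bar
    ((0.2, 0.1), (0.8, 0.1)),  # top bar
    ((0.2, 0.5), (0.8, 0.5)),  # middle bar
    ((0.2, 0.9), (0.8, 0.9)),  # bottom bar
    ((0.8, 0.1), (0.8, 0.9)),  # right bar
    ((0.2, 0.9), (0.8, 0.1)),  # diagonal
)


def _text(size: int, rng: np.random.Generator) -> np.ndarray:
    img = np.full((size, size), 255, dtype=np.uint8)
    rows, cols = 4, 6
    stroke = max(0.006 * size, 1.2)
    cell = 1.0 / (cols + 1)
    rowh = 1.0 / (rows + 1)
    for r in range(rows):
        for c in range(cols):
            ox = (c + 0.5) * cell + 0.25 * cell
            oy = (r + 0.5) * rowh + 0.25 * rowh
            n_strokes = rng.integers(2, 4)
            for si in rng.choice(len(_GLYPH_STROKES), size=n_strokes, replace=False):
                (u0, v0), (u1, v1) = _GLYPH_STROKES[si]
                p0 = np.array([(ox + u0 * cell * 0.8) * size, (oy + v0 * rowh * 0.8) * size])
                p1 = np.array([(ox + u1 * cell * 0.8) * size, (oy + v1 * rowh * 0.8) * size])
                n = max(int(np.linalg.norm(p1 - p0) * 2), 2)
                pts = p0[None, :] + np.linspace(0, 1, n)[:, None] * (p1 - p0)[None, :]
                _stamp_stroke(img, pts, stroke, 0)
    return img


_GENERATORS = {
    "spiral": _spiral,
    "treemap": _treemap,
    "gradient_disc": _gradient_disc,
    "border_stripes": _border_stripes,
    "cartoon": _cartoon,
    "text": _text,
}
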