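"""Medial axis transforms of binary layers.

The MAT of a layer is the set of centres of maximal inscribed discs
together with their radii; the layer is recovered as the union of those
discs. Radii come from the exact Euclidean distance transform (distance
to the nearest *background pixel centre*); reconstruction stamps discs
with strict inclusion ``||p - x|| < r``, which is the unique rule with
zero overshoot under that convention.

Skeleton detection and pruning follow the boundary-collapse principle:
each boundary contour is parameterised by arc length, every foreground
pixel is assigned its nearest boundary point (feature transform), and a
pixel is skeletal when the features seen across it jump along the
contour — the length of that jump is the pixel's boundary importance
``rho`` (in boundary pixels). Pruning thresholds the saliency
``sigma = rho / DT``, which removes branches caused by small boundary
perturbations while keeping branches encoding large-scale features.

Shapes touching the image border grow spurious Y-shaped junctions. They
are eliminated by extending the canvas and capping each border-touching
run with an outward semi-disc before skeletonisation, then clipping the
skeleton back to the frame (and, at decode time, linearly prolonging the
clipped branches until their medial disc is tangent to the image edge).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage.measure import find_contours
from skimage.morphology import skeletonize

from .layering import BinaryLayer

__all__ = [
    "UnboundedLayerError",
    "MedialAxis",
    "Branch",
    "BorderSegment",
    "distance_transform",
    "compute_mat",
    "regularize",
    "detect_border_segments",
    "semi_disc_extend",
    "clip_mat",
    "spur_threshold",
    "extend_border_branch",
    "extend_samples",
    "trace_branches",
]

# Minimum boundary-collapse jump (in boundary pixels) for a pixel to count
# as skeletal. Non-skeletal pixels see jumps up to 2 (a diagonal
# neighbour's feature sits two chain steps away) and the staircase corners
# of a digitised smooth edge produce jumps up to ~3 (one run), so 4 is the
# smallest granularity that separates real boundary features from pixel
# quantisation noise at moderate resolutions. Staircase noise grows in
# absolute pixels with resolution, so above ~512 px the floor scales with
# the image diagonal (keeping the stored representation scale invariant,
# like the relative fit tolerance gamma*diag). Layer reconstruction does
# not depend on this choice: the coverage-completion fringe keeps the
# unregularised disc union exact.
SPUR_IMPORTANCE = 4.0
SPUR_REL = 8.0 / math.hypot(512, 512)


def spur_threshold(diag: float) -> float:
    """Skeleton detection granularity for an image with this diagonal.

    Measured control-point counts as a function of this threshold show a
    noise-dominated regime (counts explode, growing with resolution) below
    ~8 boundary pixels per 512 px of diagonal and a scale-invariant plateau
    above it; the threshold sits at the knee, floored at 4 boundary pixels
    for small images.
    """
    return max(SPUR_IMPORTANCE, SPUR_REL * diag)

_SHIFTS = [(-1, -1), (0, -1), (1, -1), (-1, 0), (1, 0), (-1, 1), (0, 1), (1, 1)]


class UnboundedLayerError(ValueError):
    """Layer has no background pixel: its distance transform is unbounded."""


@dataclass(frozen=True, eq=False)
class MedialAxis:
    """Skeletal pixels with per-pixel radius and boundary importance.

    Arrays are parallel: ``xy[k]`` is the integer position of pixel k
    (possibly outside the original frame after semi-disc extension),
    ``dt[k]`` its maximal-disc radius, ``rho[k]`` the boundary arc length
    (in pixels) collapsing onto it, ``border[k]`` whether clipping cut the
    skeleton at this pixel.
    """

    xy: np.ndarray  # (n, 2) int, columns x, y
    dt: np.ndarray  # (n,) float
    rho: np.ndarray  # (n,) float
    border: np.ndarray = field(default=None)  # (n,) bool

    def __post_init__(self):
        if self.border is None:
            object.__setattr__(self, "border", np.zeros(len(self.xy), dtype=bool))

    def __len__(self) -> int:
        return len(self.xy)

    @property
    def sigma(self) -> np.ndarray:
        """Saliency rho / DT (importance per unit radius)."""
        return self.rho / self.dt

    def translate(self, dx: int, dy: int) -> "MedialAxis":
        return replace(self, xy=self.xy + np.array([dx, dy]))


@dataclass(frozen=True, eq=False)
class Branch:
    """Ordered 8-connected simple path of skeletal samples.

    ``samples`` has columns (x, y, dt); ``end_flags`` labels the two ends
    as one of "free-end", "junction", "border-touch".
    """

    samples: np.ndarray  # (n, 3) float
    end_flags: tuple[str, str] = ("free-end", "free-end")

    def __len__(self) -> int:
        return len(self.samples)


@dataclass(frozen=True)
class BorderSegment:
    """Maximal run of foreground pixels along one image edge."""

    a: tuple[int, int]  # (x, y) of first pixel of the run
    b: tuple[int, int]  # (x, y) of last pixel of the run
    side: str  # top / bottom / left / right

    @property
    def length(self) -> float:
        return math.hypot(self.b[0] - self.a[0], self.b[1] - self.a[1])


def distance_transform(layer: BinaryLayer) -> np.ndarray:
    """Exact Euclidean distance from each foreground pixel centre to the
    nearest background pixel centre (0 on background).

    The image frame counts as boundary: pixels just outside the canvas are
    background. Without this, a shape touching the border has no boundary
    on that side, hence no medial axis to encode — the border contact
    segments are exactly what spawns the Y-structures that semi-disc
    extension later removes.
    """
    mask = layer.mask
    if mask.all():
        raise UnboundedLayerError(
            "layer has no background pixel; apply semi_disc_extend or encode as full"
        )
    padded = np.pad(mask, 1, constant_values=False)
    return ndimage.distance_transform_edt(padded)[1:-1, 1:-1]


# ---------------------------------------------------------------------------
# boundary contours and feature transform


def _pixel_contours(mask: np.ndarray):
    """Ordered boundary-pixel chains of a mask.

    Every 0.5-level contour (outer boundaries and holes) is converted to
    the ordered sequence of *foreground pixels* it runs along: each contour
    vertex sits on the edge between a foreground and a background pixel and
    is assigned to the foreground one; consecutive duplicates collapse.
    Positions along a chain are integer boundary-pixel counts, so the
    importance measure below is in boundary pixels and adjacent boundary
    pixels always differ by exactly 1.

    Returns (pix (m,2) [y,x], idx (m,), cid (m,), lengths, closed) over the
    concatenated chains, or None if the mask has no contour.
    """
    polys = find_contours(mask.astype(float), 0.5, fully_connected="high")
    pix, idxs, cids, lengths, closed = [], [], [], [], []
    H, W = mask.shape
    ci = 0
    for poly in polys:
        is_closed = bool(np.allclose(poly[0], poly[-1])) and len(poly) > 2
        verts = poly[:-1] if is_closed else poly
        ry, rx = verts[:, 0], verts[:, 1]
        fy, fx = np.floor(ry).astype(int), np.floor(rx).astype(int)
        cy, cx = np.ceil(ry).astype(int), np.ceil(rx).astype(int)
        fy, fx = np.clip(fy, 0, H - 1), np.clip(fx, 0, W - 1)
        cy, cx = np.clip(cy, 0, H - 1), np.clip(cx, 0, W - 1)
        take_floor = mask[fy, fx]
        py = np.where(take_floor, fy, cy)
        px = np.where(take_floor, fx, cx)
        keep = np.ones(len(py), dtype=bool)
        keep[1:] = (py[1:] != py[:-1]) | (px[1:] != px[:-1])
        py, px = py[keep], px[keep]
        if is_closed and len(py) > 1 and py[0] == py[-1] and px[0] == px[-1]:
            py, px = py[:-1], px[:-1]
        if len(py) == 0:
            continue
        pix.append(np.column_stack([py, px]))
        idxs.append(np.arange(len(py), dtype=np.float64))
        cids.append(np.full(len(py), ci))
        lengths.append(float(max(len(py), 1)))
        closed.append(is_closed)
        ci += 1
    if not pix:
        return None
    return (
        np.concatenate(pix),
        np.concatenate(idxs),
        np.concatenate(cids),
        np.asarray(lengths),
        np.asarray(closed),
    )


def compute_mat(layer: BinaryLayer, spur: float | None = None) -> MedialAxis:
    """Saliency-annotated skeleton of a layer.

    Pixels are skeletal when the boundary arc collapsing onto them (the
    jump between nearest-boundary-point parameters across the pixel)
    reaches the detection granularity ``spur`` (default:
    :func:`spur_threshold` of the mask diagonal; the encoder passes the
    original image's threshold so canvas extension does not change it),
    or when they are local maxima of the
    distance transform (centres of maximal discs in thin structures); the
    union is thinned to a one-pixel-wide skeleton. Every foreground
    component contributes at least one skeletal pixel.
    """
    mask = layer.mask
    dt = distance_transform(layer)
    if not mask.any():
        return MedialAxis(
            xy=np.empty((0, 2), dtype=int), dt=np.empty(0), rho=np.empty(0)
        )
    H, W = mask.shape
    # contours of the frame-padded mask: border-touching shapes get closed
    # boundary chains running along the frame edge (consistent with the DT)
    cont = _pixel_contours(np.pad(mask, 1, constant_values=False))
    if cont is None:  # pathological: foreground without a traceable contour
        return _fallback_maxima(mask, dt)
    bpix, bidx, bcid, lengths, closed = cont
    bpix = bpix - 1  # back to frame coordinates; chain pixels are foreground
    total_boundary = float(lengths.sum())

    # per-pixel (contour id, chain position) of the nearest boundary pixel
    bp_mask = np.zeros(mask.shape, dtype=bool)
    cid_grid = np.full(mask.shape, -1, dtype=np.int32)
    idx_grid = np.zeros(mask.shape, dtype=np.float64)
    # first occurrence wins (a thin-structure pixel can sit on two chain legs)
    rev = slice(None, None, -1)
    bp_mask[bpix[:, 0], bpix[:, 1]] = True
    cid_grid[bpix[rev, 0], bpix[rev, 1]] = bcid[rev]
    idx_grid[bpix[rev, 0], bpix[rev, 1]] = bidx[rev]

    _, (fy, fx) = ndimage.distance_transform_edt(~bp_mask, return_indices=True)
    cid_p = cid_grid[fy, fx]
    idx_p = idx_grid[fy, fx]

    def shifted_view(arr, dx, dy, fill):
        out = np.full(arr.shape, fill, dtype=arr.dtype)
        ys = slice(max(dy, 0), H + min(dy, 0))
        xs = slice(max(dx, 0), W + min(dx, 0))
        yd = slice(max(-dy, 0), H + min(-dy, 0))
        xd = slice(max(-dx, 0), W + min(-dx, 0))
        out[yd, xd] = arr[ys, xs]
        return out

    # importance: largest feature jump (in boundary pixels) across the pixel
    jump = np.zeros(mask.shape)
    clen = lengths[np.clip(cid_p, 0, None)]
    is_closed = closed[np.clip(cid_p, 0, None)]
    for dx, dy in _SHIFTS:
        sc = shifted_view(cid_p, dx, dy, np.int32(-2))
        sa = shifted_view(idx_p, dx, dy, 0.0)
        sm = shifted_view(mask, dx, dy, False)
        both = mask & sm
        d = np.abs(idx_p - sa)
        wrap = np.where(is_closed, np.minimum(d, clen - d), d)
        j = np.where(sc == cid_p, wrap, total_boundary)
        jump = np.where(both, np.maximum(jump, j), jump)

    # local maxima of DT catch maximal discs of 1-2 px thin structures,
    # which the feature-jump test can miss when one side owns both features
    localmax = mask & (dt <= 2.0)
    for dx, dy in _SHIFTS:
        localmax &= dt >= shifted_view(dt, dx, dy, 0.0)

    if spur is None:
        spur = spur_threshold(math.hypot(W, H))
    cand = mask & ((jump >= spur) | localmax)
    skel = skeletonize(cand)

    # coverage completion: a pixel whose maximal disc is contained in an
    # 8-neighbour's disc (dt(y) >= dt(x) + |x-y|) is covered by that disc,
    # transitively up to the ridge; pixels with no such neighbour are
    # maximal-disc centres in their own right and must be kept or the
    # disc union cannot rebuild the layer exactly. This fringe hugs curved
    # boundary runs; no boundary interval collapses onto it, so it carries
    # sub-pixel importance 0.5 and any saliency threshold >= 0.6 prunes it.
    covered = np.zeros(mask.shape, dtype=bool)
    for dx, dy in _SHIFTS:
        step = math.hypot(dx, dy)
        covered |= shifted_view(dt, dx, dy, 0.0) >= dt + step - 1e-9
    fringe = mask & ~covered & ~skel
    skel |= fringe

    # every component keeps at least its deepest pixel
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=bool))
    have = np.unique(labels[skel])
    missing = np.setdiff1d(np.arange(1, n + 1), have)
    for lab in missing:
        flat_idx = np.argmax(np.where(labels == lab, dt, -1.0))
        skel[np.unravel_index(flat_idx, mask.shape)] = True

    ys, xs = np.nonzero(skel)
    order = np.lexsort((xs, ys))
    ys, xs = ys[order], xs[order]
    # rho: boundary pixels collapsing here. The feature jump is the AFMM
    # measure; thin-structure pixels (DT local maxima) encode both flanking
    # boundary runs, hence at least 2; a component collapsed to its single
    # deepest pixel encodes its whole boundary (~perimeter of its disc).
    rho = np.maximum(jump[ys, xs], 1.0)
    rho = np.where(localmax[ys, xs], np.maximum(rho, 2.0), rho)
    rho = np.where(fringe[ys, xs], 0.5, rho)
    fallback = np.isin(labels[ys, xs], missing)
    rho = np.where(fallback, np.maximum(rho, 2.0 * np.pi * dt[ys, xs]), rho)
    return MedialAxis(
        xy=np.column_stack([xs, ys]).astype(int),
        dt=dt[ys, xs],
        rho=rho,
    )


def _fallback_maxima(mask: np.ndarray, dt: np.ndarray) -> MedialAxis:
    ys, xs = np.nonzero(mask & (dt == dt.max()))
    return MedialAxis(
        xy=np.column_stack([xs[:1], ys[:1]]).astype(int),
        dt=dt[ys[:1], xs[:1]],
        rho=2.0 * np.pi * dt[ys[:1], xs[:1]],
    )


def regularize(ma: MedialAxis, sigma_thr: float) -> MedialAxis:
    """Keep skeletal pixels with saliency sigma = rho/DT >= sigma_thr."""
    if sigma_thr < 0:
        raise ValueError("sigma_thr must be >= 0")
    if sigma_thr == 0:
        return ma
    keep = ma.sigma >= sigma_thr
    return MedialAxis(
        xy=ma.xy[keep], dt=ma.dt[keep], rho=ma.rho[keep], border=ma.border[keep]
    )


# ---------------------------------------------------------------------------
# border Y-structure handling


def detect_border_segments(layer: BinaryLayer) -> list[BorderSegment]:
    """Maximal runs of foreground pixels along each of the four image edges."""
    mask = layer.mask
    H, W = mask.shape
    out: list[BorderSegment] = []

    def runs(line: np.ndarray):
        padded = np.concatenate([[False], line, [False]])
        d = np.diff(padded.astype(np.int8))
        starts = np.flatnonzero(d == 1)
        ends = np.flatnonzero(d == -1) - 1
        return zip(starts, ends)

    for s, e in runs(mask[0]):
        out.append(BorderSegment((int(s), 0), (int(e), 0), "top"))
    for s, e in runs(mask[H - 1]):
        out.append(BorderSegment((int(s), H - 1), (int(e), H - 1), "bottom"))
    for s, e in runs(mask[:, 0]):
        out.append(BorderSegment((0, int(s)), (0, int(e)), "left"))
    for s, e in runs(mask[:, W - 1]):
        out.append(BorderSegment((W - 1, int(s)), (W - 1, int(e)), "right"))
    return out


def semi_disc_extend(layer: BinaryLayer) -> tuple[BinaryLayer, int]:
    """Cap every border-touching run with an outward semi-disc.

    The canvas grows by ``band = ceil(max_j ||A_j - B_j|| / 2)`` on all four
    sides and, for each border run, the outward half of the disc centred at
    ``(A_j + B_j)/2`` with radius ``||A_j - B_j||/2`` is added as
    foreground. Returns the extended layer and the band width (0 when the
    shape does not touch the border).
    """
    segments = detect_border_segments(layer)
    if not segments:
        return layer, 0
    band = int(math.ceil(max(s.length for s in segments) / 2.0))
    if band == 0:
        return layer, 0
    H, W = layer.mask.shape
    big = np.zeros((H + 2 * band, W + 2 * band), dtype=bool)
    big[band : band + H, band : band + W] = layer.mask
    yy, xx = np.mgrid[0 : H + 2 * band, 0 : W + 2 * band]
    for seg in segments:
        r = seg.length / 2.0
        if r == 0:
            continue
        cx = (seg.a[0] + seg.b[0]) / 2.0 + band
        cy = (seg.a[1] + seg.b[1]) / 2.0 + band
        inside = (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r
        if seg.side == "top":
            inside &= yy < band
        elif seg.side == "bottom":
            inside &= yy > band + H - 1
        elif seg.side == "left":
            inside &= xx < band
        else:
            inside &= xx > band + W - 1
        big |= inside
    return BinaryLayer(layer.intensity, layer.polarity, big), band


def clip_mat(
    ma: MedialAxis, frame: tuple[int, int], keep_tangent: bool = False
) -> MedialAxis:
    """Keep skeletal pixels inside the frame (positions already in
    original-frame coordinates); pixels that lose an 8-neighbour to the
    clip are flagged border-touch.

    With ``keep_tangent`` an out-of-frame pixel survives while its medial
    disc still reaches at least one pixel deep into the image (Euclidean
    distance outside the frame < radius - 1; the 45-degree-plane criterion
    with sub-pixel contributions dropped). Removing those pixels loses
    in-frame coverage that a linear prolongation of the clipped branch
    cannot always recover — e.g. when the out-of-frame medial of a large
    border cap runs parallel to the edge and never meets a clipped end.
    """
    w, h = frame
    x, y = ma.xy[:, 0], ma.xy[:, 1]
    keep = (x >= 0) & (x < w) & (y >= 0) & (y < h)
    if keep_tangent:
        dx = np.maximum(0, np.maximum(-x, x - (w - 1)))
        dy = np.maximum(0, np.maximum(-y, y - (h - 1)))
        tangent = np.hypot(dx, dy) < ma.dt
        # stay within the representable coordinate box [-w, 2w] x [-h, 2h]
        tangent &= (x > -w) & (x < 2 * w) & (y > -h) & (y < 2 * h)
        keep |= tangent
    if keep.all():
        return ma
    removed = {(int(px), int(py)) for px, py in ma.xy[~keep]}
    border = ma.border[keep].copy()
    kept_xy = ma.xy[keep]
    for k, (px, py) in enumerate(kept_xy):
        for dx, dy in _SHIFTS:
            if (int(px) + dx, int(py) + dy) in removed:
                border[k] = True
                break
    return MedialAxis(xy=kept_xy, dt=ma.dt[keep], rho=ma.rho[keep], border=border)


def extend_samples(
    samples: np.ndarray, frame: tuple[float, float], max_steps: int | None = None
) -> np.ndarray:
    """Prolong a 3-D MAT sample chain (x, y, r) beyond the frame.

    Extrapolates linearly from the last two samples in unit steps and stops
    at the first sample whose radius no longer exceeds its Euclidean
    distance outside the frame — i.e. where the medial disc is tangent to
    (about to leave) the image. Returns the appended samples only.
    """
    if len(samples) < 2:
        return np.empty((0, 3))
    w, h = frame
    p1, p0 = samples[-1], samples[-2]
    d = p1[:2] - p0[:2]
    step = float(np.hypot(d[0], d[1]))
    if step < 1e-9:
        return np.empty((0, 3))
    d = d / step
    slope = (p1[2] - p0[2]) / step
    if max_steps is None:
        max_steps = int(2 * math.hypot(w, h)) + 4
    out = []
    prev_out = math.hypot(
        max(0.0, -p1[0], p1[0] - (w - 1)), max(0.0, -p1[1], p1[1] - (h - 1))
    )
    for k in range(1, max_steps + 1):
        x, y = p1[0] + k * d[0], p1[1] + k * d[1]
        r = p1[2] + k * slope
        if r <= 0.5:
            break
        dx = max(0.0, -x, x - (w - 1))
        dy = max(0.0, -y, y - (h - 1))
        dist_out = math.hypot(dx, dy)
        if dist_out <= prev_out:  # not leaving the frame: nothing to prolong
            break
        prev_out = dist_out
        out.append((x, y, r))
        if dist_out >= r:
            break
    return np.asarray(out).reshape(-1, 3)


def extend_border_branch(branch: Branch, frame: tuple[int, int]) -> Branch:
    """Append extrapolated samples at each border-touch end of a branch."""
    if "border-touch" not in branch.end_flags:
        raise ValueError("branch has no border-touch endpoint")
    samples = branch.samples
    if branch.end_flags[1] == "border-touch":
        samples = np.vstack([samples, extend_samples(samples, frame)])
    if branch.end_flags[0] == "border-touch":
        rev = samples[::-1]
        samples = np.vstack([extend_samples(rev, frame)[::-1], samples])
    return Branch(samples=samples, end_flags=branch.end_flags)


# ---------------------------------------------------------------------------
# branch tracing


def trace_branches(ma: MedialAxis) -> list[Branch]:
    """Partition skeletal pixels into simple 8-connected paths.

    Paths split at junctions (pixels with >= 3 skeletal 8-neighbours);
    junction pixels are duplicated into every incident branch. Ordering is
    deterministic: traversal prefers the smallest (y, x) neighbour and
    branches are sorted by their smallest endpoint.
    """
    n = len(ma)
    if n == 0:
        return []
    pos = [(int(x), int(y)) for x, y in ma.xy]
    index = {p: k for k, p in enumerate(pos)}
    data = {p: (float(ma.dt[k]), bool(ma.border[k])) for k, p in enumerate(pos)}

    def nbrs(p):
        found = [
            (p[0] + dx, p[1] + dy) for dx, dy in _SHIFTS if (p[0] + dx, p[1] + dy) in index
        ]
        found.sort(key=lambda q: (q[1], q[0]))
        return found

    neighbors = {p: nbrs(p) for p in pos}
    junction = {p for p in pos if len(neighbors[p]) >= 3}
    path_pixels = [p for p in pos if p not in junction]
    pnbrs = {p: [q for q in neighbors[p] if q not in junction] for p in path_pixels}

    visited: set = set()
    covered: set = set()
    chains: list[list] = []

    def walk(start):
        chain = [start]
        visited.add(start)
        cur = start
        while True:
            nxt = [q for q in pnbrs[cur] if q not in visited]
            if not nxt:
                break
            cur = nxt[0]
            visited.add(cur)
            chain.append(cur)
        return chain

    order = sorted(path_pixels, key=lambda q: (q[1], q[0]))
    for p in order:  # open paths first
        if p in visited or len(pnbrs[p]) > 1:
            continue
        chain = walk(p)
        js = [q for q in neighbors[chain[0]] if q in junction]
        je = [q for q in neighbors[chain[-1]] if q in junction]
        if len(chain) == 1:
            start_j = js[0] if js else None
            end_j = js[1] if len(js) > 1 else None
        else:
            start_j = js[0] if js else None
            end_j = je[0] if je else None
        if start_j:
            chain.insert(0, start_j)
        if end_j:
            chain.append(end_j)
        chains.append(chain)
        covered.update(chain)
    for p in order:  # remaining cycles
        if p in visited:
            continue
        chain = walk(p)
        if len(chain) > 2 and chain[0] in neighbors[chain[-1]]:
            chain.append(chain[0])
        chains.append(chain)
        covered.update(chain)
    # junction pixels not yet covered (junction-only clusters)
    jorder = sorted((p for p in junction if p not in covered), key=lambda q: (q[1], q[0]))
    for p in jorder:
        if p in covered:
            continue
        chain = [p]
        covered.add(p)
        cur = p
        while True:
            nxt = [q for q in neighbors[cur] if q in junction and q not in covered]
            if not nxt:
                break
            cur = nxt[0]
            covered.add(cur)
            chain.append(cur)
        chains.append(chain)

    def flag(chain, end):
        p = chain[0] if end == 0 else chain[-1]
        if p in junction:
            return "junction"
        if data[p][1]:
            return "border-touch"
        return "free-end"

    branches = []
    for chain in chains:
        samples = np.array([(p[0], p[1], data[p][0]) for p in chain], dtype=float)
        branches.append(Branch(samples=samples, end_flags=(flag(chain, 0), flag(chain, -1))))

    def key(b: Branch):
        e0 = (b.samples[0, 1], b.samples[0, 0])
        e1 = (b.samples[-1, 1], b.samples[-1, 0])
        lo, hi = sorted([e0, e1])
        return (lo, hi, len(b))

    branches.sort(key=key)
    return branches
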