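"""B-spline encoding of 3-D MAT branches.

Each skeleton branch is a chain of samples (x, y, r) — position plus disc
radius — fitted by a clamped uniform-knot B-spline that minimises the sum
of squared 3-D residuals at chord-length parameters. The encoder searches
for the cheapest representation: control-point counts increase from d+1
upward and, per count, degrees 1..3 are tried in order, accepting the
first fit whose maximum 3-D deviation is within the absolute tolerance
``tau = gamma * image diagonal``. When no bounded fit exists the branch is
split at its worst-fit sample and both halves are fitted recursively
(fit-and-split), which always terminates because a degree-1 interpolating
polyline has zero error.

Knots are implied (clamped uniform) and never stored; decoding converts
each spline to Bezier segments by knot insertion and rasterises them with
de Casteljau's algorithm, subdividing adaptively until consecutive rounded
samples are 8-connected. Because control points and tolerance are both
relative to image size, the representation is scale invariant: rasterising
at ``scale > 1`` yields a super-resolution reconstruction at no storage
cost.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BSplineBranch",
    "FitResult",
    "FitFailure",
    "basis_matrix",
    "clamped_uniform_knots",
    "least_squares_fit",
    "fit_branch",
    "evaluate",
    "rasterize",
]

MAX_CONTROL_POINTS = 64  # per spline, before fit-and-split kicks in
MAX_DEGREE = 3


class FitFailure(Exception):
    """Least-squares system is singular (degenerate parameterisation)."""


@dataclass(frozen=True, eq=False)
class BSplineBranch:
    """Clamped uniform B-spline with 3-D control points (x, y, r)."""

    degree: int
    ctrl: np.ndarray  # (m, 3) float

    def __post_init__(self):
        ctrl = np.asarray(self.ctrl, dtype=float)
        object.__setattr__(self, "ctrl", ctrl)
        if not 1 <= self.degree <= MAX_DEGREE:
            raise ValueError(f"degree {self.degree} outside [1, {MAX_DEGREE}]")
        if len(ctrl) < self.degree + 1:
            raise ValueError("need at least degree+1 control points")

    def __len__(self) -> int:
        return len(self.ctrl)


@dataclass(frozen=True, eq=False)
class FitResult:
    splines: list[BSplineBranch]
    max_err: float
    split_count: int = field(default=0)

    @property
    def n_control_points(self) -> int:
        return sum(len(s) for s in self.splines)


def clamped_uniform_knots(m: int, degree: int) -> np.ndarray:
    """Knot vector [0]*(d+1), 1/s, 2/s, ..., [1]*(d+1) with s = m - d spans."""
    spans = m - degree
    if spans < 1:
        raise ValueError("need m >= degree + 1")
    inner = np.arange(1, spans) / spans
    return np.concatenate([np.zeros(degree + 1), inner, np.ones(degree + 1)])


def basis_matrix(ts: np.ndarray, m: int, degree: int) -> np.ndarray:
    """Design matrix N[i, j] = B_{j,degree}(ts[i]) on clamped uniform knots.

    Cox-de Boor recursion vectorised over the parameters; t = 1 is assigned
    to the last non-empty span so the clamped end point evaluates exactly.
    """
    ts = np.asarray(ts, dtype=float)
    knots = clamped_uniform_knots(m, degree)
    n_knots = len(knots)
    # zeroth degree: indicator of the (right-open) knot span
    span = np.searchsorted(knots, ts, side="right") - 1
    last = np.flatnonzero(knots < knots[-1])[-1]
    span = np.minimum(span, last)
    b = np.zeros((len(ts), n_knots - 1))
    b[np.arange(len(ts)), span] = 1.0
    for d in range(1, degree + 1):
        nb = np.zeros((len(ts), n_knots - 1 - d))
        for j in range(n_knots - 1 - d):
            left = knots[j + d] - knots[j]
            right = knots[j + d + 1] - knots[j + 1]
            v = np.zeros(len(ts))
            if left > 0:
                v += (ts - knots[j]) / left * b[:, j]
            if right > 0:
                v += (knots[j + d + 1] - ts) / right * b[:, j + 1]
            nb[:, j] = v
        b = nb
    return b[:, :m]


def chord_parameters(points: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(points[:, :2], axis=0), axis=1)
    total = seg.sum()
    if total <= 0:
        return np.linspace(0.0, 1.0, len(points))
    return np.concatenate([[0.0], np.cumsum(seg)]) / total


def least_squares_fit(
    points: np.ndarray, degree: int, m: int, ts: np.ndarray | None = None
) -> tuple[BSplineBranch, float]:
    """Best clamped B-spline of given degree and control-point count.

    End control points are clamped to the first/last sample (so adjacent
    branches stay connected at junctions); interior control points solve
    the normal equations at chord-length parameters. Returns the spline
    and the max 3-D deviation over the samples (at their parameters).
    Raises :class:`FitFailure` when the system is rank deficient.
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    if m < degree + 1:
        raise ValueError("m must be >= degree + 1")
    if n < m:
        raise ValueError("need at least m samples")
    if ts is None:
        ts = chord_parameters(points)
    B = basis_matrix(ts, m, degree)
    ctrl = np.empty((m, 3))
    ctrl[0] = points[0]
    ctrl[-1] = points[-1]
    if m > 2:
        rhs = points - np.outer(B[:, 0], ctrl[0]) - np.outer(B[:, -1], ctrl[-1])
        A = B[:, 1:-1]
        sol, _, rank, _ = np.linalg.lstsq(A, rhs, rcond=None)
        if rank < m - 2:
            raise FitFailure(f"rank {rank} < {m - 2} interior control points")
        ctrl[1:-1] = sol
    spline = BSplineBranch(degree=degree, ctrl=ctrl)
    resid = B @ ctrl - points
    max_err = float(np.linalg.norm(resid, axis=1).max())
    return spline, max_err


def _polyline(points: np.ndarray) -> BSplineBranch:
    pts = np.asarray(points, dtype=float)
    if len(pts) == 1:
        pts = np.vstack([pts, pts])
    return BSplineBranch(degree=1, ctrl=pts)


def fit_branch(
    samples: np.ndarray, gamma: float, diag: float, bbox: tuple | None = None
) -> FitResult:
    """Fit a branch (or Branch object) within tolerance gamma * diag.

    Searches control-point counts upward (cheapest first) and degrees 1..3
    per count; splits at the worst sample and recurses when the count cap
    is reached. Branches with <= 2 samples are stored as exact degree-1
    polylines. With ``bbox = (xmin, xmax, ymin, ymax)`` a fit whose control
    points leave the box is rejected (the interpolating polyline of in-box
    samples always satisfies it), keeping control points representable in
    the container's quantisation range.
    """
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    if hasattr(samples, "samples"):  # accept mat.Branch
        samples = samples.samples
    samples = np.asarray(samples, dtype=float)
    tau = gamma * diag
    splines: list[BSplineBranch] = []
    worst = 0.0
    splits = 0

    def fit(pts: np.ndarray):
        nonlocal worst, splits
        n = len(pts)
        if n <= 2:
            splines.append(_polyline(pts))
            return
        ts = chord_parameters(pts)
        m_cap = min(n, MAX_CONTROL_POINTS)
        best = None  # (err, degree, m) of the closest failed fit
        for m in range(2, m_cap + 1):
            for d in range(1, min(MAX_DEGREE, m - 1) + 1):
                try:
                    spline, err = least_squares_fit(pts, d, m, ts)
                except FitFailure:
                    continue
                if bbox is not None and (
                    spline.ctrl[:, 0].min() < bbox[0]
                    or spline.ctrl[:, 0].max() > bbox[1]
                    or spline.ctrl[:, 1].min() < bbox[2]
                    or spline.ctrl[:, 1].max() > bbox[3]
                ):
                    continue
                if err <= tau:
                    splines.append(spline)
                    worst = max(worst, err)
                    return
                if best is None or err < best[0]:
                    best = (err, d, m)
        if best is not None:  # split at the worst sample of the best attempt
            spline, _ = least_squares_fit(pts, best[1], best[2], ts)
            resid = np.linalg.norm(basis_matrix(ts, best[2], best[1]) @ spline.ctrl - pts, axis=1)
            k = int(np.argmax(resid))
        else:
            k = n // 2
        k = min(max(k, 1), n - 2)
        splits += 1
        fit(pts[: k + 1])
        fit(pts[k:])

    fit(samples)
    return FitResult(splines=splines, max_err=worst, split_count=splits)


# ---------------------------------------------------------------------------
# evaluation and rasterisation


def _insert_knot(knots: np.ndarray, ctrl: np.ndarray, degree: int, t: float):
    """Boehm's single knot insertion."""
    k = np.searchsorted(knots, t, side="right") - 1
    new_ctrl = np.empty((len(ctrl) + 1, ctrl.shape[1]))
    new_ctrl[: k - degree + 1] = ctrl[: k - degree + 1]
    for j in range(k - degree + 1, k + 1):
        denom = knots[j + degree] - knots[j]
        a = 0.0 if denom <= 0 else (t - knots[j]) / denom
        new_ctrl[j] = (1 - a) * ctrl[j - 1] + a * ctrl[j]
    new_ctrl[k + 1 :] = ctrl[k:]
    return np.insert(knots, k + 1, t), new_ctrl


def to_bezier_segments(spline: BSplineBranch) -> list[np.ndarray]:
    """Convert to Bezier segments by raising every interior knot to full
    multiplicity (each segment is (degree+1, 3) control points)."""
    d = spline.degree
    ctrl = spline.ctrl
    if len(ctrl) == d + 1:
        return [ctrl]
    knots = clamped_uniform_knots(len(ctrl), d)
    for t in np.unique(knots[(knots > 0) & (knots < 1)]):
        mult = int(np.sum(knots == t))
        for _ in range(d - mult):
            knots, ctrl = _insert_knot(knots, ctrl, d, float(t))
    segs = []
    n_seg = (len(ctrl) - 1) // d
    for i in range(n_seg):
        segs.append(ctrl[i * d : i * d + d + 1])
    return segs


def _de_casteljau(bezier: np.ndarray, ts: np.ndarray) -> np.ndarray:
    """Evaluate one Bezier segment at parameters ts (vectorised lerps)."""
    ts = np.asarray(ts, dtype=float)
    b = np.repeat(bezier[None, :, :], len(ts), axis=0)  # (k, d+1, 3)
    t = ts[:, None, None]
    while b.shape[1] > 1:
        b = (1.0 - t) * b[:, :-1, :] + t * b[:, 1:, :]
    return b[:, 0, :]


def evaluate(spline: BSplineBranch, ts: np.ndarray) -> np.ndarray:
    """Evaluate the curve at global parameters in [0, 1] via de Casteljau."""
    ts = np.atleast_1d(np.asarray(ts, dtype=float))
    segs = to_bezier_segments(spline)
    n_seg = len(segs)
    idx = np.clip((ts * n_seg).astype(int), 0, n_seg - 1)
    local = ts * n_seg - idx
    out = np.empty((len(ts), 3))
    for i in range(n_seg):
        sel = idx == i
        if sel.any():
            out[sel] = _de_casteljau(segs[i], local[sel])
    return out


def rasterize(
    spline: BSplineBranch, scale: float = 1.0, return_float: bool = False
):
    """Rasterise a spline into an 8-connected pixel chain with radii.

    All three coordinates (x, y, r) are multiplied by ``scale``; the curve
    is split into Bezier segments and evaluated by de Casteljau with
    adaptive subdivision until consecutive samples round to 8-connected
    pixels. Returns ``(pixels (n,2) int, radii (n,) float)`` or, with
    ``return_float``, ``(ts, points (n,3) float)`` before rounding.
    """
    if scale < 1.0:
        raise ValueError("scale must be >= 1")
    scaled = BSplineBranch(degree=spline.degree, ctrl=spline.ctrl * scale)
    poly_len = float(np.linalg.norm(np.diff(scaled.ctrl[:, :2], axis=0), axis=1).sum())
    n0 = max(int(poly_len * 1.5) + 2, 4)
    ts = np.linspace(0.0, 1.0, n0)
    pts = evaluate(scaled, ts)
    for _ in range(32):  # adaptive refinement: insert parameter midpoints at gaps
        pix = np.floor(pts[:, :2] + 0.5).astype(np.int64)
        gaps = np.abs(np.diff(pix, axis=0)).max(axis=1) > 1
        if not gaps.any():
            break
        mid = (ts[:-1][gaps] + ts[1:][gaps]) / 2.0
        ts = np.sort(np.concatenate([ts, mid]))
        pts = evaluate(scaled, ts)
    if return_float:
        return ts, pts
    pix = np.floor(pts[:, :2] + 0.5).astype(np.int64)
    # per run of samples rounding to the same pixel, keep the sample closest
    # to the pixel centre (its radius best represents the pixel)
    new_run = np.ones(len(pix), dtype=bool)
    new_run[1:] = np.any(pix[1:] != pix[:-1], axis=1)
    starts = np.flatnonzero(new_run)
    ends = np.append(starts[1:], len(pix))
    d2 = ((pts[:, :2] - pix) ** 2).sum(axis=1)
    best = np.array([s + int(np.argmin(d2[s:e])) for s, e in zip(starts, ends)])
    return pix[best], pts[best, 2]
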