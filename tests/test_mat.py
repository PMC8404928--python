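import math

import numpy as np
import pytest

from sdmd.layering import BinaryLayer
from sdmd.mat import (
    Branch,
    MedialAxis,
    UnboundedLayerError,
    clip_mat,
    compute_mat,
    detect_border_segments,
    distance_transform,
    extend_border_branch,
    extend_samples,
    regularize,
    semi_disc_extend,
    trace_branches,
)
from sdmd.reconstruct import _stamp_disc

from conftest import random_blob, random_mask


def _layer(mask):
    return BinaryLayer(0, "upper", np.asarray(mask, dtype=bool))


def _brute_force_dt(mask):
    """Min distance to any background pixel centre, including the virtual
    background ring just outside the frame."""
    H, W = mask.shape
    padded = np.pad(mask, 1, constant_values=False)
    bys, bxs = np.nonzero(~padded)
    out = np.zeros((H, W))
    for y in range(H):
        for x in range(W):
            if mask[y, x]:
                d2 = (bys - (y + 1)) ** 2 + (bxs - (x + 1)) ** 2
                out[y, x] = math.sqrt(d2.min())
    return out


def _disc_union(ma, shape):
    rec = np.zeros(shape, dtype=bool)
    for (x, y), r in zip(ma.xy, ma.dt):
        _stamp_disc(rec, float(x), float(y), float(r))
    return rec


# ---------------------------------------------------------------------------
# distance transform


def test_dt_single_pixel_between_background():
    m = np.zeros((1, 3), dtype=bool)
    m[0, 1] = True
    dt = distance_transform(_layer(m))
    assert dt[0, 1] == 1.0


def test_dt_centre_of_ring():
    m = np.ones((7, 7), dtype=bool)
    m[0, :] = m[-1, :] = m[:, 0] = m[:, -1] = False
    dt = distance_transform(_layer(m))
    assert dt[3, 3] == 3.0


def test_dt_matches_brute_force(rng):
    for _ in range(5):
        m = random_mask(rng, 16)
        got = distance_transform(_layer(m))
        np.testing.assert_allclose(got, _brute_force_dt(m), atol=1e-9)


def test_dt_all_foreground_is_unbounded():
    with pytest.raises(UnboundedLayerError):
        distance_transform(_layer(np.ones((4, 4), dtype=bool)))


def test_dt_lipschitz(rng):
    m = random_blob(rng)
    dt = distance_transform(_layer(m))
    assert np.abs(np.diff(dt, axis=0)).max() <= 1.0 + 1e-9
    assert np.abs(np.diff(dt, axis=1)).max() <= 1.0 + 1e-9


# ---------------------------------------------------------------------------
# compute_mat


def test_mat_single_pixel():
    m = np.zeros((5, 5), dtype=bool)
    m[2, 2] = True
    ma = compute_mat(_layer(m))
    assert len(ma) == 1
    assert tuple(ma.xy[0]) == (2, 2)
    assert ma.dt[0] == 1.0


def test_mat_disc_centre_detected():
    yy, xx = np.mgrid[0:25, 0:25]
    m = (xx - 12) ** 2 + (yy - 12) ** 2 <= 100
    ma = regularize(compute_mat(_layer(m)), 1.0)
    assert len(ma) > 0
    # the most salient pixel is the disc centre carrying the full radius
    k = int(np.argmax(ma.sigma))
    assert max(abs(ma.xy[k][0] - 12), abs(ma.xy[k][1] - 12)) <= 1
    assert abs(ma.dt[k] - 10) <= 1


def test_mat_pixels_are_maximal_disc_centres(rng):
    # brute-force oracle: a maximal-disc centre is a pixel whose disc is
    # contained in no other pixel's disc; every reported MAT pixel must be
    # within Chebyshev distance 1 of such a pixel
    for _ in range(5):
        m = random_blob(rng, size=32, smooth=2.0, q=0.7)
        if m.sum() < 20:
            continue
        lay = _layer(m)
        dt = distance_transform(lay)
        ys, xs = np.nonzero(m)
        maximal = np.zeros_like(m)
        for y, x in zip(ys, xs):
            contained = False
            for y2, x2 in zip(ys, xs):
                if (y2, x2) != (y, x) and math.hypot(y2 - y, x2 - x) <= dt[y2, x2] - dt[y, x]:
                    contained = True
                    break
            maximal[y, x] = not contained
        mys, mxs = np.nonzero(maximal)
        for (x, y) in compute_mat(lay).xy:
            cheb = np.maximum(np.abs(mys - y), np.abs(mxs - x)).min()
            assert cheb <= 1


def test_mat_disc_union_rebuilds_layer(rng):
    for _ in range(10):
        m = random_blob(rng, size=64, q=0.6, clear_border=False)
        if not m.any() or m.all():
            continue
        ma = compute_mat(_layer(m))
        rec = _disc_union(ma, m.shape)
        assert np.logical_xor(rec, m).sum() <= 0.01 * m.sum()


def test_mat_deterministic(rng):
    m = random_blob(rng)
    a = compute_mat(_layer(m))
    b = compute_mat(_layer(m))
    np.testing.assert_array_equal(a.xy, b.xy)
    np.testing.assert_array_equal(a.rho, b.rho)


# ---------------------------------------------------------------------------
# regularize


def test_regularize_zero_threshold_is_identity(rng):
    ma = compute_mat(_layer(random_blob(rng)))
    assert regularize(ma, 0.0) is ma


def test_regularize_saliency_arithmetic():
    ma = MedialAxis(
        xy=np.array([[3, 3], [5, 5]]),
        dt=np.array([6.0, 4.0]),
        rho=np.array([12.0, 2.0]),
    )
    kept = regularize(ma, 1.4)
    assert len(kept) == 1 and tuple(kept.xy[0]) == (3, 3)  # sigma 2.0 vs 0.5


def test_regularize_monotone(rng):
    ma = compute_mat(_layer(random_blob(rng)))
    sets = []
    for thr in (0.5, 1.0, 1.5):
        kept = regularize(ma, thr)
        sets.append({tuple(p) for p in kept.xy})
    assert sets[2] <= sets[1] <= sets[0]


# ---------------------------------------------------------------------------
# border segments and semi-disc extension


def test_border_segments_interior_shape_empty(rng):
    m = np.zeros((20, 20), dtype=bool)
    m[5:15, 5:15] = True
    assert detect_border_segments(_layer(m)) == []


def test_border_segments_stripe():
    m = np.zeros((30, 30), dtype=bool)
    m[:, 10:21] = True
    segs = detect_border_segments(_layer(m))
    sides = {s.side: s for s in segs}
    assert sides["top"].a == (10, 0) and sides["top"].b == (20, 0)
    assert sides["bottom"].a == (10, 29) and sides["bottom"].b == (20, 29)
    assert set(sides) == {"top", "bottom"}


def test_border_segments_match_runs_oracle(rng):
    for _ in range(10):
        m = random_mask(rng, 12, p=0.6)
        segs = detect_border_segments(_layer(m))
        # oracle: simple per-edge run scan
        def runs(line):
            out, start = [], None
            for i, v in enumerate(line):
                if v and start is None:
                    start = i
                if not v and start is not None:
                    out.append((start, i - 1))
                    start = None
            if start is not None:
                out.append((start, len(line) - 1))
            return out

        expect = (
            len(runs(m[0])) + len(runs(m[-1])) + len(runs(m[:, 0])) + len(runs(m[:, -1]))
        )
        assert len(segs) == expect


def test_semi_disc_extend_no_contact_is_identity(rng):
    m = np.zeros((20, 20), dtype=bool)
    m[5:15, 5:15] = True
    layer = _layer(m)
    out, band = semi_disc_extend(layer)
    assert band == 0 and out is layer


def test_semi_disc_extend_geometry():
    m = np.zeros((30, 30), dtype=bool)
    m[0:12, 10:21] = True  # touches top with run (10,0)-(20,0), length 10
    out, band = semi_disc_extend(_layer(m))
    assert band == 5  # ceil(10 / 2)
    assert out.mask.shape == (40, 40)
    # semi-disc centred at (15, 0) + band offset, radius 5, extends upward
    assert out.mask[band - 5, 15 + band]  # top of the semi-disc
    assert out.mask[band - 1, 15 + band]
    assert not out.mask[band - 5, 5 + band]  # outside the disc
    # original foreground preserved at offset
    np.testing.assert_array_equal(out.mask[band : band + 30, band : band + 30], m)


def test_semi_disc_extension_removes_y_junctions():
    # vertical stripe through the whole frame: its skeleton has junctions
    # at the border contacts; after extension + clip they are gone
    m = np.zeros((40, 40), dtype=bool)
    m[:, 15:26] = True

    def junction_count(ma):
        pos = {tuple(p) for p in ma.xy}
        count = 0
        for (x, y) in pos:
            deg = sum(
                (x + dx, y + dy) in pos
                for dx in (-1, 0, 1)
                for dy in (-1, 0, 1)
                if (dx, dy) != (0, 0)
            )
            if deg >= 3:
                count += 1
        return count

    plain = regularize(compute_mat(_layer(m)), 1.0)
    assert junction_count(plain) >= 1
    ext, band = semi_disc_extend(_layer(m))
    fixed = clip_mat(regularize(compute_mat(ext), 1.0).translate(-band, -band), (40, 40))
    assert junction_count(fixed) == 0


# ---------------------------------------------------------------------------
# clip and extension


def test_clip_mat_identity_and_bounds(rng):
    ma = compute_mat(_layer(random_blob(rng, 32)))
    clipped = clip_mat(ma, (32, 32))
    assert len(clipped) == len(ma)

    shifted = ma.translate(-5, 0)
    clipped = clip_mat(shifted, (32, 32))
    x = shifted.xy[:, 0]
    assert len(clipped) == int(((x >= 0) & (x < 32)).sum())


def test_clip_mat_flags_cut_pixels():
    ma = MedialAxis(
        xy=np.array([[0, 5], [1, 5], [-1, 5], [10, 10]]),
        dt=np.ones(4),
        rho=np.ones(4) * 4,
    )
    clipped = clip_mat(ma, (20, 20))
    flags = {tuple(p): b for p, b in zip(clipped.xy, clipped.border)}
    assert flags[(0, 5)]  # lost its out-of-frame neighbour
    assert not flags[(10, 10)]


def test_extend_samples_stopping_rule():
    # constant radius 3 moving straight out of the top edge: samples are
    # appended until the distance outside reaches the radius
    chain = np.array([[5.0, 1.0, 3.0], [5.0, 0.0, 3.0]])
    ext = extend_samples(chain, (20, 20))
    assert len(ext) == 3  # y = -1, -2, -3; stops at dist_out 3 >= r
    np.testing.assert_allclose(ext[-1], [5.0, -3.0, 3.0])


def test_extend_samples_zero_radius_adds_nothing():
    chain = np.array([[5.0, 1.0, 0.4], [5.0, 0.0, 0.2]])
    assert len(extend_samples(chain, (20, 20))) == 0


def test_extend_samples_inward_direction_adds_nothing():
    chain = np.array([[5.0, 0.0, 3.0], [5.0, 1.0, 3.0]])  # moving into the frame
    assert len(extend_samples(chain, (20, 20))) == 0


def test_extend_border_branch_requires_flag():
    br = Branch(samples=np.array([[1.0, 1.0, 2.0], [2.0, 1.0, 2.0]]))
    with pytest.raises(ValueError):
        extend_border_branch(br, (10, 10))
    flagged = Branch(
        samples=np.array([[5.0, 2.0, 3.0], [5.0, 0.0, 3.0]]),
        end_flags=("free-end", "border-touch"),
    )
    out = extend_border_branch(flagged, (10, 10))
    assert len(out) > 2
    assert (out.samples[2:, 1] < 0).all()


# ---------------------------------------------------------------------------
# branch tracing


def _axis_from_pixels(pixels, dt=2.0):
    xy = np.array(sorted(pixels, key=lambda p: (p[1], p[0])))
    return MedialAxis(xy=xy, dt=np.full(len(xy), dt), rho=np.full(len(xy), 8.0))


def test_trace_straight_segment():
    ma = _axis_from_pixels([(x, 5) for x in range(3, 13)])
    branches = trace_branches(ma)
    assert len(branches) == 1 and len(branches[0]) == 10


def test_trace_x_shape_splits_at_junction():
    # four diagonal arms meeting at one centre pixel (a clean junction in
    # 8-connectivity, unlike an axis-aligned cross whose inner pixels touch)
    pixels = {(5, 5)}
    for k in range(1, 4):
        pixels |= {(5 + k, 5 + k), (5 - k, 5 - k), (5 + k, 5 - k), (5 - k, 5 + k)}
    ma = _axis_from_pixels(sorted(pixels))
    branches = trace_branches(ma)
    assert len(branches) == 4
    for br in branches:
        # each arm carries the duplicated junction pixel at one end
        ends = [tuple(br.samples[0, :2]), tuple(br.samples[-1, :2])]
        assert (5.0, 5.0) in ends
        assert "junction" in br.end_flags


def test_trace_covers_every_pixel_once(rng):
    from skimage.morphology import skeletonize

    for _ in range(5):
        skel = skeletonize(random_blob(rng, 48, q=0.55))
        ys, xs = np.nonzero(skel)
        if len(ys) < 3:
            continue
        ma = _axis_from_pixels(list(zip(xs, ys)))
        branches = trace_branches(ma)
        pos = {tuple(p) for p in ma.xy}
        counts = {p: 0 for p in pos}
        junctions = set()
        for p in pos:
            deg = sum(
                (p[0] + dx, p[1] + dy) in pos
                for dx in (-1, 0, 1)
                for dy in (-1, 0, 1)
                if (dx, dy) != (0, 0)
            )
            if deg >= 3:
                junctions.add(p)
        for br in branches:
            for x, y, _ in br.samples:
                counts[(int(x), int(y))] += 1
            d = np.abs(np.diff(br.samples[:, :2], axis=0)).max(axis=1)
            assert (d <= 1).all()  # consecutive samples 8-connected
        assert all(c >= 1 for c in counts.values())
        for p, c in counts.items():
            if p not in junctions:
                assert c <= 2  # interior pixels once; cycle closure may repeat


def test_trace_deterministic(rng):
    from skimage.morphology import skeletonize

    skel = skeletonize(random_blob(rng, 48, q=0.55))
    ys, xs = np.nonzero(skel)
    ma = _axis_from_pixels(list(zip(xs, ys)))
    a = trace_branches(ma)
    b = trace_branches(ma)
    assert len(a) == len(b)
    for ba, bb in zip(a, b):
        np.testing.assert_array_equal(ba.samples, bb.samples)
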