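# Methods

`sdmd` compresses 8-bit grayscale and colour raster images by storing, for a
small set of threshold layers, the B-spline control points of each layer's
medial axis transform. This note documents the model, the numerical choices,
the synthetic benchmark, and the limits of what the tests demonstrate.

## Model

An image channel `I : Z^2 -> [0,255]` is decomposed into upper threshold
sets `T_i = {x : I(x) >= i}` for `L` selected intensities. Each binary layer
is represented by its medial axis transform (MAT): the skeleton `S(T_i)`
together with the distance transform `DT(x)` (radius of the maximal
inscribed disc centred at `x`). The layer is recovered as the union of
discs `B(x, DT(x))` over skeletal pixels, layers are painted atop each
other in increasing intensity, and banding between consecutive layers is
blended away using distance transforms of the rendered masks.

Instead of storing skeleton pixels, every skeleton branch — an 8-connected
simple path of `(x, y, DT)` samples — is fitted with a clamped uniform-knot
B-spline in 3D. The encoder searches control-point counts upward (degree
1..3 per count) and accepts the first fit whose maximum 3D deviation at the
chord-length parameters is within `tau = gamma * diag(image)`; if no fit
with at most 64 control points succeeds, the branch is split at its
worst-fit sample and both halves are fitted recursively. Decoding converts
each spline to Bezier segments by knot insertion and evaluates them with de
Casteljau's algorithm, subdividing until consecutive samples round to
8-connected pixels. Because only control points are stored and the
tolerance is relative to the image diagonal, the same encoding can be
rasterised at any target scale (super-resolution costs no extra storage).

Three encoder refinements:

- **Adaptive polarity.** For each selected intensity the encoder also tries
  the lower set `{I <= i-1}` (whose complement is exactly the upper set)
  and keeps whichever needs fewer control points, recording a flip bit.
  Thin dark structures — outlines, strokes, glyphs — are dramatically
  cheaper as lower sets. We threshold the lower candidate at `i-1`, not
  `i`: the complement of `{I <= i}` is `{I > i}`, which differs from the
  upper set exactly on pixels whose value equals a selected intensity, and
  synthetic imagery concentrates much of its mass there (a binary image
  would lose its entire top layer under the `i` convention).
- **Per-channel scaling.** Colour images are encoded as full-resolution
  Y/Cb/Cr planes (full-range BT.601); the chroma planes use the scaled
  parameter set `(round(n1*L), min(1, n2*eps), n3*sigma, n4*gamma)` with
  defaults `n1=0.5, n2=5, n3=2, n4=1`, exploiting the eye's lower chromatic
  acuity.
- **Border Y-structure removal.** A layer touching the image border is
  bounded there by the frame itself, which spawns Y-shaped junctions in the
  skeleton. Each maximal border-contact run `A_jB_j` is capped with an
  outward semi-disc (radius `|A_jB_j|/2`) on an enlarged canvas before
  skeletonisation; the skeleton is then clipped back to the frame. At
  decode time, clipped branch ends are prolonged linearly until the medial
  disc is tangent to the image edge (the 45-degree-plane stopping rule).
  Out-of-frame skeleton branches whose discs still reach at least one pixel
  into the image and that never cross the frame (so no clipped end exists
  to prolong from — typically the medial of a large border cap running
  parallel to the edge) are stored as-is; the container's coordinate range
  `[-w, 2w] x [-h, 2h]` exists for them.

## Skeletonisation

The skeleton is computed on the CPU by boundary collapse. Boundary contours
of the (frame-padded) layer are traced as ordered chains of boundary
pixels; the exact Euclidean feature transform assigns every foreground
pixel its nearest boundary pixel; and a pixel is skeletal when the chain
positions of the features seen across it and its 8-neighbours jump by at
least the *detection granularity*. Non-skeletal pixels see jumps of at most
2 chain steps, and the staircase corners of digitised smooth edges produce
jumps up to roughly one run length, so the granularity is 4 boundary pixels
for small images and grows proportionally to the image diagonal above
512 px (8 per 512-diagonal). The proportional regime is what keeps the
stored representation scale-invariant: with a fixed absolute threshold,
re-rendering the same scene at twice the resolution admits a fresh
population of staircase-noise branches and the control-point count
quadruples; with the relative threshold the counts agree within 1%.
DT local maxima with `DT <= 2` are added to capture 1–2 px thin structures
that single-sided feature assignment misses, and the union is thinned to a
one-pixel-wide skeleton.

**Boundary importance and pruning.** Each skeletal pixel carries
`rho` = the feature jump across it, in boundary pixels (thin-structure
pixels carry at least 2; a component collapsed to a single pixel carries
its disc perimeter). Regularisation keeps pixels with saliency
`sigma = rho / DT >= sigma_thr`; this removes branches encoding small
boundary perturbations while keeping those encoding large-scale features.

**Coverage completion.** A one-pixel-wide pruned skeleton loses roughly
half a pixel of rim along curved boundaries (5–6% of the foreground of a
64x64 blob), because many maximal discs there are centred off the ridge.
The MAT therefore also includes every pixel whose maximal disc is contained
in no 8-neighbour's disc (the Lipschitz containment test
`DT(y) >= DT(x) + |x-y|`; containment is transitive, so the union of the
kept discs reproduces the layer *exactly*). No boundary interval collapses
onto these fringe pixels, so they carry sub-pixel importance 0.5 and every
practical saliency threshold (>= 0.6) prunes them: the unregularised MAT is
exact, while the encoder path stays compact.

## Reconstruction conventions

- `DT` is the distance to the nearest background pixel centre, with the
  frame counting as background. Discs are stamped with strict inclusion
  `||p - c|| < r`, the unique rule with zero overshoot under that
  convention (non-strict stamping overpaints a full one-pixel ring around
  every axis-aligned edge). Stamping is implemented as an exact scanline
  interval union, O(sum of radii) rather than O(sum of radii squared).
- Inter-layer blending: a pixel inside layer `v_i` but outside `v_{i+1}`
  takes `v_i + (v_{i+1}-v_i) * d_i / (d_i + d_{i+1})` where `d_i` is its
  depth inside the rendered layer and `d_{i+1}` its distance to the next
  layer; the value is continuous at both layer boundaries. A layer whose
  rendered mask covers the whole frame has no lower contour, so its band is
  left at the painted value (blending against the frame would smear flat
  dark detail toward the next layer).
- Layer selection: "histogram" (default) greedily adds the intensity that
  most reduces the total per-pixel quantisation error of the layered
  approximation; "uniform" spaces L intensities evenly over the channel's
  range. The channel minimum is always included as the base layer.
- Island removal deletes 8-connected foreground components smaller than
  `eps * |T_i|`. Background holes are *not* filled: a hole is an island of
  the opposite polarity and is filtered there when that polarity is
  encoded, whereas filling holes against the (typically much larger)
  upper-set size erases legitimate thin dark detail, after which the
  polarity optimiser happily stores the now-trivial layer and the detail is
  gone.
- Container: coordinates are quantised to 16 bits over `[-w, 2w] x [-h, 2h]`
  (~0.023 px at 512); radii over `[-2, diag]` — the small negative headroom
  absorbs least-squares overshoot of radius control points near thin
  structures (negative radii stamp nothing, and deeper lobes are flattened
  to the floor, which is reconstruction-lossless). Counts are LEB128
  varints; a layer costs 3 bytes plus 6 bytes per control point.

## Parameters

| name | meaning | default | unit |
| --- | --- | --- | --- |
| `L` | threshold layers per channel | 18 | count (presets 10–20) |
| `eps` | island threshold | 0.01 | fraction of layer foreground |
| `sigma` | saliency pruning threshold | 1.0 | boundary px per radius px (presets 0.6–1.4) |
| `gamma` | spline fit tolerance | 0.002 | fraction of image diagonal |
| `n1..n4` | chroma multipliers for (L, eps, sigma, gamma) | 0.5, 5, 2, 1 | — |

All four main knobs trade quality against compression; on the gradient
benchmark image every one of them moves SSIM down and CR up monotonically
when pushed toward stronger compression (the gamma sweep is sampled upward
from the preset — below it the tolerance drops under the pixel quantisation
noise of the skeleton itself, where a slightly looser fit acts as a
denoiser and quality is not monotone).

## Synthetic benchmark

Medial codecs target imagery made of sizeable shapes over smooth
backgrounds; `make_fixture` generates six such classes procedurally
(spiral stroke leaving the frame, cushion treemap, anti-aliased discs over
a colour gradient, full-frame colour bands, outlined cartoon blobs over a
colour-gradient backdrop, glyph-like strokes). Geometry is expressed in
unit coordinates scaled by the image size, so the same seed at two sizes
depicts the same scene — the basis of the resolution-sweep experiment. The
treemap uses 8 cells at 512^2, matching the cell-per-pixel density of
published cushion treemaps; the cartoon backdrop and blob counts are chosen
so the colour classes carry both luma and chroma structure.

What the fixtures do *not* emulate: sensor noise, texture, and high spatial
frequencies (where medial codecs are known to do poorly), camera optics,
and natural-image statistics generally. Quantitative results on them bound
behaviour on clean synthetic imagery only.

Experiment sizes (chosen once for the test budget): unit tests <= 160 px;
comparison experiments 256^2; quality floor 512^2; resolution sweep
512 vs 1024; super-resolution 500^2 -> 3000^2.

## Known limitations

- **Cross-scale consistency.** Decoding at scale 1 versus box-downsampling
  a scale-2 decode differs by ~0.3 x (contour length / area) x (intensity
  step) on average: boundary positions re-quantise at each target grid.
  For a low-contour-density image (a large two-tone disc) the mean
  difference is well under 2 intensity levels; on the 500^2 benchmark
  classes it measures 2.2–3.4 because their contour density times contrast
  exceeds that budget. This is a sampling-floor property of binary disc
  stamping, not a fixable bug short of anti-aliased rendering.
- **Per-channel savings need chroma detail.** The chroma scaling mechanism
  prunes small/low-saliency chroma structure; on the flat-colour classes
  (cartoon, border bands) there is little to prune and the byte saving is
  ~0.5–14% rather than the >= 15% it reaches on the chroma-rich treemap
  class (22% at 256^2).
- SSIM for colour images is computed on the luma plane, so pure chroma loss
  is underweighted by the quality metric.
- The interpolation blend uses nonlocal distances; in large flat regions
  lying strictly between two selected intensities it can shift values by a
  few levels based on faraway structure.
- Images above 65535 px per side are not representable in the container
  (u16 dimensions).
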