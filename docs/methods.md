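# Methods

This note documents the models, procedures, and numerical choices behind
`terralabel`, and what the synthetic-scene experiments do and do not show.

## Grid conventions

All rasters are row-major with the map origin at the top-left corner, pixel
coordinates 0-based, extents half-open, and each pixel's value located at
its center. Map axes are planar with east = +x and north = +y, so row index
grows southward. Azimuths are degrees clockwise from geographic north; the
anti-solar displacement direction is `(sin(az+180°), cos(az+180°))` in
(east, north) components. Bilinear resampling evaluates output pixel centers
against the four nearest input centers (clamped at edges) and propagates
nodata strictly: any output pixel whose 2×2 stencil touches nodata becomes
nodata, so reflectance is never fabricated. Boolean masks are coarsened with
an *any* rule (a coarse cell is flagged if any covered fine cell is), a
deliberately conservative choice: over-masking discards usable pixels,
under-masking contaminates products.

## Cloud and shadow masking

The cloud mask is computed at 20 m in three steps and the defaults are:

| parameter | default | meaning |
|---|---|---|
| `s2c_threshold` | 0.65 | cloud-probability threshold (≥) |
| `cdi_threshold` | −0.5 | parallax threshold (strict <) |
| `cdi_window` | 7 px | window of the local-variance estimate |
| `cirrus_threshold` | 0.01 | B10 reflectance threshold (≥) |
| `cirrus_mode` | union | how the cirrus mask combines with the core mask |
| `opening_radius` | 1 px | structuring disk of the morphological opening |
| `shadow_distance_m` | 5000 | length of the anti-solar shadow extension |
| `compute/final_pixel_size` | 20 / 100 m | working and output resolutions |

The Cloud Displacement Index is computed from the ratio fields r1 = B7/B8A
and r2 = B8/B8A as `CDI = (V(r2) − V(r1)) / (V(r2) + V(r1))` with V a
window-variance estimate (population variance over `cdi_window`²,
reflect-padded), defined as 0 where both variances vanish and invalid where
B8A = 0. Elevated clouds give the two near-infrared ratios very different
local variance while flat bright targets (metal roofs, sand, snow patches)
do not, so requiring `CDI < −0.5` *in conjunction with* the
cloud-probability threshold removes commission errors over bright ground.
The threshold-boundary semantics (≥ for s2c and cirrus, strict < for CDI)
are fixed so outputs are bit-stable.

`cirrus_mode` defaults to *union* (core ∨ cirrus): a literal intersection
with the cirrus threshold would erase every cloud without a cirrus top,
defeating the mask's purpose; the intersection variant is retained as a
config option for sensitivity studies.

The shadow step is a directional distance transform: a pixel is
shadow-flagged iff some cloud pixel lies within `shadow_distance_m` behind
it along the anti-solar ray. It is implemented as a sweep of shifted copies
of the cloud mask, one OR per unique rounded pixel offset along the ray,
which is exactly equivalent to per-pixel ray casting (the test suite checks
the equivalence on random masks and azimuths). For one isolated cloud pixel
at 20 m the extension spans ⌊5000/20⌋ = 250 pixels = 5 km.

## Reflectance normalization

Top-of-atmosphere reflectance is concentrated near the dark end with a long
bright tail. Normalization is `x → logistic(g(log max(x, ε)))` with
ε = 10⁻⁴ guarding log(0), where `g` interpolates the fitted per-band
percentiles {1, 5, 50, 95, 99} of the log values onto sigmoid arguments
{−3, −1.5, 0, 1.5, 3} piecewise-linearly and extrapolates beyond the end
breakpoints with the terminal segment slopes. The map is strictly monotone
and bounded on (0, 1) with no hard clipping; the percentile set and anchor
values are frozen configuration (symmetric anchors put the fitted median at
0.5). Stats are fitted once on a training corpus and serialized; inference
loads them and never refits per scene, matching a single global model.

*Numerical limitation*: when a band's fitted 95th and 99th percentiles are
nearly equal (a distribution with no bright tail, as in low-noise synthetic
scenes), the terminal slope is steep and float64 saturates the logistic to
exactly 1.0 a little beyond the last breakpoint. The transform is designed
for long-tailed reflectance, where the slopes stay moderate and the open
bound holds far beyond 100× the 99th percentile.

## Annotation preparation

Annotations are polygons over a 10-class taxonomy (the nine product classes
plus cloud, class 9). Rasterization labels a pixel by the polygon containing
its center, resolving overlaps by the highest draw order. One-hot targets
are smoothed toward uniform according to annotator confidence,
`t(k) = (1−ε)[k=c] + ε/K` with ε = 0.2 (expert) or 0.3 (non-expert): at
K = 10 that puts 82 % / 73 % of the mass on the annotated class, mirroring
the observed non-expert-to-expert agreement level.

Three per-pixel weights are produced: *class balance* `T/(C·n_c)` over the
corpus (conserving total mass, Σ n_c w_c = T); *high-frequency*
`1 + β·‖∇x‖` (β = 4, mean gradient magnitude over bands) used by the
synthesis loss so reconstruction attends to spatial detail; and *edge
attenuation* (1.0 within `d_edge` = 2 px of a label boundary, 0.5 deeper
inside) down-weighting polygon interiors where annotators gloss over small
inclusions. The classification weight is class-balance × edge. The edge
kernel and interior factor are package choices; only the existence of the
three weights is inherited from the problem statement.

Augmentation makes 4 copies of each example with independent rotations from
{0°, 90°, 180°, 270°} (applied identically to all per-pixel fields — exact
index permutations, no resampling artifacts) and per-band contrast
`x → x^γ`, γ ∈ [0.8, 1.25], a monotone transform closed on (0, 1).

## The dual-pathway model

The labeling model is a fully convolutional dilated-residual stack: a 3×3
stem into 32 channels, four residual blocks `x → x + ReLU(conv3×3_d(x))`
with dilations 1, 2, 4, 8 (a 31-pixel receptive field), and a 1×1 head onto
9 classes with channel-softmax — about 4.1×10⁴ parameters, orders of
magnitude below standard segmentation architectures. The synthesis model is
an architectural replica mapping the 9-class distribution back to the 9
input bands through a sigmoid. Both are implemented in numpy (float32,
im2col convolutions) with explicit backprop.

Losses: the classification term is weighted cross-entropy between the
smoothed targets (cloud column dropped and the remaining 9 renormalized)
and the predicted distribution, over pixels that are labeled, clear, and
not annotated cloud; the synthesis term is high-frequency-weighted mean
squared reconstruction error over all clear pixels, labeled or not — this
is the weak supervision: unlabeled or sloppily labeled pixels still
constrain the model through reconstruction. Total = classification +
λ·synthesis (λ = 1). Gradient routing is asymmetric: the labeling model
receives gradients from both terms (the synthesis term reaching it through
the replica's input), while the synthesis model is updated only by its own
term. With λ = 0 the synthesis model is untouched and training reduces
exactly to supervised training.

Optimization uses Adam (lr 5×10⁻³, β = 0.9/0.999) with one parameter update
per example (batch size 1) for 20 epochs — frozen defaults chosen so the
loss decreases reliably on synthetic corpora within a CPU-minutes budget.
Training is deterministic given the seed up to BLAS reduction order.

## Inference, products, aggregation

Inference keeps bands B2, B3, B4, B5, B6, B7, B8, B11, B12 (dropping B1,
B8A, B9, B10), bilinearly upsamples to 10 m, normalizes, and applies the
labeling model. Products carry nine probability bands summing to 1 at every
valid pixel plus a Top-1 label band in [0, 8]; argmax ties break toward the
lowest class index. The 100 m mask is expanded to 10 m by nearest
replication (each coarse cell masks its whole block — again the
conservative reading). Collections are filtered at cloudiness strictly
below 35 % (the boundary is excluded; the threshold semantics at exactly
35 % are a frozen package choice).

Composites use half-open time windows `[start, end)`. The mode composite
tallies Top-1 labels over valid observations; the mean composite averages
probability vectors (a convex combination, hence still on the simplex) and
takes the argmax of the mean. Pixels never observed are nodata.

## Validation

Three expert annotations fuse per pixel under four schemes — Three Expert
Strict (all three present and agreeing), Expert Consensus (every present
opinion agrees, at least one present), Expert Majority (an agreeing pair,
or a lone opinion), Expert Simple Majority (at least two present and an
agreeing pair). The scheme definitions follow the campaign's prose
descriptions. Valid sets nest: strict ⊆ consensus ⊆ majority, with labels
equal where jointly valid. Confusion matrices have candidate rows and
reference columns, precision (user's accuracy) on rows and recall
(producer's accuracy) on columns; overall agreement is trace / n. Cloud
participates in annotator-to-annotator comparisons but cloud-reference
pixels are dropped when the candidate is a model product, which has no
cloud class. Crosswalks to coarser external maps upsample
nearest-neighbour, remap classes totally (a missing entry is an error
naming the class), then tally.

## Synthetic scenes: what they emulate, and what they do not

The generator draws patchy label worlds on a coarse grid of blocks the size
of the minimum mapping unit (5×5 pixels = 50 m), which guarantees every
patch respects the MMU by construction; per-class biases on smoothed
Gaussian score fields are tuned iteratively toward a target class mixture.
Tiles default to 510×510 pixels; any edge divisible by 30 keeps all native
grids (10/20/60 m) and the 100 m finalization aligned. Rendering assigns
each class a fixed mean spectrum per band plus Gaussian noise (σ = 0.012
reflectance) at 10 m; 20 m and 60 m bands are block means of the 10 m
field, as a coarser detector integrating the same radiance would record.
Clouds are random ellipses with a brightness boost (+0.55), near-1 cloud
probability, and a B10 cirrus signal; over clouds the B7/B8A ratio receives
a smooth multiplicative ripple so the two CDI ratio fields have distinct
local variance, while an optional bright "building" gets a uniform boost
and a high cloud probability — the commission error the parallax step must
correct. Shadows are the cloud mask displaced 1 km anti-solar (within the
5 km extension by construction) and darkened ×0.35. Annotators operate on
the connected constant-label patches: each may skip patches (never dropping
below its 70 % coverage floor) and flips whole patches through a
row-stochastic confusion kernel, mimicking polygon-level disagreement.

What passing on this substrate shows: the masking logic discriminates
parallax-textured clouds from bright uniform targets; the geometry of the
shadow transform is exact; the training loop recovers a label model when
classes are spectrally separable (a nearest-class-mean oracle reaches ≥0.9
on rendered scenes, and the trained network ≥0.85 — in practice ≈0.99 — on
held-out tiles); and every schema contract holds end to end. What it does
not show: performance under real atmospheric variability, mixed pixels,
BRDF and topographic effects, detector geometry, or human annotation
pathologies — the spectra here are idealised and class-separable by
construction.

## Problem sizes

The recovery experiment uses 40 training + 6 held-out tiles of 126×126
pixels (the nearest MMU- and resolution-aligned size to 128) at default
noise, ≈7 CPU-minutes; the masking-discrimination study uses 20 seeds of
126-pixel tiles at 12 % cloud cover; the acceptance script trains on six
90-pixel tiles for 6 epochs, which is ample for its schema-level targets.
These sizes are the package's standard desk-scale study conditions.

## Known limitations

* The numpy network trains on one CPU; there is no GPU path and no
  mini-batch parallelism beyond BLAS.
* Normalization saturates in float64 for bands whose fitted upper
  percentiles coincide (see above).
* No CRS handling: all grids share one planar coordinate frame; GeoTIFF
  georeferencing is carried in JSON sidecars rather than TIFF tags.
* The synthesis loss is plain weighted MSE; perceptual or spectral-angle
  reconstruction losses were not explored.
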