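# Methods

This note records the models, conventions and design choices behind the
pipeline, in the order the stages run.

## Grayscale and coordinates

All gray-level work uses broadcast luma, `round(0.299 R + 0.587 G +
0.114 B)`, on a 0–255 scale. Coordinates are 0-based row-major; a
quadtree block is the half-open rectangle `[top, top+h) x [left, left+w)`.

## Split-and-merge segmentation

The segmenter assumes a single object of interest roughly centered in the
frame, photographed under lighting that drifts smoothly across the scene.
A global threshold fails on such scenes because the background's gray
range overlaps the object's; the quadtree approach localizes the
decision.

**Split.** A block is homogeneous iff `max − min ≤ split_tolerance`
(default 20 gray levels). Inhomogeneous blocks split into four quadrants
(floor/ceil halves for odd sides, no padding) until homogeneous or at
`min_size` (default 4 px). The cheap range predicate is deterministic and
makes the split independent of pixel order.

**Merge.** Adjacent homogeneous blocks whose means differ by at most
`merge_tolerance` (default 10) merge transitively through the block
adjacency graph (4-adjacency of pixels by default), via union-find on
static block means. Using static means keeps the result independent of
merge order and makes the region count monotone in the tolerance.

**Mixed blocks.** Blocks still inhomogeneous at `min_size` straddle
region boundaries or lie in heavily textured areas. They are excluded
from the union-find: boundary-straddling blocks take intermediate means
(one per coverage fraction), and letting them participate builds a
stepping-stone chain that can transitively merge the object into the
background. Instead, mixed blocks first merge among themselves (same
tolerance), then each *pixel* of a mixed group joins the adjacent clean
region whose mean matches its gray value within `merge_tolerance`; the
unmatched remainder becomes a region of its own. A razor-sharp edge thus
dissolves cleanly into its two sides, while a textured object whose
blocks are all inhomogeneous survives as one region. Leftover regions may
in principle be disconnected; in practice they are thin edge remnants or
texture cores. Region means reported for merged regions are the
area-weighted means of their clean blocks.

**Foreground rule.** Regions touching the frame border are clustered by
mean-gray similarity (single linkage, gap ≤ `merge_tolerance`); the
cluster with the largest total area is background, everything else is
foreground. This encodes the assumption that the object is centered and
never dominates the border. A homogeneous image therefore has no
foreground and raises an error rather than guessing.

**Otsu baseline.** The classical maximum-between-class-variance threshold
(smallest maximizing level, for determinism), with the smaller-border-share
side taken as the object. Kept as the comparison baseline the segmenter
is designed to beat under gradient lighting.

## The 79-feature descriptor

Fixed layout: indexes 0–63 color, 64–70 texture, 71–78 shape. The layout
is validated on assembly and serialized with every model so a fitted
pipeline can refuse foreign feature tables.

**Color (64).** Each RGB channel is quantized to 4 bins of width 64; the
cell index is `bR*16 + bG*4 + bB`. Only foreground pixels count
(configurable). The stored features are the normalized fractions, making
them invariant to object scale as well as to translation and rotation.

**Texture (7).** The grayscale object is requantized to G = 64 levels
(`level = gray // 4`). For a displacement (δ₁, δ₂) — default (1, 1) —
histograms of pixel-pair sums `s = I(k,l) + I(k+δ₁,l+δ₂)` and differences
`d = I(k,l) − I(k+δ₁,l+δ₂)` are tallied over all pairs lying fully inside
the mask, then normalized to probability masses P_s (support 0..2(G−1))
and P_d (support −(G−1)..G−1). The seven indexes are mean, contrast,
homogeneity, energy, variance, correlation and entropy as given in the
README; natural-log entropy with 0·log 0 := 0. Normalizing first keeps
energy and homogeneity in (0, 1]; the identity σ² = C_r + C_n holds by
construction and is asserted in the tests. Note the difference histogram
is a *difference* even though sum and difference definitions are easily
conflated: with d := s the whole construction degenerates.

**Shape (8).** Area is the pixel count. Perimeter is the crack-edge
count: the number of unit edges between a foreground pixel and background
(the frame border counts as background) — integer-exact and additive.
Euler number = 8-connected foreground components minus 4-connected
interior holes (the complementary connectivities avoid the classic
paradox of a diagonal line enclosing a hole). The convex hull is computed
by the package's own Graham scan over the corner points of boundary
pixels; convex area counts pixel centers inside or on the hull, evaluated
with exact integer cross products on doubled coordinates (corners sit at
integers, centers at half-integers). Solidity = area / convex area.
Ellipse axes come from the central second moments of the pixel centers
plus a 1/12 per-pixel variance correction (a single pixel then has
nonzero axes), with `major = 4√λ₁`, `minor = 4√λ₂`,
`ecc = √(1 − λ₂/λ₁)` — the convention in which a solid disk of radius r
gets axis lengths 2r.

## Normalization and PCA

Features are standardized column-wise (mean 0, sample standard deviation
1, ddof = 1); zero-variance columns are flagged and pinned to deviation 1
so they transform to constant 0. PCA is the eigendecomposition of the
sample covariance of the standardized data, components ordered by
decreasing eigenvalue with a deterministic sign convention (the
largest-magnitude loading entry of each component is positive). The
retained dimension k is the smallest number of leading components whose
cumulative explained-variance fraction reaches the energy threshold
(default 0.95). Fitting happens on training data only; held-out folds are
projected with the training fit — the leakage-free reading of an
otherwise ambiguous protocol.

## Binary SVM and multiclass schemes

The soft-margin dual

max Σαₙ − ½ ΣΣ αₙαₘ yₙyₘ k(xₙ, xₘ)  s.t. 0 ≤ αₙ ≤ C, Σαₙyₙ = 0

is solved by sequential minimal optimization with second-order working-set
selection: the first index is the maximal KKT violator of the "up" set,
the second maximizes the guaranteed objective decrease
(g_i − g_j)²/η_ij, which keeps the solver fast on degenerate (low-rank)
Gram matrices where maximal-violating-pair selection zigzags. Multipliers
within 1e-10·C of a box bound snap to the bound so they leave the working
sets. The loop stops when the maximal violation falls below `tol`
(default 1e-3, absolute — callers with poorly scaled kernels should
standardize their inputs, as the pipeline itself does); a step budget
(default 10⁶ pair updates) guards against pathological inputs with a
diagnostic error. The bias is the midpoint of the feasible KKT interval,
refined by averaging over on-margin support points when any exist, in the
convention `f(x) = Σ yₙαₙ k(xₙ, x) − b`. `dual_qp_reference` provides an
independent SLSQP solve of the same dual for validation; it is never used
in production training.

Decisions: `O(x) = sgn(f(x))` with `sgn(0) := +1`, so every prediction is
defined. WTA trains C one-vs-rest machines and takes the argmax of
decision values (ties to the smallest class index). MWV trains the
C(C−1)/2 one-vs-one machines — class i is +1 in machine (i, j), i < j —
and takes the most-voted class (ties to the smallest index). DAG shares
the MWV bank but eliminates sequentially from the candidate list [1..C]
by evaluating the (first, last) machine, always exactly C−1 evaluations.
The default GRB scale, used when none is given, is `1/(p·var(X))` of the
(reduced) training features; `tune_kernel` grid-searches kernel
parameters by mean CV error (ties to the earliest grid entry), with
default grids d ∈ {1..5} and γ ∈ {2⁻⁶..2⁴}.

## Evaluation protocol

`stratified_split` allocates `floor(f·n_c)` of each class to training and
tops up to `floor(f·N)` from the largest fractional remainders — the 18
published class sizes of the original 1,653-image collection then give
exactly 1,322 / 331 at f = 4/5. `stratified_kfold` shuffles within class
(seeded) and deals round-robin, rotating the starting fold by the running
remainder so overall fold sizes also differ by at most one. The confusion
matrix is *predicted on rows, target on columns*; per-class rates are
diagonal over column sum, reported as percentages at a configurable
precision (the conventional reports mix one and two decimals); overall
accuracy is trace over total; CV accuracy is the unweighted mean of fold
accuracies. All randomness flows from explicit seeds recorded in outputs.

## Synthetic image generator

The generator renders what the pipeline assumes: one object, roughly
centered (margin ≥ 10% of the 256 px frame), on a gray background with an
oriented linear gradient (±40 levels) plus a shallow radial bowl (±10)
around a base of 60 — the non-uniform lighting that defeats global
thresholding. The same light field shades the object surface, so object
colors drift smoothly across the frame and object/background contrast is
locally preserved. Object appearance stacks: a per-image color jitter
(±8/channel), low-frequency per-channel surface mottle (σ = 8, 6×6
cells, cubic-upsampled), optional texture (stripes or speckle), a camera
point-spread blur (σ = 0.5 px) and Gaussian pixel noise (σ = 3). The
mottle and blur matter beyond cosmetics: perfectly flat-colored objects
produce near-discrete color histograms whose rare bins explode under
z-scoring, a pathology real photographs do not have. Shapes are ellipses,
superellipses ("rounded-rect") or blobs (low-order radial harmonics),
with radius 0.45–0.62 of the half-frame.

Three six-class presets isolate descriptor families: `color6` (color
structure), `texture6` (equal colors, different patterns), `shape6`
(equal colors and textures, different geometry). `color6` deliberately
contains, besides three solid-color classes, a *bicolor* class (each
fruit shows two skin colors at once, like bicolor apples) and a
*ripeness-shifting* class (each fruit is entirely one of two colors, like
passion fruit — the class occupies two separate modes). The shifting
pair shares its luma, so the distinction is purely chromatic, and its two
colors are exactly the bicolor class's: the shifting class's feature
region must then contain both color modes but exclude their mixtures,
which is non-convex — no argmax of linear one-vs-all machines can
realize it, while pairwise RBF machines separate all clusters. This makes
the qualitative scheme ordering (pairwise RBF above linear one-vs-all) a
structural property of the data rather than a tuned margin. Bimodal
classes alternate their mode with the image index so cross-validation
folds always train on both modes.

What the generator does *not* emulate: real specularities and cast
shadows, perspective and 3-D shading, backgrounds with clutter or
multiple objects, JPEG artifacts, and the long-tailed intra-class
variability of photographs gathered in the wild. Passing the end-to-end
tests therefore shows the pipeline's stages compose correctly and behave
as designed on scenes satisfying its assumptions — not that any
particular accuracy carries over to a specific real dataset.

## Problem sizes and numerical conventions

The shipped end-to-end experiment uses the `color6` preset at 20 images
per class (120 images, 256×256) with 5-fold stratified CV — small enough
to rerun casually, large enough for stable fold estimates. Solver/oracle
comparisons use 30 random 12-point problems at `tol = 1e-6` so the
comparison measures solver correctness rather than stopping slack; hull
validation uses 100 random integer point sets (≤ 60 points) against an
LP convex-combination oracle (integer coordinates keep the vertex set
unambiguous). Degenerate inputs raise typed errors rather than returning
defaults: constant images (no Otsu threshold, no foreground), empty
masks, single-class training sets, sub-3-point or collinear hulls.

## Known limitations

* The segmenter targets single centered objects; scenes whose object
  dominates the border, or multi-object scenes, violate the
  background rule by construction.
* Perimeter uses crack edges, which overestimates smooth-boundary length
  by up to ~27% relative to geometric perimeter (it is exact for
  axis-aligned rectangles); comparisons should stay within one
  convention.
* The SMO stopping rule is absolute; extremely scaled kernels (e.g.
  high-degree polynomials on unstandardized data) converge slowly.
  Standardization — which the pipeline performs — avoids this.
* PCA energy selection is variance-, not discrimination-driven: a
  low-variance but discriminative direction can fall below the threshold.
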