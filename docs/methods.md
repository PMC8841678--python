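# Methods

## Graph model and local costs

A transversal slice is an 8-connected weighted bi-directed graph on
pixels. The directed link cost into pixel *v* is
`c(u,v) = w_zx·S_zx(v) + w_g·S_g(v)·len(u,v) + w_d·S_d(u,v)` with
default weights `(0.43, 0.14, 0.43)`, the classical intelligent-scissors
weighting. The three features:

- **Gradient magnitude** `S_g = 1 − G/max(G)`, Sobel 3×3 with edge
  replication, computed on raw HU (display window/level never enters).
  A constant image yields `S_g ≡ 1` by definition rather than a division
  error. The gradient term of a diagonal link is scaled by √2 so that
  cost accrues per unit geometric length and path shape is not biased
  toward diagonal moves.
- **Laplacian zero-crossing** `S_zx`: binary; a pixel costs 0 when the
  3×3 Laplacian of the Gaussian-smoothed image (σ = 1 px,
  `log_sigma_px`) changes sign against a 4-neighbour and its |L| is the
  smaller of the pair, i.e. the pixel closer to the continuous zero.
  Two guards matter in practice: the Gaussian pre-smoothing, and an
  **edge-strength gate** (`zx_gradient_gate`, default 0.10) that ignores
  sign changes at pixels whose gradient magnitude is below 10% of the
  image maximum. Without the gate, roughly three quarters of flat noisy
  background pixels register spurious crossings (measured on a 5 HU
  noise phantom) and band searches wander. A *graded*
  distance-to-crossing variant of `S_zx` was evaluated and rejected: it
  improves boundary placement slightly but creates near-tie optimal
  cycles, destroying the exact trajectory-invariance property that is
  the method's point.
- **Gradient direction** `S_d(u,v) = 2/(3π)·(acos d_u + acos d_v)`
  where `d_u`, `d_v` are dot products of the (sign-adjusted) unit link
  vector with the boundary direction — the gradient rotated 90° — at
  each endpoint; normalized to [0,1]. Where the gradient vanishes the
  boundary direction is undefined and the term takes a neutral mid
  value.

## Search

Dijkstra's algorithm over the link-cost stack (precomputed vectorized,
reused across seeds) yields a tree of optimal paths from a seed to every
reachable pixel; the boundary between two seeds is read off by parent
traversal. Ties on cumulative cost are broken by path length (fewer
steps), then by row-major pixel index. The hop tie-break is needed
wherever zero-cost plateaus exist (e.g. along a strong boundary): it
makes the shorter of two equal-cost arcs the canonical one, so results
are deterministic and platform-independent; two runs on identical input
are bit-identical.

## Band and two-pass scheme

The search is restricted to the band of pixels within
`band_half_width_px` (default 10) of the rasterized user trajectory;
distance is the Euclidean distance transform of the chain, so the band
around a loop is an annulus-like corridor. Eight seeds (default) are
sampled at equal arc length along the trajectory. Pass one chains
band-restricted optimal paths through them; pass two replaces each
segment's seed by the segment pixel with the lowest node-local cost
`w_zx·S_zx + w_g·S_g` (ties: row-major) and re-runs the chain. Exactly
two passes are run; refined seeds *replace* the originals, and a forced
pixel may override any refined seed (the interactive correction hook).
Adjacent segments occasionally refine to the same pixel; duplicates are
collapsed before pass two.

On noise-free phantoms the final contour is pixel-identical across
jittered trajectories whose bands contain the boundary (50/50 phantoms
in the validation suite). Under the default 5 HU noise, rare near-tie
single-pixel detours appear (a few phantoms per fifty differ in one
pixel between readers) without any effect on the measured diameters;
the acceptance script reports the observed invariance rate honestly.

## Between-slice propagation

Key-slice contours are resampled to `interp_n_points` (default 32)
matched control points: arc-length parameterization, counter-clockwise
orientation, starting phase anchored at polar angle 0 from the
centroid. Control points are blended linearly in z, connected into a
closed trajectory, and the two-pass search runs in its band. One search
per between-slice; key-slice contours pass through untouched.

## Measurement

Diameters are measured in mm after per-axis spacing scaling (DICOM
PixelSpacing is anisotropic in general). The longest diameter is the
maximum vertex-pair distance, computed on the convex hull (the polygon
diameter is attained at hull vertices); tied pairs resolve to the
lexicographically smallest endpoints. The short axis is the longest
chord perpendicular to the long axis — chord length versus position is
piecewise linear with breakpoints at vertex abscissas, so scanning
abscissas and midpoints is exact for simple polygons. 3D mode selects
the maximum-area slice (shoelace, mm²; ties to the lowest index) before
measuring, which is not the slice with the longest chord in general.

Detected contours are pixel chains; the max-pair diameter of a digital
chain is biased upward by half-pixel quantization spikes. The standard
measurement path therefore applies a cyclic moving-average smoothing of
the chain (`smooth_window`, default 7 vertices) before measuring; the
curvature-induced shrinkage of this window is second order (≈0.08 px on
a radius-10 circle), an order of magnitude below the bias it removes.
Residual error is dominated by the outward displacement of
zero-crossing edges on convex boundaries (≈σ²/r) plus rasterization;
across the validation phantoms (radii 9–16 px) the mean absolute
diameter error is ≈1.3%.

## Response classification

RECIST 1.1 thresholds, all configurable: PR at ≥30% decrease from
baseline, PD at ≥20% increase over the nadir that is also ≥5 mm
absolute, CR at a zero diameter sum; SD otherwise, with precedence
CR → PD → PR. Nodal lesions contribute their short axis to the sum, and
with `nodal_cr_normalization` (default on) a timepoint whose extranodal
lesions all measure 0 and whose nodes are below 10 mm short axis is CR
despite a positive sum, unless it is progression. Follow-up lesions
below 10 mm remain measured and included. Target-lesion bookkeeping
enforces ≤5 lesions and ≤2 per organ with a warning (keeping the
largest), and a lesion missing at a follow-up timepoint is an error —
sums would otherwise be incomparable.

## Agreement statistics

CV uses the sample SD (n−1) over readers divided by the mean. The
Pearson matrix summary follows the per-reader-mean convention: each
reader's mean off-diagonal correlation, then the mean and sample SD of
those per-reader values — the convention that reproduces the embedded
published five-reader summaries (0.73 ± 0.07 manual, 0.84 ± 0.03
contour tool) exactly after rounding; a pooled-pairs convention does
not. "Two-way mixed" ICC is read as ICC(3,1) single-measure consistency
`(MS_rows − MS_err)/(MS_rows + (k−1)·MS_err)`, with ICC(2,1) absolute
agreement available (`icc_variant`); both are cross-checked against
pingouin in the tests. Fleiss' kappa is reported together with the raw
percent agreement (mean fraction of concordant reader pairs) because
published summaries quote either; a single-category table makes chance
agreement 1 and returns an explicit degenerate flag rather than a
division error. Rows with any missing reader are excluded everywhere
(complete-case analysis). Group-comparison helpers (rank-sum, χ²,
t-test) are thin scipy wrappers.

## Synthetic phantoms and the simulated reader study

Phantoms are rasterized disks, ellipses, spheres, ellipsoids or
lobulated shapes (radius perturbed by a low-order Fourier series),
rendered at 60 HU on a −100 HU background, Gaussian edge blur σ = 1 px,
additive Gaussian noise σ = 5 HU, 1 mm isotropic in-plane spacing —
representative of a soft-tissue lesion on contrast-enhanced CT. Radii
9–16 px give 18–32 mm lesions, inside the 10–105 mm clinical range.
Ground truth is the analytic boundary polygon and the diameter of its
dense mm-space sampling. The generator deliberately omits beam
hardening, streaks, texture and neighbouring anatomy: passing phantom
tests demonstrates boundary-location correctness and reproducibility,
not robustness to confounding structures that touch the lesion.

The simulated study has two arms per phantom: the contouring arm feeds
jittered trajectories (smooth radial Fourier displacement, max 4 px
against a 10 px band) through the two-pass search; the manual arm draws
diameters with a Gaussian relative error of SD 0.30, a synthetic reader
model calibrated to the dispersion reported for unaided measurements.
The response-evaluation study extends this to two timepoints with a
uniformly drawn true change factor (0.45–1.45), each reader classifying
against their own baseline.

## Problem sizes and numerical choices

The validation suite uses 64–80 px images, 50-phantom invariance and
reader studies, a 25-trial randomized graph-oracle sweep (grids ≤7×7),
and the full 1-mm response lattice up to 100 mm (vectorized); the whole
suite runs in well under a minute, the acceptance script in about ten
seconds. Floating-point path costs are compared exactly where
determinism guarantees bit-equality and at 1e-9 against library oracles.
Degenerate inputs have defined behaviour throughout: constant images
(all-ones features), zero-variance ANOVA (configurable 0 or error),
single-category kappa (flagged), collinear contours (pairwise-distance
fallback for the hull).

## Known limitations

Boundary placement follows the zero-crossing/gradient-ridge definition
of an edge, which sits ≈0.2–0.4 px outside the 50%-level boundary of
small convex objects; relative errors grow accordingly below ~10 px
radius. Only closed trajectories and axial-plane contours are
supported; open trajectories, oblique reformats and 3D-oblique
diameters are out of scope, as are GPU acceleration and learned cost
functions. New-lesion and non-target progression are not classified.
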