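# Methods

This note documents the models, parameters, and design choices behind
`spineannot`, and what the synthetic phantom does and does not emulate.

## Pipeline model

The package assumes a mid-sagittal T2-weighted slice with a six-region
label map (Anterior, PosteriorA, PosteriorB, Vertebrae, IVD, Sacrum) in
a square working frame of 384 px.  Images acquired at another dimension
`dm` are resampled (cubic for intensities, nearest for labels) and the
pixel spacing rescaled as `ps' = ps * dm / 384`, preserving the field
of view.  Coordinates are row/column with y increasing downward; points
treated as vectors are (x, y) = (column, row).

### Label-map repair

Inferred label maps are repaired to the same topology required of
expert maps: one hole-free component each for Anterior, PosteriorA, and
Sacrum; hole-free PosteriorB components (any number); one hole-free
Vertebrae+IVD union forming the spine column; discs and vertebrae
alternating bottom-up starting with a disc above the sacrum.
Foreground components are 8-connected and holes are detected against
the 4-connected background (the standard dual pairing, which avoids
topological paradoxes).  A component dissolves into the modal code of
its outer 8-boundary, ties broken toward the smallest code; spine
fragments under 20 px are dissolved (strictly: 20 px survives).  Union
holes whose vertical neighbours are vertebrae above and below are
filled as IVD (the imprint of a missed disc); other holes take the
modal adjacent code.  The repair is idempotent.

### Centerline and naming

Thinning (Zhang-Suen-class, `skimage.morphology.thin`) reduces the
merged Sacrum+Vertebrae+IVD region to a unit-width centerline.
Endpoints are foreground pixels with exactly one 8-neighbour; the start
is the endpoint with maximal y (ties: maximal x), the finish minimal y
(ties: minimal x).  A* over the skeleton pixels (axial cost 1, diagonal
sqrt(2), Euclidean heuristic) returns the unique simple path; skeleton
pixels off the path — thinning branches — are discarded.  Walking the
path, runs of disc / vertebra pixels are grouped by the identity of the
connected component they thread: brief label noise that interrupts one
structure's run re-merges, while a genuinely collapsed disc whose run
is only two points still separates its two neighbouring vertebrae.
(A fixed-width gap-bridging rule was tried first and mis-merged
vertebrae across collapsed discs, which is why component identity is
the grouping key.)  If the start point is not inside the sacrum a
warning is logged but traversal proceeds.

### Height measurement

Performed on a 4x-upscaled frame after Gaussian smoothing
(sigma = 0.5 px at the original scale; the smoothing scale is a free
parameter and configurable).  Boundary point sets are disc pixels
8-adjacent to the superior vertebra (top) and inferior structure
(bottom).  The middle 30% by x-order is kept (at least 10 points
required); its mean is the centre and its principal axis the boundary
fit — orthogonal (total-least-squares) regression, which stays stable
for steep boundaries and coincides with ordinary least squares for
near-horizontal ones.  Perpendiculars are oriented into the disc by the
sign of their dot product with (disc centroid - centre).  Both
projection points are constructed symmetrically: C'_T is the
intersection of the ray from C_T with the bottom fit line and C'_B with
the top fit line.

Endpoint refinement searches from A = M - u to B = M + k*u (u the unit
perpendicular), k = 8 upscaled px (~1.5 mm at ps' = 0.7292) by default.
Two robustness measures apply:

* k is capped per disc at floor(||M_T - M_B|| / 2) - 1 so the search
  never crosses the disc midline; for a collapsed disc (~12-16
  upscaled px tall) an uncapped range tunnels through to the opposite
  interface's stronger edge and collapses the segment.
* each candidate's directed-gradient score is averaged over a 5-sample
  probe transverse to u (offsets 0, +/-4, +/-8 upscaled px along the
  fitted boundary direction).  A real interface is transversely
  coherent while nucleus texture is not, so the probe roughly halves
  the localization variance without moving the edge.  The per-pixel
  argmax and its tie rule (closest to M) are unchanged.

Gradient direction uses correlation with unmirrored 3x3 Prewitt
kernels so g_x ~ dI/dx, with angles wrapped to (-180, 180].  Scores
tie within 1e-9 toward the pixel nearest M; a zero field therefore
returns M itself.

### Brightness normalization and the SSCC feature

Images are offset so the vertebrae-region mean matches a cohort
reference (default 69; `estimate_reference_mean` recomputes it for a
new cohort as the mean of per-study vertebrae means), clamped to
[0, 255].  Because the offset is anchored on the vertebrae, a global
exposure change cancels exactly as long as no pixel saturates.

Nucleus detection erodes the disc mask to <= 80% area, then lowers a
threshold from the region maximum in steps of 5 until the bright pixels
cover >= 30% of the shrunk region *and* the largest closed candidate
component (closing disk radius 4 upscaled px ~ 1 original px) covers
>= 20%; the winner eroded to 90% area is the inner nucleus.  If the
loop exhausts — a uniformly dark, severely degenerated disc — the
eroded disc stands in, flagged as a fallback.

The self-similar color correlogram quantizes intensities as
floor(min(gl, 150)/5), clamped to bin 29 so exactly N = 30 bins exist
(an unclamped boundary value would open a 31st, nearly empty bin).
Ordered in-mask pixel pairs at chessboard (L-infinity) distance exactly
d = 4 — the upscale factor — are tabulated into C_ij and each row
normalized into a conditional probability (all-zero rows stay zero).
The emitted feature is the band |i - j| <= w in row-major order,
length N(2w+1) - w(w+1); w defaults to 2 (length 144).  Ordered
counting makes rows stochastic; the distance metric and pair ordering
follow the correlogram literature's convention.

### Grading

A measured height strictly below 3.0 mm forces grade 5 before any
classifier runs.  Grades 1-4 come from one of six classifier families
(k-NN, decision tree, SVM with error-correcting output codes, linear
discriminant, feedforward neural network, Random Forest ensemble); the
ensemble default uses 15 trees, minimum leaf size 1, at most 114 splits
(115 leaf nodes), and 20 variables sampled per split.  The "twoing"
split criterion of the original protocol has no scikit-learn
counterpart; Gini is substituted, with a `criterion` hook for
alternatives.  Training samples are weighted tw_c = median(f)/f_c so
the median-frequency grade has weight 1; families whose scikit-learn
`fit` lacks `sample_weight` (k-NN, discriminant, neural network) ignore
the weights.  Grade-5 ground-truth samples are excluded from training —
the rule owns that grade.  Model selection reports stratified, seeded
10-fold cross-validation accuracy; evaluation reports a 5x5 confusion
matrix, per-class accuracies, and their frequency-weighted mean, which
reduces to plain accuracy when the weights are the empirical counts.

## The phantom: what it emulates, and what it does not

The generator renders the statistical structure the pipeline relies
on: a bottom-up Sacrum / disc / vertebra / ... stack satisfying the
labelling requirements by construction; a brighter nucleus ellipse
filling most of each disc's height whose mean intensity falls and
texture spread rises with grade (means 160/130/95/60, s.d. 4/8/14/18
for grades 1-4); collapsed grade-5 discs; thin dark endplate bands
(intensity ~26, ~2 px) on the bone side of every disc interface,
mirroring the hypointense cortical endplates of real T2 anatomy — they
also give the directed-gradient refinement a correctly signed interface
edge even when the disc is darker than the vertebral body.  Vertebra
pixels are recentred after rendering so the labelled vertebrae mean is
exactly the configured 69, anchoring the brightness normalization.
Texture is spatially correlated (unit-variance white noise smoothed
with sigma = 2 px, tails clipped at 2.5 s.d.) because real T2 texture
is smooth at the millimetre scale; i.i.d. texture of the same amplitude
would bury the interface gradients.

Two deliberate deviations from a naive "dial every knob independently"
design, both forced by geometry:

* Grade-5 discs render with compressed texture (s.d. 6, not a
  continuation of the monotone 4-18 ramp): at s.d. 20 the local mean of
  a 3-4 px sliver swings +/-40 grey levels, flipping the interface
  gradient's sign.  Physically a collapsed disc has lost its nucleus
  and shows uniformly dark signal; the monotone homogeneity story
  applies to grades 1-4, the classifier's domain (grade 5 never reaches
  the classifier).
* Grade-5 heights are drawn in [1.7, 2.15] mm rather than merely
  "below 3.0": integer-row rendering quantizes a height upward by up to
  one 0.73 mm row and measurement adds up to ~0.3 mm, so a disc built
  at 2.8 mm could measure above the threshold.  The margin makes the
  height rule decidable at the phantom's raster resolution.

Geometry: each disc is a parallelogram between two parallel interface
lines with its own tilt (vertebrae become trapezoids), so the rendered
perpendicular height is the vertical extent times cos(tilt); curvature
is an integer horizontal row-shift of the whole frame (sinusoidal,
amplitude 5 px, period 300 px by default), whose second-order shear
effect on perpendicular height (<0.5%) is absorbed by the rasterization
error budget.  Truth heights are computed from the *rasterized*
geometry (mean disc-row count over the middle 30% of spine columns,
times cos(tilt) times ps'), because that is the geometry any
measurement can see; re-rendering the same configuration at a different
tilt therefore legitimately changes the truth by up to half a row
(~0.36 mm), which is why rotation-consistency checks compare
measured/truth ratios rather than raw heights.

Batches group discs (the unit the grade distribution is specified in)
into studies of three, with per-study exposure offsets drawn from
N(0, 8) clipped to +/-20 grey levels and additive Gaussian noise
(s.d. 2) on top.  The "imbalanced" preset reproduces a clinical
severity mix of 3.9/64.9/10.8/19.0/1.4% for grades 1-5.

The phantom does **not** emulate: anatomically realistic bone/tissue
shapes, partial-volume or bias-field effects, end-plate trauma and
other vertebral defects (a known source of height over-estimation in
clinical use), transitional anatomy (lumbarization/sacralization), or
scanner-specific noise spectra.  Tests passing on phantoms therefore
demonstrate the pipeline's geometric and statistical machinery, not
clinical-grade accuracy; absolute clinical performance requires expert
ground truth on real studies.

## Numerical choices and degenerate inputs

* Resampling: cubic with clipping to [0, 255] for intensities; nearest
  for labels (never invents codes).  DICOM stored values map to 8-bit
  by per-image min-max scaling (the windowing function is otherwise
  unspecified upstream; it is configurable by preconverting to PNG).
* Non-square images or anisotropic spacing are rejected, not coerced.
* BFScore boundary tolerance: 0.75% of the image diagonal, rounded up.
* Endpoint/tie conventions: start endpoint ties break toward larger x,
  finish toward smaller x; merge-target ties toward the smaller region
  code; probability-to-class ties toward the lower grade.
* Degenerate geometry raises typed errors: empty boundary sets, <10
  boundary points, rays parallel to the opposite fit line, search
  segments fully outside the image, maps without a Sacrum, skeletons
  with fewer than two endpoints, paths entirely inside the Sacrum.
* Problem sizes in the test suite (50-phantom naming runs, 10-study
  height sweeps, a 240-disc grading batch with a permuted-label
  baseline) were chosen as the smallest batches at which the binomial
  noise of the checked rates is comfortably inside the asserted
  margins.

## Known limitations

* The height measurement assumes the nucleus (or disc) edge is the
  strongest directed gradient within k of the first estimate; end-plate
  defects or severe segmentation errors violate this and produce
  outliers, as they do in clinical deployments of this geometry.
* The 3.0 mm grade-5 threshold is a cohort-derived constant; normal
  disc height varies across populations, so it is a config field, not
  a universal truth.
* The classifier families are implemented and compared on synthetic
  data only; their ranking on clinical data is out of scope here.
* `run_experiment` trains and predicts on the same phantom studies
  (features from ground-truth label maps); it demonstrates the
  protocol, not generalization across segmentation backends.
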