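# Methods

This note records the model, the numerical conventions, the synthetic data
design, and the open design choices made in `cortiscan`, in the order the
measurement chain runs.

## Enhancement

The ROI is an 8-bit grayscale crop (canonically 300 × 300 px at 300 dpi,
pixel spacing 25.4/300 ≈ 0.0847 mm) over the inferior mandibular cortex.
Coordinates are 0-based, row-major, top-left origin; ROI boxes are
inclusive-start, extent-based, and come from a config file rather than manual
cropping, for reproducibility.

* **Histogram equalization** is the plain cumulative-histogram remap
  `v → round(255·CDF(v))`; it is monotone, hence rank-preserving, and
  idempotent up to one quantization level.
* **Variance threshold** maximizes the between-class variance over all 256
  integer levels (exhaustive sweep — exact and cheap for 8-bit data). Ties go
  to the smallest level; the object mask is `intensity > t` (strict, so a
  constant image has no object and is rejected as degenerate).
* **High-pass** subtracts a `k × k` moving average (edge replication). The
  window must exceed the cortical band's vertical extent for the band
  interior to stay positive after subtraction; at 300 dpi the cortex is
  roughly 35–60 px thick, so the default is `k = 75`. The filtered grid is
  signed and unclipped, is exactly zero for constant input, and is invariant
  to adding a constant.
* **Mean binarization** keeps pixels strictly above the global mean of the
  high-pass grid. In the pipeline the result is intersected with the
  variance-threshold object mask: pixels already classified as background
  cannot re-enter as object. Without this, a cortex crossing the full ROI
  width over-weights bright edge columns in the replicated moving average,
  the high-pass mean dips just below zero, and the exactly-zero background
  (which is then "above the mean") floods the foreground.

## Margin extraction

* **Distance transform.** The eight-neighbourhood distance function assigns
  each object pixel its chessboard distance to the nearest background pixel,
  with the image border counted as background so every object is finite.
* **Medial axis.** Among all left-to-right paths that advance one column per
  step with row moves in {−1, 0, +1} and visit only positive cells, dynamic
  programming returns the path with the maximum sum of distance values — a
  global optimum, not a greedy ridge-follow (the two are not equivalent).
  Ties prefer the smaller |row step|, then the smaller row, so a uniform band
  yields the straight topmost path and results are reproducible across
  implementations. Objects whose positive columns cannot be joined by such a
  path are rejected as discontinuous.
* **Disc envelope.** The margins are the per-column extremes of discs centred
  on the trace. Two conventions matter and both were chosen for metric
  consistency rather than convenience:
  * *Shape*: chessboard balls (axis-aligned squares), because the distance
    values are chessboard distances; with Euclidean discs a band tilted by θ
    reconstructs too thin by the factor 1/(cos θ + sin θ) (≈ 0.73 at 30°).
    Euclidean discs remain available via `shape="euclidean"`.
  * *Radius*: `v − ½`. The distance value v counts steps to the nearest
    background pixel *centre*; the continuous object margin lies half a pixel
    short of that centre, so `v − ½` is the distance to the margin itself.
    `radius="value"` and `radius="half"` exist for sensitivity checks.
  Margins are kept sub-pixel (float): rounding them to integer rows
  reintroduces ±1 parity artifacts that the downstream quadratic fit cannot
  remove. Margins are reported only over the trace's column span, clipped to
  the grid, and always bracket the trace.
* **End trimming (pipeline only).** The cortex continues beyond the cropped
  ROI, so the distance transform tapers artificially near the lateral image
  borders. The pipeline drops `max(v on the trace)` columns from each end of
  the margin span before fitting — a crop-artifact correction, skipped when
  fewer than 10 columns would remain.

## Width measurement

A second-order polynomial is least-squares fitted to the upper margin
(≥ 3 distinct columns required). At each column the measurement ray starts at
the upper-margin point, runs perpendicular to the fitted tangent
(slope `a₁ + 2a₂c`), and ends at its first crossing of the linearly
interpolated lower margin. Width is reported in pixels and in millimetres.
"Width" is only meaningful normal to the band axis — a literal measurement
*along* the tangent would measure length, not thickness. Columns whose ray
leaves the span without crossing are skipped and recorded; if more than 20%
of columns are skipped the measurement fails. The feature vector is the mean
and the population (divide-by-n) variance of the width profile in mm,
averaged over the right and left sides; if one side is unusable the other is
used alone with a warning.

Accuracy of the full chain on rendered ribbons of known normal width
(6–20 px, 0–30° tilt): within ±1 px noiseless and ±1.5 px with noise and
curvature. The worst case (−1 px) occurs on horizontal bands spanning an even
number of pixel rows, where the single-row trace sits on the upper of the two
central ridge rows.

## Classification

The SVM is the standard soft-margin dual: maximize
`Σαᵢ − ½ ΣΣ αᵢαⱼyᵢyⱼK(xᵢ,xⱼ)` subject to `Σαᵢyᵢ = 0`, `0 ≤ αᵢ ≤ C`, with the
RBF kernel in the `exp(−‖·‖²/(2γ²))` parameterization (γ = 1, C = 1
defaults; note this is *not* the `exp(−γ‖·‖²)` convention — the equivalent
there is `γ' = 1/(2γ²) = 0.5`). Because mean (mm) and variance (mm²) live on
different scales, features are z-scored on the training set and the transform
is stored in the model. The box-constrained QP is solved with SLSQP
(`scipy.optimize`), analytic gradient, zero start, `ftol 1e-12`; the test
suite checks the dual objective and decision scores against an independent
reference solver to 1e-4. The bias is the mean KKT estimate over margin
support vectors (`0 < αᵢ < C`, numerical floor `1e-8·C`), falling back to the
midpoint of the KKT-feasible interval when every coefficient is at a bound.
`sign(0)` is taken as +1 (borderline cases screen positive). Labels {0, 1}
are accepted and mapped 1 → +1 (low BMD), 0 → −1.

**Operating point.** Candidate cutoffs are the midpoints between consecutive
distinct scores plus a sentinel below the minimum (so a sensitivity-1.0 point
always exists); the largest cutoff whose sensitivity reaches the target
(default 0.90) is returned, maximizing specificity at the required
sensitivity. Two protocols are offered:

* `evaluate_at_sensitivity` pins the cutoff on the scores of the cohort being
  evaluated — the screening-literature "specificity at ~90% sensitivity"
  summary. Its sensitivity is at-target *by construction* and its specificity
  is mildly optimistic; it describes the ROC, not prospective performance.
* `set_operating_point` selects the cutoff on training scores for prospective
  use. In-sample scores are optimistically separated, so the realized
  sensitivity of this cutoff on new data is systematically below target
  (about 0.81 ± 0.10 under the default synthetic conditions); a user who
  needs a calibrated prospective cutoff should select it on held-out scores.

Screening metrics use the exact 2 × 2 formulas; proportion CIs are the normal
approximation `p ± 1.96·√(p(1−p)/m)` clipped to [0, 1] with m the relevant
denominator; the LR+ interval uses the log method; LR+ at specificity 1 is
flagged infinite rather than raised.

## Synthetic data

`render_ribbon` draws the set of pixels whose centre lies within
`true_width_px / 2` (normal distance, computed against a densely sampled,
frame-extended polyline of the quadratic axis) of the medial axis, at
`band_intensity` (default 180) over `background_intensity` (default 70), plus
seeded Gaussian noise (default sd 5; contrast must exceed 3·sd) and optional
small bright clutter blobs kept clear of the band (they exercise the
largest-component stage, not a physiological trabecular model). Exact
sub-pixel truth margins and widths are returned alongside. A band with an
integer-row axis and even width rasterizes to W+1 pixel rows (inclusive
ends); geometry tests therefore place axes on half-integer rows, and cohort
widths are continuous draws where no such degeneracy exists.

`generate_cohort` / `generate_feature_cohort` draw per-subject true widths
from class-conditional normals truncated at 0.5 mm — low BMD 3.0 mm, normal
4.2 mm, sd 0.4 mm, the published MCW separation at the screening threshold —
and render left/right ribbons with independent noise and gentle random
curvature (|slope| ≤ 0.15, |a₂| ≤ 5·10⁻⁴). The feature-level generator also
draws the width-variance feature from Gamma(shape 4) with class means
0.12 mm² (low) vs 0.04 mm² (normal), reflecting the more irregular width
profile of an eroded cortex. All generators are pure functions of their spec,
seed included.

What passing tests on this data do and do not show: the generator emulates
band geometry, contrast, noise and class structure, but not overlapping
anatomy (hyoid shadow, teeth), film-grain statistics, exposure variation, or
genuinely porous, broken cortical margins. Results on it validate the
algorithmic chain, not clinical performance.

## Problem sizes

The default study is 60 training / 40 test subjects (balanced classes) at
feature level, a 16-subject image-level cohort, and 12 ribbon geometries for
width recovery; oracle-equivalence checks run on hundreds of random masks up
to 25 × 25 px and exhaustive path enumerations up to 6 × 8. These sizes keep
the whole suite and the acceptance script in well under a minute each while
leaving every statistical check comfortably powered.

## Known limitations

* ROI placement is an input; the mental foramen is not localized.
* The medial-axis tracer assumes a single, roughly horizontal, unbranched
  band; vertical or branched objects are out of scope.
* The chessboard metric under-measures oblique distances; the square-disc
  envelope compensates for straight-to-moderately-curved bands but residual
  ±1 px bias remains at strong tilt.
* The ~90%-sensitivity cutoff chosen on training scores is optimistic
  in-sample (see Operating point above).
* CIs are normal approximations; with small cohorts (the default test set has
  20 positives) they are crude near 0 and 1.
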