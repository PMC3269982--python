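# cortiscan

Continuous measurement of the mandibular cortical width (MCW) on dental
panoramic-radiograph regions, and RBF-kernel support-vector screening of
postmenopausal women for low bone mineral density (BMD).

## The problem

Osteoporosis develops silently; dual-energy X-ray absorptiometry (DXA) is the
reference test but is not available for broad screening. The inferior cortex
of the mandible, visible below the mental foramen on routine dental panoramic
radiographs, thins and becomes porous as skeletal BMD falls, so its width is
a practical screening signal. Measuring it at a single point is fragile
(hyoid-bone shadows, local porosity); `cortiscan` instead measures the width
*continuously* at every column of a cropped region of interest (ROI) and
reduces the profile to two per-subject features — the mean and the variance
of the width — that feed a soft-margin support vector machine separating
low-BMD (DXA T-score ≤ −1.0, label +1) from normal (label −1) subjects.

## The measurement chain

Per 300 × 300 px ROI (8-bit grayscale, 300 dpi ⇒ 25.4/300 mm per pixel):

1. **Enhancement** — histogram equalization; between-class-variance
   (Otsu-style, exhaustive 256-level sweep) threshold to separate object from
   background; mask multiplication to delete the background; subtraction of a
   large moving-average low-pass (high-pass filtering); binarization at the
   global mean of the high-pass image.
2. **Margin extraction** — largest 8-connected component; eight-neighbourhood
   (chessboard) distance transform (ENDF) with the image border as
   background; left-to-right dynamic-programming trace of the maximum-sum
   ridge (row steps in {−1, 0, +1}) giving the medial axis; reconstruction of
   the upper/lower cortical margins as the sub-pixel envelope of chessboard
   discs of radius `v − ½` centred on the trace, where `v` is the local
   distance value.
3. **Width measurement** — ordinary least-squares fit of a second-order
   polynomial `row = a₀ + a₁·col + a₂·col²` to the upper margin; at each
   column the width is measured along the normal to the local tangent, from
   the upper margin to the linearly interpolated lower margin; widths convert
   to millimetres by the pixel spacing.
4. **Classification** — per subject, features `x = (mean width, width
   variance)` averaged over the right and left cortices; an RBF-kernel SVM

   ```
   f(x) = sign( Σᵢ αᵢ yᵢ K(x, xᵢ) + b ),   K(xᵢ, xⱼ) = exp(−‖xᵢ − xⱼ‖² / (2γ²))
   ```

   with dual coefficients maximizing `Σαᵢ − ½ ΣΣ αᵢαⱼyᵢyⱼK(xᵢ,xⱼ)` subject to
   `Σαᵢyᵢ = 0`, `0 ≤ αᵢ ≤ C` (γ = 1, C = 1 by default; features are z-scored
   before the kernel). The screening operating point is the decision-score
   cutoff at ≈90% sensitivity, and performance is reported as sensitivity,
   specificity, PPV, NPV, accuracy and LR+ with 95% confidence intervals.

No public radiograph/DXA dataset exists for this problem, so the package
ships a first-class synthetic generator (`cortiscan.synth`): seeded cortical
ribbons of known sub-pixel geometry over noisy backgrounds, and seeded
feature cohorts with class-conditional width distributions (low BMD
3.0 ± 0.4 mm, normal 4.2 ± 0.4 mm by default).

## Worked example

```python
from cortiscan import CohortSpec, CorticalWidthSVM, generate_feature_cohort

Xtr, ytr = generate_feature_cohort(CohortSpec(n_low=30, n_normal=30, seed=11))
Xte, yte = generate_feature_cohort(CohortSpec(n_low=20, n_normal=20, seed=12))

results = CorticalWidthSVM(Xtr, ytr, gamma=1.0, C=1.0).fit()
print(results.summary())
metrics, op = results.evaluate_at_sensitivity(Xte, yte, 0.90)
print(metrics)
```

prints

```
RBF-SVM low-BMD screening model
===============================================
n training samples                60
  low BMD (+1) / normal (-1)  30 /  30
gamma (2*gamma^2 kernel)       1.000
C (box constraint)             1.000
support vectors                   17
bias b                        0.2449
dual objective                7.6676
solver iterations                 27
converged                       True

Statistic       Value   95% CI
Sensitivity     0.900   (0.769, 1.000)
Specificity     1.000   (1.000, 1.000)
PPV             1.000   (1.000, 1.000)
NPV             0.909   (0.789, 1.000)
Accuracy        0.950   (0.882, 1.000)
LR+               inf   (-, -)
```

Of the 60 training subjects 17 become support vectors; on the held-out 40
subjects the cutoff pinned at 90% sensitivity classifies every normal subject
correctly (specificity 1.0, so LR+ is flagged infinite rather than raised).

The same workflow is scriptable from a shell:

```sh
cortiscan synth --n-low 30 --n-normal 30 --seed 1 --out cohort/
cortiscan measure --right cohort/S000_right.png --left cohort/S000_left.png \
    --subject-id S000 --out features.csv
cortiscan train --features train.csv --gamma 1.0 --cost 1.0 --model model.json
cortiscan test --model model.json --features test.csv --out metrics.json
cortiscan predict --model model.json --right r.png --left l.png
```

`cortiscan measure --audit dir/` writes every intermediate stage image
(equalized ROI, Otsu mask, high-pass, object, distance map) for visual
inspection.

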