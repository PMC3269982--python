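"""Synthetic cortical-ribbon images and feature cohorts with known truth.

No public radiograph/DXA dataset accompanies the screening method, so every
pipeline stage is exercised on rendered stand-ins: an elongated, gently
curved bright band of known constant normal width over a darker, noisy
background (optionally with small bright clutter blobs emulating trabecular
structure), in left/right pairs with class-conditional width distributions
(low-BMD cortices thinner and more variable than normal ones).

All generators are pure functions of their spec, seed included.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from cortiscan.errors import ParameterError
from cortiscan.width import DEFAULT_PIXEL_SPACING_MM


@dataclass(frozen=True)
class RibbonSpec:
    """One rendered cortical band.

    The band is the set of pixels within ``true_width_px / 2`` (normal
    distance) of the quadratic medial axis row(col) = a0 + a1*col + a2*col^2.
    ``texture`` > 0 adds small bright clutter blobs below the band.
    """

    image_size: tuple[int, int] = (300, 300)
    axis_poly: tuple[float, float, float] = (150.0, 0.0, 0.0)
    true_width_px: float = 40.0
    band_intensity: float = 180.0
    background_intensity: float = 70.0
    noise_sd: float = 5.0
    texture: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.true_width_px <= 0:
            raise ParameterError("true_width_px must be positive")
        if self.band_intensity - self.background_intensity < 3.0 * self.noise_sd:
            raise ParameterError(
                "band must exceed background by >= 3 * noise_sd for detectability")


@dataclass(frozen=True)
class RibbonTruth:
    """Exact geometry of a rendered ribbon (sub-pixel, per column)."""

    columns: np.ndarray
    axis_rows: np.ndarray
    upper: np.ndarray          # axis - (w/2) * sqrt(1 + slope^2)
    lower: np.ndarray
    width_px: float

    def normal_width(self) -> np.ndarray:
        """Width recomputed geometrically from the stored margins."""
        slope = np.gradient(self.axis_rows, self.columns)
        return (self.lower - self.upper) / np.sqrt(1.0 + slope ** 2)


def _axis_rows(spec: RibbonSpec, cols: np.ndarray) -> np.ndarray:
    a0, a1, a2 = spec.axis_poly
    return a0 + a1 * cols + a2 * cols ** 2


def render_ribbon(spec: RibbonSpec) -> tuple[np.ndarray, RibbonTruth]:
    """Render the 8-bit image and return it with its exact truth geometry."""
    n_rows, n_cols = spec.image_size
    cols = np.arange(n_cols, dtype=float)
    axis = _axis_rows(spec, cols)
    a0, a1, a2 = spec.axis_poly
    slope = a1 + 2.0 * a2 * cols
    half = spec.true_width_px / 2.0
    norm = np.sqrt(1.0 + slope ** 2)
    upper = axis - half * norm
    lower = axis + half * norm
    outside = (upper < 0) | (lower > n_rows - 1)
    if outside.mean() > 0.20:
        raise ParameterError(
            f"band leaves the frame on {outside.mean():.0%} of columns (> 20%)")

    # normal distance from every pixel to the axis curve, via a dense
    # polyline sampling extended past the frame so border columns are fair
    ext = half + 2.0
    cs = np.arange(-ext, n_cols + ext, 0.25)
    samples = np.column_stack([_axis_rows(spec, cs), cs])
    tree = cKDTree(samples)
    rr, cc = np.mgrid[0:n_rows, 0:n_cols]
    pix = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    dist = tree.query(pix, workers=-1)[0].reshape(n_rows, n_cols)
    band = dist <= half

    rng = np.random.default_rng(spec.seed)
    img = np.full((n_rows, n_cols), spec.background_intensity, dtype=float)
    img[band] = spec.band_intensity
    if spec.texture > 0:
        for _ in range(rng.poisson(6)):
            br = rng.uniform(2.0, 5.0)
            r0 = rng.uniform(0, n_rows)
            c0 = rng.uniform(0, n_cols)
            blob = (rr - r0) ** 2 + (cc - c0) ** 2 <= br ** 2
            # keep clutter clear of the band so it stays a separate component
            if dist[blob].min() > half + 12.0:
                img[blob] = spec.background_intensity + spec.texture
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    truth = RibbonTruth(columns=cols, axis_rows=axis, upper=upper, lower=lower,
                        width_px=float(spec.true_width_px))
    return img, truth


@dataclass(frozen=True)
class CohortSpec:
    """Class-conditional truth for a synthetic screening cohort.

    Width means follow published mandibular-cortical-width separations at the
    screening threshold (low BMD ~3.0 mm vs normal ~4.2 mm, sd 0.4 mm); the
    width-variance truth gives low-BMD cortices a more irregular width
    profile (Gamma-distributed, mean 0.12 vs 0.04 mm^2).
    """

    n_low: int = 30
    n_normal: int = 30
    width_mean_low_mm: float = 3.0
    width_mean_normal_mm: float = 4.2
    width_sd_mm: float = 0.4
    var_mean_low: float = 0.12
    var_mean_normal: float = 0.04
    pixel_spacing_mm: float = DEFAULT_PIXEL_SPACING_MM
    image_size: tuple[int, int] = (300, 300)
    noise_sd: float = 5.0
    texture: float = 60.0
    seed: int = 0

    def __post_init__(self):
        if self.n_low <= 0 or self.n_normal <= 0:
            raise ParameterError("class sizes must be positive")
        if self.pixel_spacing_mm <= 0:
            raise ParameterError("pixel spacing must be positive")
        if self.width_mean_low_mm == self.width_mean_normal_mm:
            raise ParameterError("class width means must be distinct")


@dataclass(frozen=True)
class SubjectImages:
    subject_id: str
    right: np.ndarray
    left: np.ndarray
    label: int
    true_width_mm: float
    truth_right: RibbonTruth = field(repr=False, default=None)
    truth_left: RibbonTruth = field(repr=False, default=None)


def _truncated_normal(rng, mean, sd, lo=0.5):
    """Normal draw resampled until above ``lo`` (truncation at 0.5 mm)."""
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if v > lo:
            return float(v)
    raise ParameterError("truncated normal failed: mean too far below bound")


def _subject_labels(spec: CohortSpec) -> list[int]:
    return [1] * spec.n_low + [-1] * spec.n_normal


def generate_cohort(spec: CohortSpec) -> list[SubjectImages]:
    """Render left/right ribbon images per subject with class-dependent widths."""
    rng = np.random.default_rng(spec.seed)
    n_rows, n_cols = spec.image_size
    subjects = []
    for i, label in enumerate(_subject_labels(spec)):
        mean_mm = spec.width_mean_low_mm if label == 1 else spec.width_mean_normal_mm
        width_mm = _truncated_normal(rng, mean_mm, spec.width_sd_mm)
        width_px = width_mm / spec.pixel_spacing_mm
        sides = {}
        truths = {}
        for side in ("right", "left"):
            cc = n_cols / 2.0
            r0 = n_rows / 2.0 + rng.uniform(-10, 10)
            s1 = rng.uniform(-0.15, 0.15)
            s2 = rng.uniform(-5e-4, 5e-4)
            # convert centred quadratic r0 + s1*(c-cc) + s2*(c-cc)^2 to a0,a1,a2
            a0 = r0 - s1 * cc + s2 * cc * cc
            a1 = s1 - 2.0 * s2 * cc
            a2 = s2
            rspec = RibbonSpec(image_size=spec.image_size,
                               axis_poly=(a0, a1, a2),
                               true_width_px=width_px,
                               noise_sd=spec.noise_sd,
                               texture=spec.texture,
                               seed=int(rng.integers(0, 2**31 - 1)))
            sides[side], truths[side] = render_ribbon(rspec)
        subjects.append(SubjectImages(subject_id=f"S{i:03d}",
                                      right=sides["right"], left=sides["left"],
                                      label=label, true_width_mm=width_mm,
                                      truth_right=truths["right"],
                                      truth_left=truths["left"]))
    return subjects


def generate_feature_cohort(spec: CohortSpec) -> tuple[np.ndarray, np.ndarray]:
    """Draw (mean width, width variance) features directly — fast SVM fixtures.

    Bypasses the imaging chain: per subject the mean width is a truncated
    normal draw from the class distribution and the width variance a Gamma
    draw (shape 4) around the class variance mean. Returns (features, labels)
    with labels in {-1, +1}.
    """
    rng = np.random.default_rng(spec.seed)
    labels = np.array(_subject_labels(spec), dtype=np.int64)
    feats = np.empty((len(labels), 2), dtype=float)
    shape = 4.0
    for i, label in enumerate(labels):
        mean_mm = spec.width_mean_low_mm if label == 1 else spec.width_mean_normal_mm
        var_mm2 = spec.var_mean_low if label == 1 else spec.var_mean_normal
        feats[i, 0] = _truncated_normal(rng, mean_mm, spec.width_sd_mm)
        feats[i, 1] = rng.gamma(shape, var_mm2 / shape)
    return feats, labels
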