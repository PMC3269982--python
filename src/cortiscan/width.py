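"""Continuous cortical width measurement and feature reduction.

A second-order polynomial is least-squares fitted to the upper cortical
margin; at every column the width is the distance from the upper margin point
to the lower margin measured along the normal to the local tangent of the
fitted curve. Widths convert from pixels to millimetres via the scanner
pixel spacing (default 25.4/300 mm, i.e. a 300-dpi scan). The per-subject
feature vector is the (mean, population variance) of the width profile,
averaged over the right and left cortices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from cortiscan.errors import (
    InsufficientSupportError,
    MeasurementError,
    ParameterError,
)
from cortiscan.margins import CorticalMargins

DEFAULT_PIXEL_SPACING_MM = 25.4 / 300


@dataclass(frozen=True)
class PolyCoeffs:
    """row(col) = a0 + a1*col + a2*col**2 in image coordinates."""

    a0: float
    a1: float
    a2: float

    def __call__(self, col):
        return self.a0 + self.a1 * np.asarray(col, dtype=float) \
            + self.a2 * np.asarray(col, dtype=float) ** 2

    def slope(self, col):
        """d(row)/d(col) of the fitted curve."""
        return self.a1 + 2.0 * self.a2 * np.asarray(col, dtype=float)


@dataclass(frozen=True)
class WidthProfile:
    """Per-column cortical widths for one side of the mandible."""

    columns: np.ndarray
    widths_px: np.ndarray
    pixel_spacing_mm: float = DEFAULT_PIXEL_SPACING_MM
    side: str = "right"
    skipped_columns: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    @property
    def widths_mm(self) -> np.ndarray:
        return self.widths_px * self.pixel_spacing_mm

    def __len__(self) -> int:
        return len(self.columns)


@dataclass(frozen=True)
class FeatureVector:
    """SVM input: mean and population variance of the width profile (mm, mm^2)."""

    mean_width_mm: float
    var_width_mm2: float

    def as_array(self) -> np.ndarray:
        return np.array([self.mean_width_mm, self.var_width_mm2], dtype=float)


def fit_upper_polynomial(margins: CorticalMargins) -> PolyCoeffs:
    """Ordinary least-squares quadratic fit of the upper margin rows."""
    cols = margins.columns.astype(float)
    if len(np.unique(cols)) < 3:
        raise InsufficientSupportError(
            f"quadratic fit needs >= 3 distinct columns, span has {len(cols)}")
    coeffs = np.polynomial.polynomial.polyfit(cols, margins.upper.astype(float), 2)
    return PolyCoeffs(a0=float(coeffs[0]), a1=float(coeffs[1]), a2=float(coeffs[2]))


def measure_widths(margins: CorticalMargins, poly: PolyCoeffs,
                   spacing_mm: float = DEFAULT_PIXEL_SPACING_MM,
                   side: str = "right",
                   max_skip_fraction: float = 0.20) -> WidthProfile:
    """Measure the cortical width at every column of the margin span.

    At column c the measurement ray starts at the upper margin point
    (upper[c], c), runs perpendicular to the tangent of the fitted polynomial
    (slope a1 + 2*a2*c), and ends where it first crosses the linearly
    interpolated lower margin polyline. Columns whose ray leaves the span
    without crossing are skipped; if more than ``max_skip_fraction`` of
    columns are skipped, a :class:`MeasurementError` is raised.
    """
    if spacing_mm <= 0:
        raise ParameterError("pixel spacing must be positive")
    cols = margins.columns.astype(float)
    upper = margins.upper.astype(float)
    lower = margins.lower.astype(float)
    n = len(cols)
    if n < 2:
        raise InsufficientSupportError("margin span must cover >= 2 columns")

    seg_x0 = cols[:-1]
    seg_y0 = lower[:-1]
    seg_s = lower[1:] - lower[:-1]  # slope of each lower-margin segment

    kept_cols, widths, skipped = [], [], []
    eps = 1e-9
    for i, c in enumerate(cols):
        u = upper[i]
        m = poly.slope(c)
        L = np.hypot(1.0, m)
        dx, dy = -m / L, 1.0 / L  # unit normal, oriented toward larger rows
        # intersect the ray (c + t*dx, u + t*dy) with each lower segment
        denom = dy - seg_s * dx
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (seg_y0 + (c - seg_x0) * seg_s - u) / denom
        x = c + t * dx
        ok = (np.abs(denom) > eps) & (t > eps) \
            & (x >= seg_x0 - eps) & (x <= seg_x0 + 1.0 + eps)
        if ok.any():
            kept_cols.append(int(c))
            widths.append(float(t[ok].min()))
        else:
            skipped.append(int(c))
    if len(skipped) > max_skip_fraction * n:
        raise MeasurementError(
            f"{len(skipped)}/{n} columns failed to intersect the lower margin")
    return WidthProfile(columns=np.asarray(kept_cols, dtype=int),
                        widths_px=np.asarray(widths, dtype=float),
                        pixel_spacing_mm=float(spacing_mm), side=side,
                        skipped_columns=np.asarray(skipped, dtype=int))


def _profile_stats(profile: WidthProfile) -> tuple[float, float]:
    w = profile.widths_mm
    return float(np.mean(w)), float(np.var(w))  # population variance


def extract_features(right: WidthProfile | None,
                     left: WidthProfile | None) -> FeatureVector:
    """Average the per-side (mean, population variance) of widths in mm.

    If one side is missing or empty, the other side is used alone with a
    warning; two empty profiles are an error.
    """
    sides = []
    for p in (right, left):
        if p is not None and len(p) > 0:
            sides.append(_profile_stats(p))
    if not sides:
        raise ParameterError("both width profiles are empty")
    if len(sides) == 1:
        warnings.warn("only one side available; features use a single cortex",
                      stacklevel=2)
    means = [s[0] for s in sides]
    variances = [s[1] for s in sides]
    return FeatureVector(mean_width_mm=float(np.mean(means)),
                         var_width_mm2=float(np.mean(variances)))
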