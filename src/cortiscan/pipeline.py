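"""End-to-end per-subject orchestration of the measurement chain.

Per side: crop -> histogram equalization -> variance threshold -> mask
multiply -> high-pass -> mean binarization -> largest component -> distance
transform -> medial-axis trace -> disc envelope -> quadratic fit -> width
measurement; then the two sides reduce to the (mean, variance) feature vector.
Every stage failure is re-raised with the stage name and side attached, and
audit images of the intermediate stages can be written for visual inspection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from cortiscan import enhance, io, margins as margins_mod, width as width_mod
from cortiscan.enhance import RoiBox
from cortiscan.errors import PipelineStageError
from cortiscan.svm import SVMResults
from cortiscan.width import DEFAULT_PIXEL_SPACING_MM, FeatureVector, WidthProfile


@dataclass(frozen=True)
class PipelineConfig:
    """Stage parameters for a measurement run.

    ``end_trim`` controls how many columns are dropped from each end of the
    margin span before the polynomial fit and width measurement; ``"auto"``
    trims by the maximum distance value on the trace, discarding the taper the
    distance transform produces where the cortex is cut off by the ROI border.
    """

    roi_right: tuple[int, int, int, int] | None = None
    roi_left: tuple[int, int, int, int] | None = None
    kernel_size: int = 75
    pixel_spacing_mm: float = DEFAULT_PIXEL_SPACING_MM
    gamma: float = 1.0
    C: float = 1.0
    target_sensitivity: float = 0.90
    end_trim: int | str = "auto"
    audit_dir: str | None = None

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        return cls(**io.load_config(path))


@dataclass
class SubjectResult:
    subject_id: str
    features: FeatureVector
    profiles: dict = field(repr=False, default_factory=dict)
    decision_score: float | None = None
    predicted_label: int | None = None
    stage_log: dict = field(repr=False, default_factory=dict)


def _audit_write(audit_dir, side, stage, array):
    if audit_dir is None:
        return
    path = Path(audit_dir)
    path.mkdir(parents=True, exist_ok=True)
    arr = np.asarray(array, dtype=float)
    lo, hi = arr.min(), arr.max()
    scaled = (arr - lo) / (hi - lo) * 255 if hi > lo else np.zeros_like(arr)
    io.write_gray_image(path / f"{side}_{stage}.png", scaled)


def measure_side(image, side: str, cfg: PipelineConfig) -> WidthProfile:
    """Run the full single-side chain from raw ROI image to width profile."""
    stage = "crop_roi"
    try:
        box = getattr(cfg, f"roi_{side}")
        roi = enhance.crop_roi(image, RoiBox(*box, side=side)) if box else np.asarray(image)
        _audit_write(cfg.audit_dir, side, "00_roi", roi)

        stage = "equalize_histogram"
        eq = enhance.equalize_histogram(roi)
        _audit_write(cfg.audit_dir, side, "01_equalized", eq)

        stage = "variance_threshold"
        _, otsu_mask = enhance.variance_threshold(eq)
        _audit_write(cfg.audit_dir, side, "02_otsu_mask", otsu_mask * 255)

        stage = "mask_multiply"
        mult = enhance.mask_multiply(eq, otsu_mask)

        stage = "highpass"
        hp = enhance.highpass(mult, cfg.kernel_size)
        _audit_write(cfg.audit_dir, side, "03_highpass", hp)

        stage = "binarize_mean"
        # restrict to the object class: pixels already removed as background
        # by the variance threshold cannot re-enter via the high-pass step
        binary = enhance.binarize_mean(hp) & otsu_mask

        stage = "largest_component"
        obj = margins_mod.largest_component(binary)
        _audit_write(cfg.audit_dir, side, "04_object", obj * 255)

        stage = "endf"
        dmap = margins_mod.endf(obj)
        _audit_write(cfg.audit_dir, side, "05_endf", dmap)

        stage = "trace_medial_axis"
        trace = margins_mod.trace_medial_axis(dmap)

        stage = "disc_envelope"
        marg = margins_mod.disc_envelope(trace, dmap)

        stage = "trim"
        if cfg.end_trim == "auto":
            trim = int(dmap[trace.rows, trace.columns].max())
        else:
            trim = int(cfg.end_trim)
        n = len(marg.columns)
        if n - 2 * trim >= 10:
            marg = margins_mod.CorticalMargins(
                start_col=marg.start_col + trim, end_col=marg.end_col - trim,
                upper=marg.upper[trim:n - trim], lower=marg.lower[trim:n - trim])

        stage = "fit_upper_polynomial"
        poly = width_mod.fit_upper_polynomial(marg)

        stage = "measure_widths"
        return width_mod.measure_widths(marg, poly, cfg.pixel_spacing_mm, side=side)
    except PipelineStageError:
        raise
    except Exception as exc:
        raise PipelineStageError(stage, side, exc) from exc


def run_subject(image_right, image_left, cfg: PipelineConfig | None = None,
                model: SVMResults | None = None,
                subject_id: str = "subject") -> SubjectResult:
    """Measure both sides, reduce to features, and optionally classify."""
    cfg = cfg or PipelineConfig()
    prof_r = measure_side(image_right, "right", cfg)
    prof_l = measure_side(image_left, "left", cfg)
    features = width_mod.extract_features(prof_r, prof_l)
    result = SubjectResult(subject_id=subject_id, features=features,
                           profiles={"right": prof_r, "left": prof_l},
                           stage_log={"kernel_size": cfg.kernel_size,
                                      "pixel_spacing_mm": cfg.pixel_spacing_mm,
                                      "end_trim": cfg.end_trim})
    if model is not None:
        score = float(model.decision_score(features.as_array())[0])
        cutoff = model.operating_point.cutoff if model.operating_point else 0.0
        result.decision_score = score
        result.predicted_label = 1 if score >= cutoff else -1
    return result


def write_run_log(path, cfg: PipelineConfig, extra: dict | None = None) -> None:
    """Machine-readable record of the stage parameters of a run."""
    payload = {
        "roi_right": cfg.roi_right, "roi_left": cfg.roi_left,
        "kernel_size": cfg.kernel_size,
        "pixel_spacing_mm": cfg.pixel_spacing_mm,
        "gamma": cfg.gamma, "C": cfg.C,
        "target_sensitivity": cfg.target_sensitivity,
        "end_trim": cfg.end_trim,
    }
    if extra:
        payload.update(extra)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
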