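"""Image and configuration I/O.

Images are 8-bit grayscale PNG/TIFF; multi-channel or non-8-bit input is
rejected explicitly rather than silently converted. The pipeline config is a
TOML file, e.g.::

    [roi]
    right = [400, 100, 300, 300]   # top, left, height, width
    left = [400, 1500, 300, 300]

    [enhance]
    kernel_size = 75

    [measure]
    pixel_spacing_mm = 0.08466666666666667

    [svm]
    gamma = 1.0
    cost = 1.0
    target_sensitivity = 0.90
"""

from __future__ import annotations

import tomllib

import imageio.v3 as iio
import numpy as np

from cortiscan.errors import ParameterError


def read_gray_image(path) -> np.ndarray:
    """Read an 8-bit grayscale image, rejecting anything else."""
    arr = iio.imread(path)
    if arr.ndim == 3:
        raise ParameterError(
            f"{path}: expected single-channel grayscale, got {arr.shape[2]} channels")
    if arr.ndim != 2:
        raise ParameterError(f"{path}: expected a 2-D image, got ndim={arr.ndim}")
    if arr.dtype != np.uint8:
        raise ParameterError(f"{path}: expected 8-bit pixels, got dtype {arr.dtype}")
    return arr


def write_gray_image(path, image) -> None:
    arr = np.asarray(image)
    if arr.dtype != np.uint8:
        arr = np.clip(np.rint(arr.astype(float)), 0, 255).astype(np.uint8)
    iio.imwrite(path, arr)


def load_config(path) -> dict:
    """Parse a TOML pipeline config into a flat dict of known keys."""
    try:
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
    except tomllib.TOMLDecodeError as exc:
        raise ParameterError(f"{path}: config parse error: {exc}") from exc
    cfg: dict = {}
    roi = raw.get("roi", {})
    for side in ("right", "left"):
        if side in roi:
            box = roi[side]
            if len(box) != 4:
                raise ParameterError(
                    f"{path}: roi.{side} must be [top, left, height, width]")
            cfg[f"roi_{side}"] = tuple(int(v) for v in box)
    enh = raw.get("enhance", {})
    if "kernel_size" in enh:
        cfg["kernel_size"] = int(enh["kernel_size"])
    meas = raw.get("measure", {})
    if "pixel_spacing_mm" in meas:
        cfg["pixel_spacing_mm"] = float(meas["pixel_spacing_mm"])
    svm = raw.get("svm", {})
    for key, name in (("gamma", "gamma"), ("cost", "C"),
                      ("target_sensitivity", "target_sensitivity")):
        if key in svm:
            cfg[name] = float(svm[key])
    return cfg
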