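"""Independent brute-force oracles used to validate the implementation.

Each oracle recomputes a quantity from its definition by direct enumeration,
deliberately avoiding the algorithms used in the package (raster scans,
dynamic programming, vectorized sweeps).
"""

from itertools import product

import numpy as np


def oracle_equalize(image: np.ndarray) -> np.ndarray:
    """CDF remap computed by direct counting, pixel by pixel."""
    flat = image.ravel()
    n = flat.size
    out = np.empty_like(flat)
    for i, v in enumerate(flat):
        out[i] = int(round(np.sum(flat <= v) / n * 255))
    return out.reshape(image.shape).astype(np.uint8)


def oracle_otsu(image: np.ndarray) -> int:
    """Exhaustive 256-level between-class-variance sweep by direct masking."""
    flat = image.ravel().astype(float)
    n = flat.size
    best_t, best_v = None, -1.0
    for t in range(256):
        lo = flat[flat <= t]
        hi = flat[flat > t]
        if lo.size == 0 or hi.size == 0:
            continue
        w0, w1 = lo.size / n, hi.size / n
        v = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if v > best_v:
            best_v, best_t = v, t
    return best_t


def oracle_highpass(image: np.ndarray, k: int) -> np.ndarray:
    """Sliding-window mean subtraction with edge replication, by loops."""
    img = image.astype(float)
    pad = k // 2
    padded = np.pad(img, pad, mode="edge")
    out = np.empty_like(img)
    for r in range(img.shape[0]):
        for c in range(img.shape[1]):
            out[r, c] = img[r, c] - padded[r:r + k, c:c + k].mean()
    return out


def oracle_chessboard(mask: np.ndarray) -> np.ndarray:
    """All-pairs chessboard distance, image border counting as background."""
    m = mask != 0
    n_rows, n_cols = m.shape
    padded = np.pad(m, 1, mode="constant", constant_values=False)
    bg = np.argwhere(~padded)  # in padded coordinates
    fg = np.argwhere(m) + 1
    out = np.zeros((n_rows, n_cols), dtype=int)
    if fg.size:
        d = np.maximum(np.abs(fg[:, None, 0] - bg[None, :, 0]),
                       np.abs(fg[:, None, 1] - bg[None, :, 1])).min(axis=1)
        out[fg[:, 0] - 1, fg[:, 1] - 1] = d
    return out


def oracle_best_path_sum(dmap: np.ndarray) -> float:
    """Exhaustive enumeration of all feasible left-to-right ridge paths.

    Paths start in any positive cell of the leftmost positive column, advance
    one column per step with row moves in {-1, 0, +1}, visit only positive
    cells, and end in the rightmost positive column. Returns the maximum path
    sum (-inf if no feasible path exists).
    """
    d = np.asarray(dmap, dtype=float)
    pos = d > 0
    col_any = pos.any(axis=0)
    c0 = int(np.argmax(col_any))
    c1 = int(len(col_any) - 1 - np.argmax(col_any[::-1]))
    width = c1 - c0 + 1
    n_rows = d.shape[0]
    best = -np.inf
    if width == 1:
        vals = d[pos[:, c0], c0]
        return float(vals.max()) if vals.size else best
    steps = np.array(list(product((-1, 0, 1), repeat=width - 1)))
    for r_start in range(n_rows):
        if not pos[r_start, c0]:
            continue
        rows = r_start + np.concatenate(
            [np.zeros((len(steps), 1), dtype=int), np.cumsum(steps, axis=1)],
            axis=1)
        inside = ((rows >= 0) & (rows < n_rows)).all(axis=1)
        rows_ok = rows[inside]
        cols = np.arange(c0, c1 + 1)
        feasible = pos[rows_ok, cols].all(axis=1)
        if feasible.any():
            sums = d[rows_ok[feasible], cols].sum(axis=1)
            best = max(best, float(sums.max()))
    return best


def oracle_envelope(trace_rows, trace_cols, values, radii, shape="square"):
    """Per-column disc-envelope extremes by direct loops over all discs."""
    n = len(trace_cols)
    upper = [np.inf] * n
    lower = [-np.inf] * n
    for i in range(n):          # target column index
        c = trace_cols[i]
        for j in range(n):      # disc index
            rho = radii[j]
            dc = abs(c - trace_cols[j])
            if dc > rho:
                continue
            if shape == "square":
                half = rho
            else:
                half = (rho * rho - dc * dc) ** 0.5
            upper[i] = min(upper[i], trace_rows[j] - half)
            lower[i] = max(lower[i], trace_rows[j] + half)
    return np.array(upper), np.array(lower)


def oracle_confusion(pred, lab):
    """Tally a 2x2 table by explicit iteration."""
    tp = fn = fp = tn = 0
    for p, y in zip(pred, lab):
        if y == 1:
            if p == 1:
                tp += 1
            else:
                fn += 1
        else:
            if p == 1:
                fp += 1
            else:
                tn += 1
    return tp, fn, fp, tn


def random_band_mask(rng, n_rows, n_cols, max_halfwidth=3):
    """Random column-connected positive band for distance/trace tests."""
    lo, hi = max_halfwidth + 1, n_rows - max_halfwidth - 1
    center = rng.integers(lo, hi) if hi > lo else n_rows // 2
    rows = [center]
    for _ in range(n_cols - 1):
        rows.append(int(np.clip(rows[-1] + rng.integers(-1, 2),
                                1, n_rows - 2)))
    mask = np.zeros((n_rows, n_cols), dtype=np.uint8)
    for c, r in enumerate(rows):
        h = int(rng.integers(1, max_halfwidth + 1))
        mask[max(0, r - h):min(n_rows, r + h + 1), c] = 1
    return mask
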