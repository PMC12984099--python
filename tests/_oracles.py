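"""Independent reference implementations used as test oracles.

Everything here is deliberately written from scratch, without importing
any decomposition or metric code from the package, so tests compare two
independent routes to the same quantity.
"""
from __future__ import annotations

import numpy as np
from scipy.interpolate import CubicSpline


# ---------------------------------------------------------------------------
# classic 1D EMD (diff-based extrema, cubic-spline envelopes, SD stopping)


def _extrema_indices_1d(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d = np.diff(x)
    maxima, minima = [], []
    for i in range(1, len(x) - 1):
        if d[i - 1] > 0 and d[i] < 0:
            maxima.append(i)
        elif d[i - 1] < 0 and d[i] > 0:
            minima.append(i)
    return np.array(maxima, dtype=int), np.array(minima, dtype=int)


def _spline_envelope_1d(idx: np.ndarray, vals: np.ndarray, n: int) -> np.ndarray:
    # mirror two extrema across each end (classic boundary treatment)
    k = min(2, len(idx) - 1)
    left = 2 * idx[0] - idx[1:k + 1][::-1]
    right = 2 * idx[-1] - idx[-k - 1:-1][::-1]
    xs = np.concatenate([left, idx, right])
    ys = np.concatenate([vals[1:k + 1][::-1], vals, vals[-k - 1:-1][::-1]])
    xs, uniq = np.unique(xs, return_index=True)
    ys = ys[uniq]
    t = np.arange(n, dtype=float)
    if len(xs) < 4:
        return np.interp(t, xs, ys)
    return CubicSpline(xs, ys)(t)


def emd_1d(
    signal: np.ndarray,
    max_imfs: int = 8,
    max_sift: int = 50,
    sd_stop: float = 0.2,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Classic Huang-style 1D sifting; returns (imfs, residual)."""
    x = np.asarray(signal, dtype=float).ravel()
    n = len(x)
    imfs: list[np.ndarray] = []
    residual = x.copy()
    for _ in range(max_imfs):
        h = residual.copy()
        extracted = False
        for _ in range(max_sift):
            mx, mn = _extrema_indices_1d(h)
            if len(mx) < 2 or len(mn) < 2:
                break
            upper = _spline_envelope_1d(mx, h[mx], n)
            lower = _spline_envelope_1d(mn, h[mn], n)
            m = 0.5 * (upper + lower)
            h_new = h - m
            sd = float(np.sum(m * m) / max(np.sum(h * h), 1e-300))
            h = h_new
            extracted = True
            if sd < sd_stop:
                break
        if not extracted:
            break
        imfs.append(h)
        residual = residual - h
    return imfs, residual


# ---------------------------------------------------------------------------
# brute-force image helpers


def brute_extrema_2d(img: np.ndarray) -> tuple[list, list]:
    """Exhaustive strict 8-neighbour scan (no plateau handling)."""
    h, w = img.shape
    maxima, minima = [], []
    for i in range(h):
        for j in range(w):
            neigh = [
                img[i + di, j + dj]
                for di in (-1, 0, 1)
                for dj in (-1, 0, 1)
                if (di or dj) and 0 <= i + di < h and 0 <= j + dj < w
            ]
            if all(img[i, j] > v for v in neigh):
                maxima.append((i, j))
            if all(img[i, j] < v for v in neigh):
                minima.append((i, j))
    return maxima, minima


def brute_zero_crossings(img: np.ndarray) -> int:
    total = 0
    for arr in (img, img.T):
        for line in arr:
            signs = [np.sign(v) for v in line if v != 0]
            total += sum(
                1 for a, b in zip(signs, signs[1:]) if a != b
            )
    return total


def brute_bilinear_resize(img: np.ndarray, out_size: int) -> np.ndarray:
    """Naive per-pixel bilinear resample, pixel-centre aligned, edge clamp."""
    h, w = img.shape
    out = np.zeros((out_size, out_size))
    sy, sx = h / out_size, w / out_size
    for i in range(out_size):
        for j in range(out_size):
            y = min(max((i + 0.5) * sy - 0.5, 0), h - 1)
            x = min(max((j + 0.5) * sx - 0.5, 0), w - 1)
            y0, x0 = int(np.floor(y)), int(np.floor(x))
            y1, x1 = min(y0 + 1, h - 1), min(x0 + 1, w - 1)
            fy, fx = y - y0, x - x0
            out[i, j] = (
                img[y0, x0] * (1 - fy) * (1 - fx)
                + img[y0, x1] * (1 - fy) * fx
                + img[y1, x0] * fy * (1 - fx)
                + img[y1, x1] * fy * fx
            )
    return out


def brute_confusion(true_labels, pred_labels, k: int) -> np.ndarray:
    counts = np.zeros((k, k), dtype=int)
    for t, p in zip(true_labels, pred_labels):
        counts[t][p] += 1
    return counts


def brute_prf(counts: np.ndarray) -> dict:
    """Per-class precision/recall/F1 straight from the definitions."""
    k = counts.shape[0]
    out = {}
    for i in range(k):
        tp = counts[i, i]
        fp = sum(counts[r, i] for r in range(k)) - tp
        fn = sum(counts[i, c] for c in range(k)) - tp
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        out[i] = (prec, rec, f1)
    return out


def brute_auc(labels, scores) -> float:
    """All-pairs AUC with half credit for ties."""
    pos = [s for y, s in zip(labels, scores) if y == 1]
    neg = [s for y, s in zip(labels, scores) if y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def brute_dice(a: np.ndarray, b: np.ndarray) -> float:
    inter = sum(
        1 for x, y in zip(a.ravel(), b.ravel()) if x and y
    )
    sa = int(np.sum(a != 0))
    sb = int(np.sum(b != 0))
    if sa + sb == 0:
        return 1.0
    return 2.0 * inter / (sa + sb)


def pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    a = a - a.mean()
    b = b - b.mean()
    return float(np.sum(a * b) / np.sqrt(np.sum(a * a) * np.sum(b * b)))
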