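"""Naive, loop-based reference implementations used as independent oracles.

These deliberately avoid the vectorized code paths of the package: GLCMs
are accumulated with explicit Python loops, the 13 co-occurrence statistics
are computed from their literal textbook double-sum definitions (including
the HXY1 / HXY2 information measures, which the package computes via an
algebraic simplification), and dominant gradient orientations come from an
explicit per-pixel SVD.
"""

from __future__ import annotations

import numpy as np


def naive_glcm_stats(P: np.ndarray) -> dict:
    """Literal double-sum definitions of the 13 Haralick statistics."""
    L = P.shape[0]
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    i_idx = np.arange(L)

    energy = sum(P[i, j] ** 2 for i in range(L) for j in range(L))
    entropy = -sum(
        P[i, j] * np.log(P[i, j]) for i in range(L) for j in range(L) if P[i, j] > 0
    )
    inertia = sum((i - j) ** 2 * P[i, j] for i in range(L) for j in range(L))

    mu_x = sum(i * px[i] for i in range(L))
    mu_y = sum(j * py[j] for j in range(L))
    var_x = sum((i - mu_x) ** 2 * px[i] for i in range(L))
    var_y = sum((j - mu_y) ** 2 * py[j] for j in range(L))
    if var_x > 0 and var_y > 0:
        correlation = sum(
            (i - mu_x) * (j - mu_y) * P[i, j] for i in range(L) for j in range(L)
        ) / np.sqrt(var_x * var_y)
    else:
        correlation = 0.0
    idm = sum(P[i, j] / (1 + (i - j) ** 2) for i in range(L) for j in range(L))

    p_sum = np.zeros(2 * L - 1)
    p_dif = np.zeros(L)
    for i in range(L):
        for j in range(L):
            p_sum[i + j] += P[i, j]
            p_dif[abs(i - j)] += P[i, j]
    sum_average = sum(k * p_sum[k] for k in range(2 * L - 1))
    sum_variance = sum((k - sum_average) ** 2 * p_sum[k] for k in range(2 * L - 1))
    sum_entropy = -sum(p_sum[k] * np.log(p_sum[k]) for k in range(2 * L - 1) if p_sum[k] > 0)
    dif_average = sum(k * p_dif[k] for k in range(L))
    difference_variance = sum((k - dif_average) ** 2 * p_dif[k] for k in range(L))
    difference_entropy = -sum(p_dif[k] * np.log(p_dif[k]) for k in range(L) if p_dif[k] > 0)

    hx = -sum(px[i] * np.log(px[i]) for i in range(L) if px[i] > 0)
    hy = -sum(py[j] * np.log(py[j]) for j in range(L) if py[j] > 0)
    # literal HXY1 / HXY2 definitions (not the algebraic shortcut)
    hxy1 = -sum(
        P[i, j] * np.log(px[i] * py[j])
        for i in range(L)
        for j in range(L)
        if P[i, j] > 0 and px[i] * py[j] > 0
    )
    hxy2 = -sum(
        px[i] * py[j] * np.log(px[i] * py[j])
        for i in range(L)
        for j in range(L)
        if px[i] * py[j] > 0
    )
    hmax = max(hx, hy)
    imc1 = (entropy - hxy1) / hmax if hmax > 0 else 0.0
    imc2 = np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - entropy))))

    return {
        "energy": energy,
        "entropy": entropy,
        "inertia": inertia,
        "correlation": correlation,
        "variance": var_x,
        "inverse difference moment": idm,
        "sum average": sum_average,
        "sum variance": sum_variance,
        "sum entropy": sum_entropy,
        "difference variance": difference_variance,
        "difference entropy": difference_entropy,
        "information measure of correlation 1": imc1,
        "information measure of correlation 2": imc2,
    }


def naive_window_glcm(levels: np.ndarray, center: tuple[int, int], window: int,
                      n_levels: int, directions) -> np.ndarray:
    """Symmetric normalized GLCM of one window, pairs fully inside it."""
    half = window // 2
    padded = np.pad(levels, half, mode="reflect")
    r0, c0 = center
    win = padded[r0 : r0 + window, c0 : c0 + window]
    P = np.zeros((n_levels, n_levels))
    for dr, dc in directions:
        for r in range(window):
            for c in range(window):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < window and 0 <= c2 < window:
                    a, b = int(win[r, c]), int(win[r2, c2])
                    P[a, b] += 1
                    P[b, a] += 1
    return P / P.sum()


def naive_quantize(image: np.ndarray, n_levels: int, mask=None) -> np.ndarray:
    ref = image[mask] if mask is not None else image
    lo, hi = float(ref.min()), float(ref.max())
    if hi <= lo:
        return np.zeros(image.shape, dtype=int)
    q = np.floor((image - lo) / (hi - lo) * n_levels).astype(int)
    return np.clip(q, 0, n_levels - 1)


def naive_haralick_maps(image: np.ndarray, window: int, n_levels: int, directions) -> dict:
    """Double-loop windowed Haralick maps over every pixel."""
    from periradiomics.textures import HARALICK_STATISTICS

    levels = naive_quantize(np.asarray(image, float), n_levels)
    H, W = levels.shape
    maps = {s: np.zeros((H, W)) for s in HARALICK_STATISTICS}
    for r in range(H):
        for c in range(W):
            P = naive_window_glcm(levels, (r, c), window, n_levels, directions)
            stats = naive_glcm_stats(P)
            for s in HARALICK_STATISTICS:
                maps[s][r, c] = stats[s]
    return maps


def naive_dominant_orientations(image: np.ndarray, window: int) -> np.ndarray:
    """Per-pixel dominant gradient orientation via explicit SVD."""
    image = np.asarray(image, float)
    padded = np.pad(image, 1, mode="reflect")
    gy, gx = np.gradient(padded)
    gy, gx = gy[1:-1, 1:-1], gx[1:-1, 1:-1]
    half = window // 2
    gx_p = np.pad(gx, half, mode="reflect")
    gy_p = np.pad(gy, half, mode="reflect")
    H, W = image.shape
    theta = np.zeros((H, W))
    for r in range(H):
        for c in range(W):
            Gx = gx_p[r : r + window, c : c + window].ravel()
            Gy = gy_p[r : r + window, c : c + window].ravel()
            F = np.column_stack([Gx, Gy])
            if np.allclose(F, 0):
                theta[r, c] = 0.0
                continue
            _, _, Vt = np.linalg.svd(F, full_matrices=False)
            v = Vt[0]
            theta[r, c] = np.mod(np.arctan2(v[1], v[0]), np.pi)
    return theta


def naive_collage_maps(image: np.ndarray, window: int, n_bins: int, directions) -> dict:
    from periradiomics.textures import HARALICK_STATISTICS

    theta = naive_dominant_orientations(image, window)
    bins = np.clip(np.floor(theta / np.pi * n_bins).astype(int), 0, n_bins - 1)
    H, W = bins.shape
    maps = {s: np.zeros((H, W)) for s in HARALICK_STATISTICS}
    for r in range(H):
        for c in range(W):
            P = naive_window_glcm(bins, (r, c), window, n_bins, directions)
            stats = naive_glcm_stats(P)
            for s in HARALICK_STATISTICS:
                maps[s][r, c] = stats[s]
    return maps


def naive_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank AUC by direct pair enumeration (ties get half credit)."""
    pos = np.asarray(scores)[np.asarray(labels) == 1]
    neg = np.asarray(scores)[np.asarray(labels) == 0]
    wins = 0.0
    for sp in pos:
        for sn in neg:
            wins += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
    return wins / (len(pos) * len(neg))
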