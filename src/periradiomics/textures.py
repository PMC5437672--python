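"""Voxel-wise 2D texture descriptor maps: Laws, Gabor, Haralick, CoLlAGe.

Ninety-nine descriptors are computed per slice and phase:

* 25 Laws energy maps — responses to the 5x5 separable filters built from
  the level/edge/spot/wave/ripple 1D kernels;
* 48 Gabor magnitude maps — 6 frequencies x 8 orientations;
* 13 Haralick maps — gray-level co-occurrence statistics within a sliding
  5x5 window;
* 13 CoLlAGe maps — the same co-occurrence statistics applied to binned
  dominant gradient orientations, quantifying local gradient (dis)order.

All computations are in-plane with mirror padding at image borders.  The
windowed co-occurrence machinery (shared by Haralick and CoLlAGe) only
pairs pixels that both lie inside the analysis window, using unit offsets
in four directions (0, 45, 90, 135 degrees) pooled into one symmetric,
normalized matrix per pixel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

# ---------------------------------------------------------------------------
# Laws energy measures
# ---------------------------------------------------------------------------

LAWS_KERNELS_1D = {
    "L5": np.array([1.0, 4.0, 6.0, 4.0, 1.0]),
    "E5": np.array([-1.0, -2.0, 0.0, 2.0, 1.0]),
    "S5": np.array([-1.0, 0.0, 2.0, 0.0, -1.0]),
    "W5": np.array([-1.0, 2.0, 0.0, -2.0, 1.0]),
    "R5": np.array([1.0, -4.0, 6.0, -4.0, 1.0]),
}
LAWS_ORDER = ["L5", "E5", "S5", "W5", "R5"]

# Descriptor names in Table-4 style ("spot-ripple" = S5 rows, R5 cols).
LAWS_WORD = {"L5": "level", "E5": "edge", "S5": "spot", "W5": "wave", "R5": "ripple"}


def laws_names() -> list[str]:
    return [f"{LAWS_WORD[a]}-{LAWS_WORD[b]}" for a in LAWS_ORDER for b in LAWS_ORDER]


def laws_maps(image: np.ndarray) -> dict[str, np.ndarray]:
    """25 Laws filter responses (row-kernel x col-kernel, row-major order)."""
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or min(image.shape) < 5:
        raise ValueError("slice must be 2D and at least 5x5")
    out: dict[str, np.ndarray] = {}
    for a in LAWS_ORDER:
        for b in LAWS_ORDER:
            kern = np.outer(LAWS_KERNELS_1D[a], LAWS_KERNELS_1D[b])
            name = f"{LAWS_WORD[a]}-{LAWS_WORD[b]}"
            out[name] = ndimage.convolve(image, kern, mode="mirror")
    return out


# ---------------------------------------------------------------------------
# Gabor bank
# ---------------------------------------------------------------------------

GABOR_FREQUENCIES = (0, 2, 4, 8, 16, 32)
GABOR_THETAS_UNIFORM = (0.0, 22.5, 45.0, 67.5, 90.0, 112.5, 135.0, 157.5)
# As printed in the source feature table; 167.5 breaks the uniform grid.
GABOR_THETAS_PRINTED = (0.0, 22.5, 45.0, 67.5, 90.0, 112.5, 135.0, 167.5)
#: Cycles-per-window reference: a frequency index f corresponds to a spatial
#: frequency of f / GABOR_REF_WINDOW cycles per pixel, so f=32 is Nyquist.
GABOR_REF_WINDOW = 64
_BANDWIDTH_SIGMA = 3.0 * np.sqrt(np.log(2.0) / 2.0) / np.pi  # one-octave


def gabor_kernel(f: float, theta_deg: float) -> np.ndarray:
    """Complex Gabor kernel with isotropic Gaussian envelope.

    ``f`` is in cycles per reference window (``GABOR_REF_WINDOW`` px); the
    envelope sigma follows the one-octave-bandwidth convention
    ``sigma = 0.5622 / f0``.  Kernels with f > 0 are DC-corrected (zero
    complex mean) so constant images produce zero response.  ``f = 0`` is
    implemented as the low-pass limit: the unit-sum Gaussian envelope alone,
    with the sigma of the smallest nonzero frequency in the bank.
    """
    if f > 0:
        f0 = f / GABOR_REF_WINDOW
    else:
        f0 = min(x for x in GABOR_FREQUENCIES if x > 0) / GABOR_REF_WINDOW
    sigma = _BANDWIDTH_SIGMA / f0
    half = int(np.ceil(3.0 * sigma))
    y, x = np.mgrid[-half : half + 1, -half : half + 1]
    envelope = np.exp(-(x**2 + y**2) / (2.0 * sigma**2))
    if f <= 0:
        return (envelope / envelope.sum()).astype(complex)
    theta = np.deg2rad(theta_deg)
    xr = x * np.cos(theta) + y * np.sin(theta)
    kern = envelope * np.exp(1j * 2.0 * np.pi * f0 * xr)
    return kern - kern.mean()


def _convolve_mirror(image: np.ndarray, kern: np.ndarray) -> np.ndarray:
    half = kern.shape[0] // 2
    padded = np.pad(image, half, mode="reflect")
    out = signal.fftconvolve(padded, kern[::-1, ::-1].conj(), mode="valid")
    return out


def gabor_names(thetas=GABOR_THETAS_UNIFORM) -> list[str]:
    return [f"f={f}, theta={t:g}" for f in GABOR_FREQUENCIES for t in thetas]


def gabor_maps(
    image: np.ndarray, thetas=GABOR_THETAS_UNIFORM
) -> dict[str, np.ndarray]:
    """48 Gabor magnitude maps, frequency-major then orientation order."""
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("slice must be 2D")
    out: dict[str, np.ndarray] = {}
    for f in GABOR_FREQUENCIES:
        if f <= 0:
            # orientation-independent low-pass response, repeated per theta
            resp = np.abs(_convolve_mirror(image, gabor_kernel(f, 0.0)))
            for t in thetas:
                out[f"f={f}, theta={t:g}"] = resp.copy()
        else:
            for t in thetas:
                resp = _convolve_mirror(image, gabor_kernel(f, t))
                out[f"f={f}, theta={t:g}"] = np.abs(resp)
    return out


# ---------------------------------------------------------------------------
# Windowed co-occurrence statistics (shared by Haralick and CoLlAGe)
# ---------------------------------------------------------------------------

HARALICK_STATISTICS = (
    "energy",
    "entropy",
    "inertia",
    "correlation",
    "variance",
    "inverse difference moment",
    "sum average",
    "sum variance",
    "sum entropy",
    "difference variance",
    "difference entropy",
    "information measure of correlation 1",
    "information measure of correlation 2",
)

#: Unit offsets (drow, dcol) for the four co-occurrence directions.
COOC_DIRECTIONS = ((0, 1), (-1, 1), (-1, 0), (-1, -1))


def _window_pair_indices(window: int, directions) -> tuple[np.ndarray, np.ndarray]:
    """Flat in-window indices (a, b) of all unit-offset pairs fully inside
    the window, for the given directions."""
    a_idx, b_idx = [], []
    for dr, dc in directions:
        for r in range(window):
            for c in range(window):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < window and 0 <= c2 < window:
                    a_idx.append(r * window + c)
                    b_idx.append(r2 * window + c2)
    return np.asarray(a_idx), np.asarray(b_idx)


_GLCM_WEIGHT_CACHE: dict[int, dict] = {}


def _glcm_weights(L: int) -> dict:
    """Precomputed flat weight vectors and diagonal-grouping permutations."""
    if L in _GLCM_WEIGHT_CACHE:
        return _GLCM_WEIGHT_CACHE[L]
    i = np.arange(L, dtype=float)
    I = np.repeat(i, L).reshape(L, L)
    J = I.T
    k_sum = (I + J).astype(int).ravel()
    k_dif = np.abs(I - J).astype(int).ravel()
    perm_sum = np.argsort(k_sum, kind="stable")
    perm_dif = np.argsort(k_dif, kind="stable")
    w = {
        "i": i,
        "inertia": ((I - J) ** 2).ravel(),
        "ij": (I * J).ravel(),
        "idm": (1.0 / (1.0 + (I - J) ** 2)).ravel(),
        "perm_sum": perm_sum,
        "cuts_sum": np.searchsorted(k_sum[perm_sum], np.arange(2 * L - 1)),
        "perm_dif": perm_dif,
        "cuts_dif": np.searchsorted(k_dif[perm_dif], np.arange(L)),
    }
    _GLCM_WEIGHT_CACHE[L] = w
    return w


def _plogp(x: np.ndarray) -> np.ndarray:
    from scipy.special import xlogy

    return xlogy(x, x)


def glcm_statistics(P: np.ndarray) -> dict[str, np.ndarray]:
    """The 13 Haralick statistics of a stack of normalized GLCMs.

    ``P`` has shape ``(m, L, L)``; each matrix must sum to 1.  Entropies use
    the natural logarithm.  Degenerate matrices (zero marginal variance)
    yield correlation 0; a zero information denominator yields IMC1 = 0.
    """
    m, L, _ = P.shape
    w = _glcm_weights(L)
    i = w["i"]
    Pf = np.ascontiguousarray(P.reshape(m, -1))

    px = P.sum(axis=2)  # (m, L) — equals py for symmetric P
    py = P.sum(axis=1)

    energy = np.einsum("ij,ij->i", Pf, Pf)
    entropy = -_plogp(Pf).sum(axis=1)
    inertia = Pf @ w["inertia"]

    mu_x = (px * i).sum(axis=1)
    mu_y = (py * i).sum(axis=1)
    var_x = (px * (i[None, :] - mu_x[:, None]) ** 2).sum(axis=1)
    var_y = (py * (i[None, :] - mu_y[:, None]) ** 2).sum(axis=1)
    sx, sy = np.sqrt(var_x), np.sqrt(var_y)
    cov = Pf @ w["ij"] - mu_x * mu_y
    denom = sx * sy
    correlation = np.where(denom > 0, cov / np.where(denom > 0, denom, 1.0), 0.0)

    variance = var_x
    idm = Pf @ w["idm"]

    # p_{x+y}(k), k = i+j in [0, 2L-2];  p_{x-y}(d), d = |i-j| in [0, L-1]
    p_sum = np.add.reduceat(Pf[:, w["perm_sum"]], w["cuts_sum"], axis=1)
    p_dif = np.add.reduceat(Pf[:, w["perm_dif"]], w["cuts_dif"], axis=1)

    ks = np.arange(2 * L - 1, dtype=float)
    kd = np.arange(L, dtype=float)
    sum_average = p_sum @ ks
    sum_variance = (p_sum * (ks[None, :] - sum_average[:, None]) ** 2).sum(axis=1)
    sum_entropy = -_plogp(p_sum).sum(axis=1)
    dif_average = p_dif @ kd
    difference_variance = (p_dif * (kd[None, :] - dif_average[:, None]) ** 2).sum(axis=1)
    difference_entropy = -_plogp(p_dif).sum(axis=1)

    hx = -_plogp(px).sum(axis=1)
    hy = -_plogp(py).sum(axis=1)
    mutual_info = hx + hy - entropy
    hmax = np.maximum(hx, hy)
    imc1 = np.where(hmax > 0, -mutual_info / np.where(hmax > 0, hmax, 1.0), 0.0)
    imc2 = np.sqrt(np.clip(1.0 - np.exp(-2.0 * mutual_info), 0.0, None))

    return {
        "energy": energy,
        "entropy": entropy,
        "inertia": inertia,
        "correlation": correlation,
        "variance": variance,
        "inverse difference moment": idm,
        "sum average": sum_average,
        "sum variance": sum_variance,
        "sum entropy": sum_entropy,
        "difference variance": difference_variance,
        "difference entropy": difference_entropy,
        "information measure of correlation 1": imc1,
        "information measure of correlation 2": imc2,
    }


def _windowed_cooccurrence_stats(
    levels: np.ndarray,
    n_levels: int,
    window: int,
    directions,
    mask: np.ndarray | None,
    chunk: int = 512,
) -> dict[str, np.ndarray]:
    """Per-pixel co-occurrence statistics of an integer level map.

    Returns one float map per statistic; pixels outside ``mask`` (if given)
    are NaN.  The level map is mirror-padded so every pixel has a full
    ``window`` x ``window`` neighbourhood.
    """
    H, W = levels.shape
    half = window // 2
    padded = np.pad(levels, half, mode="reflect")
    windows = np.lib.stride_tricks.sliding_window_view(padded, (window, window))
    a_idx, b_idx = _window_pair_indices(window, directions)

    if mask is None:
        coords = np.argwhere(np.ones((H, W), dtype=bool))
    else:
        coords = np.argwhere(mask)
    maps = {s: np.full((H, W), np.nan) for s in HARALICK_STATISTICS}
    if coords.size == 0:
        return maps

    L2 = n_levels * n_levels
    for start in range(0, len(coords), chunk):
        cc = coords[start : start + chunk]
        win = windows[cc[:, 0], cc[:, 1]].reshape(len(cc), -1).astype(np.int64)
        A = win[:, a_idx]
        B = win[:, b_idx]
        row = np.arange(len(cc))[:, None] * L2
        flat = np.concatenate(
            [(row + A * n_levels + B).ravel(), (row + B * n_levels + A).ravel()]
        )
        counts = np.bincount(flat, minlength=len(cc) * L2).astype(float)
        P = counts.reshape(len(cc), n_levels, n_levels)
        P /= P.sum(axis=(1, 2), keepdims=True)
        stats = glcm_statistics(P)
        for s in HARALICK_STATISTICS:
            maps[s][cc[:, 0], cc[:, 1]] = stats[s]
    return maps


# ---------------------------------------------------------------------------
# Haralick maps
# ---------------------------------------------------------------------------

@dataclass
class HaralickSpec:
    window_px: int = 5
    n_gray_levels: int = 64
    directions: tuple = COOC_DIRECTIONS

    def __post_init__(self) -> None:
        if self.n_gray_levels < 2:
            raise ValueError("n_gray_levels must be >= 2")
        if self.window_px % 2 == 0:
            raise ValueError("window must be odd-sized")


def quantize_gray_levels(
    image: np.ndarray, n_levels: int, reference_mask: np.ndarray | None = None
) -> np.ndarray:
    """Min-max quantization to integer levels 0..n_levels-1.

    The scaling range is taken over ``reference_mask`` (typically the
    tumor + ring union on the slice) when given, else the whole slice;
    out-of-range values are clipped.  A constant range maps to level 0.
    """
    image = np.asarray(image, dtype=float)
    ref = image[reference_mask] if reference_mask is not None else image
    lo, hi = float(np.min(ref)), float(np.max(ref))
    if hi <= lo:
        return np.zeros(image.shape, dtype=np.int64)
    q = np.floor((image - lo) / (hi - lo) * n_levels).astype(np.int64)
    return np.clip(q, 0, n_levels - 1)


def haralick_maps(
    image: np.ndarray,
    spec: HaralickSpec | None = None,
    mask: np.ndarray | None = None,
    quantization_mask: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """13 windowed Haralick statistic maps of a 2D slice.

    ``mask`` restricts which pixels are evaluated (others are NaN);
    ``quantization_mask`` sets the gray-level scaling region.
    """
    spec = spec or HaralickSpec()
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or min(image.shape) < spec.window_px:
        raise ValueError("slice must be 2D and at least window-sized")
    levels = quantize_gray_levels(image, spec.n_gray_levels, quantization_mask)
    return _windowed_cooccurrence_stats(
        levels, spec.n_gray_levels, spec.window_px, spec.directions, mask
    )


# ---------------------------------------------------------------------------
# CoLlAGe maps
# ---------------------------------------------------------------------------

@dataclass
class CollageSpec:
    window_px: int = 5
    n_orientation_bins: int = 64
    directions: tuple = COOC_DIRECTIONS

    def __post_init__(self) -> None:
        if self.n_orientation_bins < 2:
            raise ValueError("n_orientation_bins must be >= 2")
        if self.window_px % 2 == 0:
            raise ValueError("window must be odd-sized")


def dominant_gradient_orientations(
    image: np.ndarray, window_px: int = 5
) -> np.ndarray:
    """Per-pixel dominant gradient orientation in [0, pi).

    Gradients are central differences on a mirror-padded slice.  For each
    pixel, the dominant orientation is the principal singular direction of
    the stacked gradient vectors in its window, obtained in closed form from
    the 2x2 gradient scatter matrix.  Windows with identically zero
    gradients take orientation 0 (convention for degenerate input).
    """
    image = np.asarray(image, dtype=float)
    padded = np.pad(image, 1, mode="reflect")
    gy, gx = np.gradient(padded)
    gy, gx = gy[1:-1, 1:-1], gx[1:-1, 1:-1]
    size = window_px
    sxx = ndimage.uniform_filter(gx * gx, size=size, mode="mirror")
    syy = ndimage.uniform_filter(gy * gy, size=size, mode="mirror")
    sxy = ndimage.uniform_filter(gx * gy, size=size, mode="mirror")
    theta = 0.5 * np.arctan2(2.0 * sxy, sxx - syy)
    return np.mod(theta, np.pi)


def collage_maps(
    image: np.ndarray,
    spec: CollageSpec | None = None,
    mask: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """13 CoLlAGe maps: Haralick statistics on co-occurring binned dominant
    gradient orientations within a sliding window."""
    spec = spec or CollageSpec()
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or min(image.shape) < spec.window_px:
        raise ValueError("slice must be 2D and at least window-sized")
    theta = dominant_gradient_orientations(image, spec.window_px)
    bins = np.floor(theta / np.pi * spec.n_orientation_bins).astype(np.int64)
    bins = np.clip(bins, 0, spec.n_orientation_bins - 1)
    return _windowed_cooccurrence_stats(
        bins, spec.n_orientation_bins, spec.window_px, spec.directions, mask
    )


# ---------------------------------------------------------------------------
# Full 99-descriptor bank
# ---------------------------------------------------------------------------

@dataclass
class TextureMapSet:
    """Named descriptor maps with (family, descriptor) metadata, in the
    stable bank order: Laws (25), Gabor (48), Haralick (13), CoLlAGe (13)."""

    maps: dict[str, np.ndarray]
    families: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.maps)

    @property
    def names(self) -> list[str]:
        return list(self.maps)


def descriptor_names(thetas=GABOR_THETAS_UNIFORM) -> list[tuple[str, str]]:
    """The 99 (family, descriptor) pairs in bank order."""
    out = [("Laws", n) for n in laws_names()]
    out += [("Gabor", n) for n in gabor_names(thetas)]
    out += [("Haralick", s) for s in HARALICK_STATISTICS]
    out += [("CoLlAGe", s) for s in HARALICK_STATISTICS]
    return out


def texture_bank(
    image: np.ndarray,
    haralick_spec: HaralickSpec | None = None,
    collage_spec: CollageSpec | None = None,
    thetas=GABOR_THETAS_UNIFORM,
    mask: np.ndarray | None = None,
    quantization_mask: np.ndarray | None = None,
) -> TextureMapSet:
    """Compute all 99 descriptor maps of a 2D slice.

    ``mask`` restricts the expensive windowed families (Haralick, CoLlAGe)
    to the pixels of interest; Laws and Gabor maps are always dense.
    """
    maps: dict[str, np.ndarray] = {}
    families: dict[str, str] = {}
    for name, arr in laws_maps(image).items():
        key = f"Laws {name}"
        maps[key], families[key] = arr, "Laws"
    for name, arr in gabor_maps(image, thetas=thetas).items():
        key = f"Gabor {name}"
        maps[key], families[key] = arr, "Gabor"
    for name, arr in haralick_maps(
        image, haralick_spec, mask=mask, quantization_mask=quantization_mask
    ).items():
        key = f"Haralick {name}"
        maps[key], families[key] = arr, "Haralick"
    for name, arr in collage_maps(image, collage_spec, mask=mask).items():
        key = f"CoLlAGe {name}"
        maps[key], families[key] = arr, "CoLlAGe"
    assert len(maps) == 99
    return TextureMapSet(maps=maps, families=families)
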