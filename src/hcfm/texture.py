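"""2D texture and shape descriptors computed on masked projections.

Three descriptor families:

* **Haralick textures** — 13 statistics of the gray-level co-occurrence
  matrix (GLCM), accumulated at distance 1 in 4 directions over pixel
  pairs that both lie inside the object mask, after quantization to 64
  gray levels spanning the object's intensity range.  Reported as the
  mean and the range (max - min) over the 4 directions.
* **Local binary patterns** — rotation-robust uniform-LBP code
  histograms over the mask, at (radius 1, 8 points) and (radius 2,
  12 points), normalized to sum 1.
* **Zernike moments** — magnitudes of complex Zernike moments up to
  degree 8 on the disk circumscribing the mask, computed on the masked
  intensity normalized to unit total, hence invariant to rotation and to
  positive intensity scaling.

Degenerate inputs (empty masks, constant intensity, too few pixel pairs)
yield zeros, never NaN: downstream classifiers require finite values.
"""

from __future__ import annotations

from functools import lru_cache
from math import factorial

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from skimage.feature import local_binary_pattern

N_GRAY_LEVELS = 64
ZERNIKE_DEGREE = 8

HARALICK_NAMES = (
    "asm",
    "contrast",
    "correlation",
    "variance",
    "idm",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "entropy",
    "difference_variance",
    "difference_entropy",
    "imc1",
    "imc2",
)

#: distance-1 co-occurrence offsets (dx, dy): 0, 45, 90, 135 degrees
GLCM_OFFSETS = ((1, 0), (1, 1), (0, 1), (-1, 1))

LBP_CONFIGS = ((1, 8), (2, 12))  # (radius, points) -> points + 2 uniform bins


def quantize(values: np.ndarray, mask: np.ndarray, levels: int = N_GRAY_LEVELS) -> np.ndarray:
    """Quantize masked intensities to ``levels`` bins over their min-max."""
    q = np.zeros(values.shape, dtype=np.int64)
    inside = values[mask]
    if inside.size == 0:
        return q
    lo, hi = float(inside.min()), float(inside.max())
    if hi > lo:
        scaled = (values - lo) / (hi - lo) * levels
        q = np.clip(scaled.astype(np.int64), 0, levels - 1)
        q[~mask] = 0
    return q


def _glcm(quantized: np.ndarray, mask: np.ndarray, offset: tuple[int, int]) -> np.ndarray:
    """Symmetric normalized co-occurrence matrix for one offset, masked pairs
    only."""
    dx, dy = offset
    nx, ny = quantized.shape
    sx = slice(max(dx, 0), nx + min(dx, 0))
    sy = slice(max(dy, 0), ny + min(dy, 0))
    tx = slice(max(-dx, 0), nx + min(-dx, 0))
    ty = slice(max(-dy, 0), ny + min(-dy, 0))
    valid = mask[sx, sy] & mask[tx, ty]
    a = quantized[sx, sy][valid]
    b = quantized[tx, ty][valid]
    p = np.zeros((N_GRAY_LEVELS, N_GRAY_LEVELS), dtype=float)
    if a.size:
        np.add.at(p, (a, b), 1.0)
        p += p.T
        p /= p.sum()
    return p


def _haralick_13(p: np.ndarray) -> np.ndarray:
    """The 13 Haralick statistics of one normalized symmetric GLCM."""
    if p.sum() == 0:
        return np.zeros(13)
    L = p.shape[0]
    i = np.arange(L, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    mu = float((i * px).sum())
    sigma = float(np.sqrt(((i - mu) ** 2 * px).sum()))

    def ent(v: np.ndarray) -> float:
        v = v[v > 0]
        return float(-(v * np.log(v)).sum())

    asm = float((p**2).sum())
    contrast = float(((ii - jj) ** 2 * p).sum())
    if sigma > 0:
        correlation = float(((ii * jj * p).sum() - mu * mu) / (sigma * sigma))
    else:
        correlation = 0.0
    variance = float(((ii - mu) ** 2 * p).sum())
    idm = float((p / (1.0 + (ii - jj) ** 2)).sum())

    # distributions of i+j and |i-j|
    psum = np.zeros(2 * L - 1)
    np.add.at(psum, (ii + jj).astype(int).ravel(), p.ravel())
    pdiff = np.zeros(L)
    np.add.at(pdiff, np.abs(ii - jj).astype(int).ravel(), p.ravel())
    k_sum = np.arange(2 * L - 1, dtype=float)
    k_diff = np.arange(L, dtype=float)

    sum_average = float((k_sum * psum).sum())
    sum_variance = float(((k_sum - sum_average) ** 2 * psum).sum())
    sum_entropy = ent(psum)
    entropy = ent(p.ravel())
    diff_mean = float((k_diff * pdiff).sum())
    difference_variance = float(((k_diff - diff_mean) ** 2 * pdiff).sum())
    difference_entropy = ent(pdiff)

    # information measures of correlation
    hx = ent(px)
    outer = np.outer(px, px)
    nz = (p > 0) & (outer > 0)
    hxy1 = float(-(p[nz] * np.log(outer[nz])).sum())
    hxy2 = ent(outer.ravel())
    denom = hx  # symmetric GLCM: HX == HY
    imc1 = (entropy - hxy1) / denom if denom > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - entropy)))))

    return np.array(
        [asm, contrast, correlation, variance, idm, sum_average, sum_variance,
         sum_entropy, entropy, difference_variance, difference_entropy, imc1, imc2]
    )


def haralick_features(values: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Direction means and ranges of the 13 Haralick statistics.

    Returns ``(means, ranges)``, each of length 13; zeros when the mask
    provides no co-occurring pixel pairs.
    """
    q = quantize(values, mask)
    per_dir = np.array([_haralick_13(_glcm(q, mask, off)) for off in GLCM_OFFSETS])
    return per_dir.mean(axis=0), per_dir.max(axis=0) - per_dir.min(axis=0)


def lbp_histograms(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Concatenated uniform-LBP histograms (10 + 14 = 24 bins), mask pixels
    only, each histogram normalized to sum 1."""
    import warnings

    out = []
    v = values.astype(float)
    for radius, points in LBP_CONFIGS:
        n_bins = points + 2
        if mask.any() and min(v.shape) > 2 * radius:
            with warnings.catch_warnings():
                # projections are floats by design; the comparison-based
                # codes are well defined for them
                warnings.simplefilter("ignore", UserWarning)
                codes = local_binary_pattern(v, points, radius, method="uniform")
            hist = np.bincount(codes[mask].astype(int), minlength=n_bins)[:n_bins]
            total = hist.sum()
            out.append(hist / total if total else np.zeros(n_bins))
        else:
            out.append(np.zeros(n_bins))
    return np.concatenate(out)


@lru_cache(maxsize=None)
def zernike_indices(degree: int = ZERNIKE_DEGREE) -> tuple[tuple[int, int], ...]:
    """(n, m) index pairs with 0 <= m <= n, n - m even, n <= degree."""
    return tuple((n, m) for n in range(degree + 1) for m in range(n % 2, n + 1, 2))


@lru_cache(maxsize=None)
def _radial_coeffs(n: int, m: int) -> tuple[tuple[int, float], ...]:
    """(power, coefficient) terms of the radial polynomial R_nm."""
    terms = []
    for s in range((n - m) // 2 + 1):
        c = (-1) ** s * factorial(n - s) / (
            factorial(s) * factorial((n + m) // 2 - s) * factorial((n - m) // 2 - s)
        )
        terms.append((n - 2 * s, float(c)))
    return tuple(terms)


def zernike_magnitudes(
    values: np.ndarray,
    mask: np.ndarray,
    degree: int = ZERNIKE_DEGREE,
) -> np.ndarray:
    """|Z_nm| up to ``degree`` over the disk circumscribing the mask.

    The disk is centered at the mask centroid with radius half the larger
    bounding-box side of the mask.  The masked intensity is normalized to
    unit total mass, making the magnitudes invariant to positive
    intensity scaling; magnitudes are rotation-invariant by construction.
    """
    idx = zernike_indices(degree)
    if not mask.any():
        return np.zeros(len(idx))
    xs, ys = np.nonzero(mask)
    cx, cy = xs.mean(), ys.mean()
    radius = max(xs.max() - xs.min() + 1, ys.max() - ys.min() + 1) / 2.0
    if radius <= 0:
        return np.zeros(len(idx))
    f = values[mask].astype(float)
    total = f.sum()
    if total <= 0:
        return np.zeros(len(idx))
    f = f / total
    dx = (xs - cx) / radius
    dy = (ys - cy) / radius
    rho = np.hypot(dx, dy)
    inside = rho <= 1.0
    if not inside.any():
        return np.zeros(len(idx))
    rho = rho[inside]
    theta = np.arctan2(dy[inside], dx[inside])
    f = f[inside]
    powers = rho[None, :] ** np.arange(degree + 1)[:, None]
    out = np.empty(len(idx))
    for k, (n, m) in enumerate(idx):
        radial = np.zeros_like(rho)
        for power, coeff in _radial_coeffs(n, m):
            radial += coeff * powers[power]
        moment = (n + 1) / np.pi * np.sum(f * radial * np.exp(-1j * m * theta))
        out[k] = np.abs(moment)
    return out


def feret_diameters(mask: np.ndarray) -> tuple[float, float]:
    """(max, min) Feret diameters of a binary mask, in pixels.

    Computed on the convex hull of pixel centers by rotating calipers
    over hull edges; degenerate masks (collinear or single-pixel) fall
    back to the maximum pairwise extent and width 0.
    """
    pts = np.column_stack(np.nonzero(mask)).astype(float)
    if len(pts) == 0:
        return 0.0, 0.0
    if len(pts) < 3:
        d = float(np.linalg.norm(pts.max(axis=0) - pts.min(axis=0)))
        return d, 0.0
    try:
        hull = ConvexHull(pts)
    except QhullError:
        d = float(np.linalg.norm(pts.max(axis=0) - pts.min(axis=0)))
        return d, 0.0
    h = pts[hull.vertices]
    dists = np.linalg.norm(h[:, None, :] - h[None, :, :], axis=2)
    feret_max = float(dists.max())
    edges = np.roll(h, -1, axis=0) - h
    norms = np.linalg.norm(edges, axis=1)
    widths = []
    for e, nrm in zip(edges, norms):
        if nrm == 0:
            continue
        normal = np.array([-e[1], e[0]]) / nrm
        proj = h @ normal
        widths.append(proj.max() - proj.min())
    feret_min = float(min(widths)) if widths else 0.0
    return feret_max, feret_min
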