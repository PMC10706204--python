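"""Radiomic texture and morphological features of the stained ROI.

Texture: 93 features per image form — 18 first-order histogram statistics
plus 75 gray-matrix features (GLCM 24, GLRLM 16, GLSZM 16, NGTDM 5, GLDM
14, following the standard radiomics definitions) — computed on 9 forms of
the green-channel ROI: the original, Laplacian-of-Gaussian at sigma 1, 2, 3,
the four subbands of a one-level Haar wavelet decomposition, and the
rotation-invariant uniform local binary pattern code image.  93 x 9 = 837
texture values, named ``texture-<form>-<idx>``.

Morphology: 9 aggregate shape features of the segmented staining regions
(Table-style order): mean area, total area, mean perimeter-to-area ratio,
total perimeter-to-area ratio, mean circularity (4*pi*A/P^2), mean
perimeter, total perimeter, minimum-rotated-rectangle aspect ratio
(short/long, averaged), and region count; named ``morphology-<i>``.

Gray levels are discretized to a fixed number of equal-width bins (default
32) over the masked intensity range.  All matrix features are defined (no
NaN) in the single-gray-level limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import ndimage as ndi
from skimage.feature import local_binary_pattern
from skimage.transform import resize

from .stain_segmenter import StainMap

__all__ = [
    "ImageForm",
    "FORM_NAMES",
    "FIRST_ORDER_NAMES",
    "MATRIX_FEATURE_NAMES",
    "MORPH_NAMES",
    "make_forms",
    "first_order",
    "matrix_features",
    "texture_block",
    "morph_block",
    "feature_definitions",
]

_EPS = np.finfo(np.float64).tiny

FORM_NAMES = (
    "original",
    "log-sigma-1",
    "log-sigma-2",
    "log-sigma-3",
    "wavelet-LL",
    "wavelet-LH",
    "wavelet-HL",
    "wavelet-HH",
    "lbp",
)

FIRST_ORDER_NAMES = (
    "energy",
    "total_energy",
    "entropy",
    "minimum",
    "percentile10",
    "percentile90",
    "maximum",
    "mean",
    "median",
    "interquartile_range",
    "range",
    "mean_absolute_deviation",
    "robust_mean_absolute_deviation",
    "root_mean_squared",
    "skewness",
    "kurtosis",
    "variance",
    "uniformity",
)

GLCM_NAMES = (
    "glcm_autocorrelation",
    "glcm_cluster_prominence",
    "glcm_cluster_shade",
    "glcm_cluster_tendency",
    "glcm_contrast",
    "glcm_correlation",
    "glcm_difference_average",
    "glcm_difference_entropy",
    "glcm_difference_variance",
    "glcm_id",
    "glcm_idm",
    "glcm_idmn",
    "glcm_idn",
    "glcm_imc1",
    "glcm_imc2",
    "glcm_inverse_variance",
    "glcm_joint_average",
    "glcm_joint_energy",
    "glcm_joint_entropy",
    "glcm_maximum_probability",
    "glcm_mcc",
    "glcm_sum_average",
    "glcm_sum_entropy",
    "glcm_sum_squares",
)

GLRLM_NAMES = (
    "glrlm_short_run_emphasis",
    "glrlm_long_run_emphasis",
    "glrlm_gray_level_nonuniformity",
    "glrlm_gray_level_nonuniformity_normalized",
    "glrlm_run_length_nonuniformity",
    "glrlm_run_length_nonuniformity_normalized",
    "glrlm_run_percentage",
    "glrlm_gray_level_variance",
    "glrlm_run_variance",
    "glrlm_run_entropy",
    "glrlm_low_gray_level_run_emphasis",
    "glrlm_high_gray_level_run_emphasis",
    "glrlm_short_run_low_gray_level_emphasis",
    "glrlm_short_run_high_gray_level_emphasis",
    "glrlm_long_run_low_gray_level_emphasis",
    "glrlm_long_run_high_gray_level_emphasis",
)

GLSZM_NAMES = (
    "glszm_small_area_emphasis",
    "glszm_large_area_emphasis",
    "glszm_gray_level_nonuniformity",
    "glszm_gray_level_nonuniformity_normalized",
    "glszm_size_zone_nonuniformity",
    "glszm_size_zone_nonuniformity_normalized",
    "glszm_zone_percentage",
    "glszm_gray_level_variance",
    "glszm_zone_variance",
    "glszm_zone_entropy",
    "glszm_low_gray_level_zone_emphasis",
    "glszm_high_gray_level_zone_emphasis",
    "glszm_small_area_low_gray_level_emphasis",
    "glszm_small_area_high_gray_level_emphasis",
    "glszm_large_area_low_gray_level_emphasis",
    "glszm_large_area_high_gray_level_emphasis",
)

NGTDM_NAMES = (
    "ngtdm_coarseness",
    "ngtdm_contrast",
    "ngtdm_busyness",
    "ngtdm_complexity",
    "ngtdm_strength",
)

GLDM_NAMES = (
    "gldm_small_dependence_emphasis",
    "gldm_large_dependence_emphasis",
    "gldm_gray_level_nonuniformity",
    "gldm_dependence_nonuniformity",
    "gldm_dependence_nonuniformity_normalized",
    "gldm_gray_level_variance",
    "gldm_dependence_variance",
    "gldm_dependence_entropy",
    "gldm_low_gray_level_emphasis",
    "gldm_high_gray_level_emphasis",
    "gldm_small_dependence_low_gray_level_emphasis",
    "gldm_small_dependence_high_gray_level_emphasis",
    "gldm_large_dependence_low_gray_level_emphasis",
    "gldm_large_dependence_high_gray_level_emphasis",
)

MATRIX_FEATURE_NAMES = GLCM_NAMES + GLRLM_NAMES + GLSZM_NAMES + NGTDM_NAMES + GLDM_NAMES
PER_FORM_NAMES = FIRST_ORDER_NAMES + MATRIX_FEATURE_NAMES  # 18 + 75 = 93

MORPH_NAMES = (
    "mean area",
    "total area",
    "mean perimeter-to-area ratio",
    "total perimeter-to-area ratio",
    "mean circularity",
    "mean perimeter",
    "total perimeter",
    "minimum external rectangle aspect ratio",
    "number",
)


@dataclass
class ImageForm:
    name: str
    pixels: np.ndarray = field(repr=False)
    mask: np.ndarray = field(repr=False)


def make_forms(roi: np.ndarray, mask: np.ndarray | None = None) -> list[ImageForm]:
    """The 9 canonical image forms of a grayscale ROI (see module docstring)."""
    if roi.ndim != 2 or min(roi.shape) < 2:
        raise ValueError("ROI must be a 2-D image of at least 2x2 pixels")
    img = roi.astype(np.float64)
    mask = np.ones(roi.shape, bool) if mask is None else mask.astype(bool)
    forms = [ImageForm("original", img, mask)]
    for s in (1, 2, 3):
        forms.append(ImageForm(f"log-sigma-{s}", ndi.gaussian_laplace(img, s), mask))
    ll, (lh, hl, hh) = pywt.dwt2(img, "haar")
    wmask = resize(mask.astype(float), ll.shape, order=0, preserve_range=True) > 0.5
    for name, band in (("wavelet-LL", ll), ("wavelet-LH", lh), ("wavelet-HL", hl), ("wavelet-HH", hh)):
        forms.append(ImageForm(name, band, wmask))
    lbp = local_binary_pattern(
        np.clip(np.rint(img), 0, 255).astype(np.uint8), P=8, R=1, method="uniform"
    )
    forms.append(ImageForm("lbp", lbp, mask))
    assert len(forms) == 9
    return forms


def _discretize(form: np.ndarray, mask: np.ndarray, bins: int) -> np.ndarray:
    """Integer gray levels 1..bins inside the mask, 0 outside."""
    g = np.zeros(form.shape, dtype=np.int32)
    vals = form[mask]
    lo, hi = float(vals.min()), float(vals.max())
    if hi == lo:
        g[mask] = 1
        return g
    q = np.floor((form - lo) / (hi - lo) * bins).astype(np.int32) + 1
    g[mask] = np.clip(q[mask], 1, bins)
    return g


# ---------------------------------------------------------------------------
# first order


def first_order(form: np.ndarray, mask: np.ndarray, bins: int = 32) -> np.ndarray:
    """The 18 first-order statistics of the masked intensities.

    Moment-based shape statistics (skewness, kurtosis) are defined as 0 when
    the variance is 0.
    """
    mask = mask.astype(bool)
    x = form[mask].astype(np.float64)
    if x.size == 0:
        raise ValueError("empty mask")
    mean = x.mean()
    var = x.var()
    m2 = var
    m3 = ((x - mean) ** 3).mean()
    m4 = ((x - mean) ** 4).mean()
    skew = m3 / m2**1.5 if m2 > 0 else 0.0
    kurt = m4 / m2**2 if m2 > 0 else 0.0
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]
    rmad = np.abs(robust - robust.mean()).mean() if robust.size else 0.0
    if x.max() > x.min():
        hist, _ = np.histogram(x, bins=bins, range=(x.min(), x.max()))
        p = hist / hist.sum()
    else:
        p = np.array([1.0])
    p_nz = p[p > 0]
    energy = float((x**2).sum())
    return np.array(
        [
            energy,
            energy,  # total energy; unit pixel spacing
            float(-(p_nz * np.log2(p_nz)).sum()),
            float(x.min()),
            float(p10),
            float(p90),
            float(x.max()),
            float(mean),
            float(p50),
            float(p75 - p25),
            float(x.max() - x.min()),
            float(np.abs(x - mean).mean()),
            float(rmad),
            float(np.sqrt((x**2).mean())),
            float(skew),
            float(kurt),
            float(var),
            float((p**2).sum()),
        ]
    )


# ---------------------------------------------------------------------------
# GLCM

_OFFSETS = ((0, 1), (1, 0), (1, 1), (1, -1))


def _cooccurrence(g: np.ndarray, bins: int, offset) -> np.ndarray:
    dr, dc = offset
    H, W = g.shape
    r0 = slice(max(0, -dr), min(H, H - dr))
    c0 = slice(max(0, -dc), min(W, W - dc))
    r1 = slice(max(0, dr), min(H, H + dr))
    c1 = slice(max(0, dc), min(W, W + dc))
    a = g[r0, c0].ravel()
    b = g[r1, c1].ravel()
    ok = (a > 0) & (b > 0)
    counts = np.bincount(a[ok] * (bins + 1) + b[ok], minlength=(bins + 1) ** 2)
    m = counts.reshape(bins + 1, bins + 1)[1:, 1:].astype(np.float64)
    return m + m.T  # symmetric


def _glcm_features(P: np.ndarray) -> np.ndarray:
    total = P.sum()
    if total == 0:
        return np.zeros(len(GLCM_NAMES))
    present = (P.sum(axis=0) + P.sum(axis=1)) > 0
    levels = np.flatnonzero(present) + 1.0
    P = P[np.ix_(present, present)] / total
    n = len(levels)
    i = levels[:, None]
    j = levels[None, :]
    px = P.sum(axis=1)
    mu = float((levels * px).sum())
    sigma2 = float(((levels - mu) ** 2 * px).sum())

    diff = np.abs(i - j)
    pdiff = np.bincount(diff.astype(int).ravel(), weights=P.ravel())
    kdiff = np.arange(len(pdiff), dtype=float)
    psum = np.bincount((i + j).astype(int).ravel(), weights=P.ravel())
    ksum = np.arange(len(psum), dtype=float)

    Ng = n
    hxy = -(P[P > 0] * np.log2(P[P > 0])).sum()
    pxpy = px[:, None] * px[None, :]
    nz = (P > 0) & (pxpy > 0)
    hxy1 = -(P[nz] * np.log2(pxpy[nz])).sum()
    nz2 = pxpy > 0
    hxy2 = -(pxpy[nz2] * np.log2(pxpy[nz2])).sum()
    hx = -(px[px > 0] * np.log2(px[px > 0])).sum()
    imc1 = (hxy - hxy1) / hx if hx > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    if n >= 2:
        # Q(a,b) = sum_k P(a,k) P(k,b) / (px(a) px(k))  (P symmetric, py = px)
        A = P / np.maximum(px[:, None], _EPS)
        ev = np.sort(np.abs(np.linalg.eigvals(A @ A)))
        mcc = float(np.sqrt(max(0.0, min(1.0, ev[-2].real))))
    else:
        mcc = 1.0

    autocorr = float((i * j * P).sum())
    da = float((kdiff * pdiff).sum())
    pd_nz = pdiff[pdiff > 0]
    corr = (autocorr - mu * mu) / sigma2 if sigma2 > 0 else 0.0
    inv_var = float((pdiff[1:] / kdiff[1:] ** 2).sum()) if len(pdiff) > 1 else 0.0
    ps_nz = psum[psum > 0]
    return np.array(
        [
            autocorr,
            float(((i + j - 2 * mu) ** 4 * P).sum()),
            float(((i + j - 2 * mu) ** 3 * P).sum()),
            float(((i + j - 2 * mu) ** 2 * P).sum()),
            float((diff**2 * P).sum()),
            float(corr),
            da,
            float(-(pd_nz * np.log2(pd_nz)).sum()),
            float(((kdiff - da) ** 2 * pdiff).sum()),
            float((P / (1.0 + diff)).sum()),
            float((P / (1.0 + diff**2)).sum()),
            float((P / (1.0 + (diff / Ng) ** 2)).sum()),
            float((P / (1.0 + diff / Ng)).sum()),
            float(imc1),
            imc2,
            inv_var,
            mu,
            float((P**2).sum()),
            float(hxy),
            float(P.max()),
            mcc,
            float((ksum * psum).sum()),
            float(-(ps_nz * np.log2(ps_nz)).sum()),
            sigma2,
        ]
    )


# ---------------------------------------------------------------------------
# GLRLM


def _direction_lines(g: np.ndarray, offset) -> list[np.ndarray]:
    if offset == (0, 1):
        return list(g)
    if offset == (1, 0):
        return list(g.T)
    if offset == (1, 1):
        return [g.diagonal(o) for o in range(-g.shape[0] + 1, g.shape[1])]
    if offset == (1, -1):
        gf = np.fliplr(g)
        return [gf.diagonal(o) for o in range(-gf.shape[0] + 1, gf.shape[1])]
    raise ValueError(offset)


def _run_lengths(lines: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """(values, lengths) of maximal runs of equal nonzero values."""
    sep = np.zeros(1, dtype=np.int32)
    parts: list[np.ndarray] = []
    for ln in lines:
        parts.append(np.asarray(ln, dtype=np.int32))
        parts.append(sep)
    long = np.concatenate(parts) if parts else sep
    change = np.flatnonzero(np.diff(long)) + 1
    bounds = np.concatenate(([0], change, [len(long)]))
    vals = long[bounds[:-1]]
    lens = np.diff(bounds)
    keep = vals > 0
    return vals[keep], lens[keep]


def _rl_style_features(pij: np.ndarray, levels: np.ndarray, sizes: np.ndarray,
                       n_elems: float, n_pixels: float) -> np.ndarray:
    """Shared 16-feature family for run-length (j = run length) and
    size-zone (j = zone size) matrices.  `pij` is normalized."""
    i = levels[:, None].astype(float)
    jj = sizes[None, :].astype(float)
    pg = pij.sum(axis=1)
    pr = pij.sum(axis=0)
    mu_i = float((levels * pg).sum())
    mu_j = float((sizes * pr).sum())
    p_nz = pij[pij > 0]
    return np.array(
        [
            float((pr / sizes.astype(float) ** 2).sum()),
            float((pr * sizes.astype(float) ** 2).sum()),
            float((pg**2).sum()) * n_elems,
            float((pg**2).sum()),
            float((pr**2).sum()) * n_elems,
            float((pr**2).sum()),
            float(n_elems / n_pixels) if n_pixels else 0.0,
            float(((levels - mu_i) ** 2 * pg).sum()),
            float(((sizes - mu_j) ** 2 * pr).sum()),
            float(-(p_nz * np.log2(p_nz)).sum()),
            float((pij / i**2).sum()),
            float((pij * i**2).sum()),
            float((pij / (i**2 * jj**2)).sum()),
            float((pij * i**2 / jj**2).sum()),
            float((pij * jj**2 / i**2).sum()),
            float((pij * i**2 * jj**2).sum()),
        ]
    )


def _glrlm_features(g: np.ndarray, bins: int, n_pixels: int) -> np.ndarray:
    per_dir = []
    for off in _OFFSETS:
        vals, lens = _run_lengths(_direction_lines(g, off))
        if len(vals) == 0:
            per_dir.append(np.zeros(16))
            continue
        lmax = int(lens.max())
        counts = np.zeros((bins, lmax), dtype=np.float64)
        np.add.at(counts, (vals - 1, lens - 1), 1.0)
        keep_i = counts.sum(axis=1) > 0
        levels = np.flatnonzero(keep_i) + 1.0
        counts = counts[keep_i]
        nr = counts.sum()
        pij = counts / nr
        sizes = np.arange(1, lmax + 1, dtype=float)
        per_dir.append(_rl_style_features(pij, levels, sizes, nr, n_pixels))
    return np.mean(per_dir, axis=0)


# ---------------------------------------------------------------------------
# GLSZM


def _glszm_features(g: np.ndarray, bins: int, n_pixels: int) -> np.ndarray:
    s8 = np.ones((3, 3), dtype=int)
    zone_levels: list[int] = []
    zone_sizes: list[int] = []
    for level in np.unique(g[g > 0]):
        lab, n = ndi.label(g == level, structure=s8)
        if n:
            sizes = np.bincount(lab.ravel())[1:]
            zone_levels.extend([int(level)] * n)
            zone_sizes.extend(sizes.tolist())
    if not zone_sizes:
        return np.zeros(16)
    zl = np.asarray(zone_levels)
    zs = np.asarray(zone_sizes)
    smax = int(zs.max())
    counts = np.zeros((bins, smax), dtype=np.float64)
    np.add.at(counts, (zl - 1, zs - 1), 1.0)
    keep_i = counts.sum(axis=1) > 0
    levels = np.flatnonzero(keep_i) + 1.0
    counts = counts[keep_i]
    nz = counts.sum()
    pij = counts / nz
    sizes = np.arange(1, smax + 1, dtype=float)
    return _rl_style_features(pij, levels, sizes, nz, n_pixels)


# ---------------------------------------------------------------------------
# NGTDM / GLDM

_NEIGHBOR_OFFSETS = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]


def _shift(a: np.ndarray, dr: int, dc: int, fill=0):
    out = np.full_like(a, fill)
    H, W = a.shape
    r_src = slice(max(0, dr), min(H, H + dr))
    c_src = slice(max(0, dc), min(W, W + dc))
    r_dst = slice(max(0, -dr), min(H, H - dr))
    c_dst = slice(max(0, -dc), min(W, W - dc))
    out[r_dst, c_dst] = a[r_src, c_src]
    return out


def _ngtdm_features(g: np.ndarray, bins: int) -> np.ndarray:
    inside = g > 0
    nb_sum = np.zeros(g.shape, dtype=np.float64)
    nb_cnt = np.zeros(g.shape, dtype=np.float64)
    for dr, dc in _NEIGHBOR_OFFSETS:
        sh = _shift(g, dr, dc)
        valid = sh > 0
        nb_sum += sh * valid
        nb_cnt += valid
    valid_px = inside & (nb_cnt > 0)
    nvp = int(valid_px.sum())
    if nvp == 0:
        return np.zeros(5)
    abar = nb_sum[valid_px] / nb_cnt[valid_px]
    gi = g[valid_px].astype(np.float64)
    dev = np.abs(gi - abar)
    n_i = np.bincount(g[valid_px], minlength=bins + 1)[1:].astype(np.float64)
    s_i = np.zeros(bins)
    np.add.at(s_i, g[valid_px] - 1, dev)
    p_i = n_i / nvp
    present = p_i > 0
    lv = np.arange(1, bins + 1, dtype=float)
    ngp = int(present.sum())

    denom_coarse = float((p_i * s_i).sum())
    coarseness = 1.0 / denom_coarse if denom_coarse > 0 else 1e6
    if ngp > 1:
        ii = lv[present][:, None]
        jj = lv[present][None, :]
        pi = p_i[present][:, None]
        pj = p_i[present][None, :]
        si = s_i[present][:, None]
        sj = s_i[present][None, :]
        contrast = float((pi * pj * (ii - jj) ** 2).sum()) / (ngp * (ngp - 1)) * s_i.sum() / nvp
        busy_den = float(np.abs(ii * pi - jj * pj).sum())
        busyness = denom_coarse / busy_den if busy_den > 0 else 0.0
        complexity = float((np.abs(ii - jj) * (pi * si + pj * sj) / (pi + pj)).sum()) / nvp
        s_sum = float(s_i.sum())
        strength = float(((pi + pj) * (ii - jj) ** 2).sum()) / s_sum if s_sum > 0 else 0.0
    else:
        contrast = busyness = complexity = strength = 0.0
    return np.array([coarseness, contrast, busyness, complexity, strength])


def _gldm_features(g: np.ndarray, bins: int) -> np.ndarray:
    inside = g > 0
    dep = np.zeros(g.shape, dtype=np.int32)
    for dr, dc in _NEIGHBOR_OFFSETS:
        sh = _shift(g, dr, dc)
        dep += ((sh == g) & (sh > 0)).astype(np.int32)
    jmax = 9  # dependence size = dependent-neighbor count + 1 (center)
    counts = np.zeros((bins, jmax), dtype=np.float64)
    np.add.at(counts, (g[inside] - 1, dep[inside]), 1.0)
    nz = counts.sum()
    if nz == 0:
        return np.zeros(14)
    keep_i = counts.sum(axis=1) > 0
    levels = np.flatnonzero(keep_i) + 1.0
    P = counts[keep_i] / nz
    i = levels[:, None]
    jj = np.arange(1, jmax + 1, dtype=float)[None, :]
    pg = P.sum(axis=1)
    pd = P.sum(axis=0)
    jv = jj.ravel()
    mu_i = float((levels * pg).sum())
    mu_j = float((jv * pd).sum())
    p_nz = P[P > 0]
    return np.array(
        [
            float((P / jj**2).sum()),
            float((P * jj**2).sum()),
            float((pg**2).sum()) * nz,
            float((pd**2).sum()) * nz,
            float((pd**2).sum()),
            float(((levels - mu_i) ** 2 * pg).sum()),
            float(((jv - mu_j) ** 2 * pd).sum()),
            float(-(p_nz * np.log2(p_nz)).sum()),
            float((P / i**2).sum()),
            float((P * i**2).sum()),
            float((P / (i**2 * jj**2)).sum()),
            float((P * i**2 / jj**2).sum()),
            float((P * jj**2 / i**2).sum()),
            float((P * i**2 * jj**2).sum()),
        ]
    )


def matrix_features(form: np.ndarray, mask: np.ndarray, bins: int = 32) -> np.ndarray:
    """The 75 gray-matrix features (GLCM 24, GLRLM 16, GLSZM 16, NGTDM 5,
    GLDM 14) of one image form, direction-averaged where applicable."""
    mask = mask.astype(bool)
    if not mask.any():
        raise ValueError("empty mask")
    g = _discretize(form, mask, bins)
    n_pixels = int(mask.sum())
    glcm = np.mean([_glcm_features(_cooccurrence(g, bins, off)) for off in _OFFSETS], axis=0)
    glrlm = _glrlm_features(g, bins, n_pixels)
    glszm = _glszm_features(g, bins, n_pixels)
    ngtdm = _ngtdm_features(g, bins)
    gldm = _gldm_features(g, bins)
    out = np.concatenate([glcm, glrlm, glszm, ngtdm, gldm])
    assert out.shape == (75,)
    return out


def texture_block(roi: np.ndarray, mask: np.ndarray, bins: int = 32) -> dict[str, float]:
    """All 837 texture features: 93 per form x 9 forms, named
    ``texture-<form>-<idx>`` (form and idx are 1-based)."""
    out: dict[str, float] = {}
    for fi, form in enumerate(make_forms(roi, mask), start=1):
        fo = first_order(form.pixels, form.mask, bins)
        mx = matrix_features(form.pixels, form.mask, bins)
        vec = np.concatenate([fo, mx])
        assert vec.shape == (93,)
        for idx, v in enumerate(vec, start=1):
            out[f"texture-{fi}-{idx}"] = float(v)
    assert len(out) == 837
    return out


# ---------------------------------------------------------------------------
# morphology


def _min_rect_aspect(coords: np.ndarray) -> float:
    """Short/long side ratio of the minimum-area rotated bounding rectangle."""
    from shapely.geometry import MultiPoint

    if len(coords) < 3:
        return 1.0
    rect = MultiPoint([(float(c), float(r)) for r, c in coords]).minimum_rotated_rectangle
    if rect.geom_type != "Polygon":
        return 1.0
    xy = np.asarray(rect.exterior.coords)
    sides = np.hypot(*np.diff(xy[:3], axis=0).T)
    lo, hi = min(sides), max(sides)
    return float(lo / hi) if hi > 0 else 1.0


def morph_block(stains: StainMap) -> dict[str, float]:
    """The 9 aggregate shape features of the staining regions ("morphology-1"
    .. "morphology-9"); all zeros for an empty map except where a zero
    convention applies."""
    n = stains.n_regions
    if n == 0:
        vals = np.zeros(9)
    else:
        areas = np.asarray(stains.areas, dtype=float)
        perims = np.asarray(stains.perimeters, dtype=float)
        pa = np.where(areas > 0, perims / np.maximum(areas, _EPS), 0.0)
        circ = np.where(perims > 0, 4 * np.pi * areas / np.maximum(perims, _EPS) ** 2, 0.0)
        circ = np.minimum(circ, 1.5)  # rasterization can push tiny regions past 1
        aspects = []
        for lab in range(1, n + 1):
            coords = np.argwhere(stains.labels == lab)
            aspects.append(_min_rect_aspect(coords))
        total_area = areas.sum()
        vals = np.array(
            [
                areas.mean(),
                total_area,
                pa.mean(),
                perims.sum() / total_area if total_area > 0 else 0.0,
                circ.mean(),
                perims.mean(),
                perims.sum(),
                float(np.mean(aspects)),
                float(n),
            ]
        )
    return {f"morphology-{i}": float(v) for i, v in enumerate(vals, start=1)}


def feature_definitions() -> dict[str, str]:
    """Name -> human-readable definition for every canonical feature."""
    out: dict[str, str] = {}
    for fi, fname in enumerate(FORM_NAMES, start=1):
        for idx, stat in enumerate(PER_FORM_NAMES, start=1):
            out[f"texture-{fi}-{idx}"] = f"{stat} on the {fname} form of the ROI"
    for i, name in enumerate(MORPH_NAMES, start=1):
        out[f"morphology-{i}"] = f"{name} of the segmented staining regions"
    from .topo_features import ScaleSet, TOPO_FEATURE_NAMES

    for k, radius in enumerate(ScaleSet().radii, start=1):
        for j, tname in enumerate(TOPO_FEATURE_NAMES, start=1):
            out[f"topology-{k}-{j}"] = f"{tname} of the dilation graph at scale {radius}"
    return out
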