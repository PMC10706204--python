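"""Preprocessing: red-channel extraction, enhancement, reflection removal.

The fixed order is: red channel -> median filter -> CLAHE -> specular
reflection removal.  The red channel shows the strongest sclera/cornea edge
contrast and is nearly blind to the green fluorescein signal, so it is the
working channel for localization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import exposure
from skimage.filters import threshold_otsu
from skimage.filters.rank import median as rank_median
from skimage.morphology import disk, footprint_rectangle

__all__ = ["PreprocConfig", "extract_red", "enhance", "remove_reflections", "preprocess"]


@dataclass(frozen=True)
class PreprocConfig:
    median_kernel: int = 21  # neighborhood side, odd
    clahe_clip: float = 0.01
    clahe_tiles: tuple[int, int] = (8, 8)

    def validate(self) -> None:
        if self.median_kernel < 3 or self.median_kernel % 2 == 0:
            raise ValueError("median_kernel must be odd and >= 3")


def extract_red(image: np.ndarray) -> np.ndarray:
    """Return the red plane of an RGB image (uint8 passthrough)."""
    if image.ndim != 3 or image.shape[-1] < 3:
        raise ValueError("expected a 3-channel RGB image")
    return np.ascontiguousarray(image[..., 0])


def enhance(gray: np.ndarray, cfg: PreprocConfig | None = None) -> np.ndarray:
    """Median filter then CLAHE; returns uint8 of the same shape."""
    if gray.ndim != 2:
        raise ValueError("expected a single-channel image")
    cfg = cfg or PreprocConfig()
    cfg.validate()
    if gray.dtype == np.uint8:
        # histogram-based rank filter: much faster than sorting for uint8
        med = rank_median(gray, footprint_rectangle((cfg.median_kernel,) * 2))
    else:
        med = ndi.median_filter(gray, size=cfg.median_kernel)
    kernel = (
        max(1, gray.shape[0] // cfg.clahe_tiles[0]),
        max(1, gray.shape[1] // cfg.clahe_tiles[1]),
    )
    eq = exposure.equalize_adapthist(med, kernel_size=kernel, clip_limit=cfg.clahe_clip)
    return (eq * 255.0).astype(np.uint8)


def _bimodality(gray_vals: np.ndarray, threshold: float) -> float:
    """Fraction of total variance explained by the Otsu split (0..1)."""
    lo = gray_vals[gray_vals <= threshold]
    hi = gray_vals[gray_vals > threshold]
    if lo.size == 0 or hi.size == 0:
        return 0.0
    total_var = gray_vals.var()
    if total_var == 0:
        return 0.0
    w0 = lo.size / gray_vals.size
    w1 = hi.size / gray_vals.size
    return float(w0 * w1 * (hi.mean() - lo.mean()) ** 2 / total_var)


def remove_reflections(
    gray: np.ndarray,
    interior: np.ndarray | None = None,
    min_bimodality: float = 0.75,
    fill_radius: int = 10,
    max_fraction: float = 0.08,
) -> tuple[np.ndarray, np.ndarray]:
    """Detect and inpaint the brightest (specular) areas.

    Otsu thresholding marks the bright class; the mask is only accepted when
    the histogram is clearly bimodal (between-class variance fraction >=
    `min_bimodality`), so reflection-free unimodal images return an empty
    mask.  Specular highlights cover a small area, so when the first split's
    bright class exceeds `max_fraction` of the region (e.g. it is the corneal
    background over the darker pupil) the bright class is split once more and
    only a small brightest class is accepted.  When `interior` (e.g. the
    corneal disk) is given, detection is restricted to it.  Masked pixels are
    replaced by the median of a surrounding ring of unmasked pixels.
    """
    if gray.ndim != 2:
        raise ValueError("expected a single-channel image")
    region = np.ones_like(gray, dtype=bool) if interior is None else interior.astype(bool)
    vals = gray[region].astype(np.float64)
    mask = np.zeros_like(gray, dtype=bool)
    if vals.size == 0 or vals.max() == vals.min():
        return gray.copy(), mask
    t = threshold_otsu(gray[region])
    if _bimodality(vals, t) < min_bimodality:
        return gray.copy(), mask
    if (vals > t).mean() > max_fraction:
        # bright class is the background itself; look for a small, brighter
        # class within it
        bright = vals[vals > t]
        if bright.max() == bright.min():
            return gray.copy(), mask
        t2 = threshold_otsu(gray[region & (gray > t)])
        if (vals > t2).mean() > max_fraction or _bimodality(bright, t2) < 0.5:
            return gray.copy(), mask
        t = t2
    mask = (gray > t) & region
    out = gray.copy()
    if not mask.any():
        return out, mask
    labels, n = ndi.label(mask, structure=np.ones((3, 3), dtype=int))
    footprint = disk(fill_radius)
    for i in range(1, n + 1):
        comp = labels == i
        ring = ndi.binary_dilation(comp, structure=footprint) & ~mask
        fill = np.median(gray[ring]) if ring.any() else np.median(gray[~mask])
        out[comp] = fill
    return out, mask


def preprocess(
    image: np.ndarray, cfg: PreprocConfig | None = None
) -> np.ndarray:
    """Red channel -> median -> CLAHE.  Reflection removal is applied by the
    pipeline once the corneal interior is known."""
    return enhance(extract_red(image), cfg)
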