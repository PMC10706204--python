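"""Cornea/pupil localization and the inferior 90-degree sector ROI.

The cornea is found from the Otsu-binarized sclera: the widest horizontal
chord of the non-sclera region gives the corneal center and radius.  The
pupil is found with Daugman's integrodifferential operator: the circle
(x0, y0, r) maximizing the Gaussian-smoothed radial derivative of the
circular mean intensity.  The grading ROI is the inferior sector with its
apex at the pupil center, radius reaching the bottom corneal edge, spanning
45 degrees either side of the downward vertical.

Coordinates are 0-based (row, col) with downward = increasing row; the
operator's (x0, y0) is carried as (row, col) internally.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.transform import resize

from .preprocess import _bimodality

__all__ = [
    "LocalizationError",
    "PupilSearchSpec",
    "PupilResult",
    "CorneaGeometry",
    "find_cornea",
    "daugman_objective",
    "daugman_pupil",
    "inferior_roi",
    "extract_roi",
    "project_to_roi",
    "locate",
]

#: normalized ROI frame (rows, cols) used by feature extraction at full scale
DEFAULT_ROI_SIZE = (596, 1104)


class LocalizationError(RuntimeError):
    """Cornea or pupil could not be located."""


@dataclass(frozen=True)
class PupilSearchSpec:
    """Search ranges for Daugman's operator, relative to the corneal radius.

    The candidate centers fill a square box centered on the corneal center
    whose side is `center_box_fraction` of the corneal radius; candidate
    radii span `r_min_frac`..`r_max_frac` of the corneal radius (inclusive).
    """

    center_box_fraction: float = 0.35
    r_min_frac: float = 0.15
    r_max_frac: float = 0.35
    angle_step_deg: float = 1.0
    gaussian_sigma: float = 2.0
    radial_step: float = 1.0
    center_step: int = 3
    flat_tolerance: float = 1e-3

    def validate(self) -> None:
        if not (0 < self.r_min_frac < self.r_max_frac):
            raise ValueError("need 0 < r_min_frac < r_max_frac")
        if self.angle_step_deg <= 0 or self.radial_step <= 0 or self.center_step < 1:
            raise ValueError("steps must be positive")


@dataclass(frozen=True)
class PupilResult:
    center: tuple[float, float]  # (row, col)
    radius: float
    objective: float
    low_confidence: bool = False


@dataclass
class CorneaGeometry:
    """Everything downstream stages need about one localized eye."""

    cornea_center: tuple[float, float]
    cornea_radius: float
    pupil_center: tuple[float, float]
    pupil_radius: float
    sector_radius: float
    image_shape: tuple[int, int]
    roi_mask: np.ndarray = field(repr=False)  # bool, full frame

    def to_json(self) -> str:
        d = {
            "cornea_center": list(self.cornea_center),
            "cornea_radius": self.cornea_radius,
            "pupil_center": list(self.pupil_center),
            "pupil_radius": self.pupil_radius,
            "sector_radius": self.sector_radius,
            "image_shape": list(self.image_shape),
        }
        return json.dumps(d, indent=1)


def find_cornea(gray: np.ndarray, min_bimodality: float = 0.5) -> tuple[tuple[float, float], float]:
    """Locate the corneal circle from the binarized sclera.

    Otsu separates the bright sclera from the darker cornea; the widest
    horizontal run of the largest non-sclera component is taken as the
    corneal diameter (the widest chord of a circle passes through its
    center).  Raises LocalizationError when the histogram shows no bimodal
    sclera/cornea separation.
    """
    if gray.ndim != 2:
        raise ValueError("expected a single-channel image")
    vals = gray.ravel().astype(np.float64)
    if vals.max() == vals.min():
        raise LocalizationError("flat image: no sclera/cornea separation")
    t = threshold_otsu(gray)
    if _bimodality(vals, t) < min_bimodality:
        raise LocalizationError("histogram not bimodal: cannot segment the sclera")
    non_sclera = gray <= t
    labels, n = ndi.label(non_sclera)
    if n == 0:
        raise LocalizationError("no corneal region below the sclera threshold")
    sizes = np.bincount(labels.ravel())[1:]
    comp = labels == (int(np.argmax(sizes)) + 1)

    best_w, best_mid = 0, 0.0
    for row in range(comp.shape[0]):
        line = comp[row]
        if not line.any():
            continue
        # longest run of True in this row
        padded = np.concatenate(([0], line.view(np.uint8), [0]))
        d = np.diff(padded)
        starts = np.flatnonzero(d == 1)
        ends = np.flatnonzero(d == -1)
        widths = ends - starts
        k = int(np.argmax(widths))
        if widths[k] > best_w:
            best_w = int(widths[k])
            best_mid = (starts[k] + ends[k] - 1) / 2.0
    if best_w < 4:
        raise LocalizationError("no corneal chord found")
    # the chord width near the center varies only quadratically with the row,
    # so the argmax row is noise-sensitive; the midpoint of the component's
    # vertical extent estimates the center row far more stably
    rows_present = np.flatnonzero(comp.any(axis=1))
    center_row = (rows_present[0] + rows_present[-1]) / 2.0
    return (float(center_row), float(best_mid)), best_w / 2.0


def daugman_objective(
    gray: np.ndarray,
    centers: np.ndarray,
    radii: np.ndarray,
    sigma: float = 2.0,
    angle_step_deg: float = 1.0,
) -> np.ndarray:
    """Evaluate |G_sigma * d/dr (mean_{arc} I)| on a grid of circles.

    `centers` is (N, 2) in (row, col); `radii` is (R,).  Returns an (N, R)
    array of the absolute smoothed radial derivative of the circular mean
    intensity (the arc integral normalized by 2*pi*r is taken as the mean
    over the sampled arc points).
    """
    img = gray.astype(np.float64)
    centers = np.atleast_2d(np.asarray(centers, dtype=np.float64))
    radii = np.asarray(radii, dtype=np.float64)
    angles = np.deg2rad(np.arange(0.0, 360.0, angle_step_deg))
    ca, sa = np.cos(angles), np.sin(angles)
    n_r, n_a = len(radii), len(angles)

    means = np.empty((len(centers), n_r), dtype=np.float64)
    # chunk candidate centers to bound the sample-coordinate array size
    chunk = max(1, int(4_000_000 / (n_r * n_a)))
    for i0 in range(0, len(centers), chunk):
        sub = centers[i0 : i0 + chunk]
        rows = sub[:, 0, None, None] + radii[None, :, None] * ca[None, None, :]
        cols = sub[:, 1, None, None] + radii[None, :, None] * sa[None, None, :]
        samp = ndi.map_coordinates(
            img, [rows.ravel(), cols.ravel()], order=1, mode="nearest"
        ).reshape(len(sub), n_r, n_a)
        means[i0 : i0 + chunk] = samp.mean(axis=2)

    smooth = ndi.gaussian_filter1d(means, sigma, axis=1, mode="nearest")
    deriv = np.gradient(smooth, radii, axis=1)
    return np.abs(deriv)


def daugman_pupil(
    gray: np.ndarray,
    cornea: tuple[tuple[float, float], float],
    spec: PupilSearchSpec | None = None,
) -> PupilResult:
    """Find the pupil circle inside a located cornea with Daugman's operator.

    Searches a discrete (row, col, r) grid (coarse center grid of step
    `center_step`, refined to 1 px around the best candidate) and returns the
    argmax of the operator.  A near-flat objective sets `low_confidence`.
    """
    spec = spec or PupilSearchSpec()
    spec.validate()
    (cy, cx), R = cornea
    half = spec.center_box_fraction * R / 2.0
    radii = np.arange(spec.r_min_frac * R, spec.r_max_frac * R + 1e-9, spec.radial_step)
    if len(radii) < 3:
        raise LocalizationError("pupil radius search grid is empty")

    def _grid(lo_r, hi_r, lo_c, hi_c, step):
        ys = np.arange(lo_r, hi_r + 1e-9, step)
        xs = np.arange(lo_c, hi_c + 1e-9, step)
        return np.array([(y, x) for y in ys for x in xs])

    centers = _grid(cy - half, cy + half, cx - half, cx + half, spec.center_step)
    if centers.size == 0:
        raise LocalizationError("pupil center search grid is empty")
    obj = daugman_objective(gray, centers, radii, spec.gaussian_sigma, spec.angle_step_deg)
    flat = (obj.max() - obj.min()) < spec.flat_tolerance
    best = int(np.argmax(obj.max(axis=1)))
    by, bx = centers[best]

    if spec.center_step > 1:
        centers2 = _grid(by - spec.center_step, by + spec.center_step,
                         bx - spec.center_step, bx + spec.center_step, 1)
        obj2 = daugman_objective(gray, centers2, radii, spec.gaussian_sigma, spec.angle_step_deg)
        best2 = int(np.argmax(obj2.max(axis=1)))
        by, bx = centers2[best2]
        r_idx = int(np.argmax(obj2[best2]))
        score = float(obj2[best2, r_idx])
    else:
        r_idx = int(np.argmax(obj[best]))
        score = float(obj[best, r_idx])

    return PupilResult(
        center=(float(by), float(bx)),
        radius=float(radii[r_idx]),
        objective=score,
        low_confidence=bool(flat),
    )


def inferior_roi(
    cornea_center: tuple[float, float],
    cornea_radius: float,
    pupil_center: tuple[float, float],
    pupil_radius: float,
    image_shape: tuple[int, int],
) -> CorneaGeometry:
    """Build the inferior-sector ROI mask.

    Sector apex at the pupil center; sector radius = distance from the pupil
    center to the bottom edge of the cornea; included angle 90 degrees about
    the downward vertical (image coordinates).
    """
    bottom = (cornea_center[0] + cornea_radius, cornea_center[1])
    pr, pc = pupil_center
    sector_radius = float(np.hypot(bottom[0] - pr, bottom[1] - pc))
    if sector_radius <= 0:
        raise ValueError("sector radius must be positive")
    H, W = image_shape[:2]
    rr, cc = np.mgrid[0:H, 0:W].astype(np.float64)
    dr = rr - pr
    dc = cc - pc
    dist = np.hypot(dr, dc)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.where(dist > 0, dr / np.maximum(dist, 1e-12), 1.0)
    mask = (dist <= sector_radius) & (cosang >= np.cos(np.deg2rad(45.0)))
    return CorneaGeometry(
        cornea_center=tuple(map(float, cornea_center)),
        cornea_radius=float(cornea_radius),
        pupil_center=(float(pr), float(pc)),
        pupil_radius=float(pupil_radius),
        sector_radius=sector_radius,
        image_shape=(H, W),
        roi_mask=mask,
    )


def _roi_bbox(geom: CorneaGeometry) -> tuple[int, int, int, int]:
    pr, pc = geom.pupil_center
    R = geom.sector_radius
    half_w = R * np.sin(np.deg2rad(45.0))
    r0 = int(np.floor(pr))
    r1 = int(np.ceil(pr + R)) + 1
    c0 = int(np.floor(pc - half_w))
    c1 = int(np.ceil(pc + half_w)) + 1
    H, W = geom.image_shape
    return max(r0, 0), min(r1, H), max(c0, 0), min(c1, W)


def project_to_roi(
    arr: np.ndarray,
    geom: CorneaGeometry,
    out_size: tuple[int, int] = DEFAULT_ROI_SIZE,
    order: int = 1,
) -> np.ndarray:
    """Crop `arr` to the sector bounding box and resize to the normalized
    ROI frame (bilinear for images, order=0 for masks)."""
    r0, r1, c0, c1 = _roi_bbox(geom)
    crop = arr[r0:r1, c0:c1]
    out_shape = out_size + crop.shape[2:]
    is_bool = crop.dtype == bool
    res = resize(
        crop.astype(np.float64),
        out_shape,
        order=order,
        preserve_range=True,
        anti_aliasing=(order > 0),
    )
    if is_bool:
        return res > 0.5
    return res


def extract_roi(
    image: np.ndarray,
    geom: CorneaGeometry,
    out_size: tuple[int, int] = DEFAULT_ROI_SIZE,
) -> tuple[np.ndarray, np.ndarray]:
    """Return (roi_image, roi_mask) in the normalized ROI frame."""
    roi_img = project_to_roi(image, geom, out_size, order=1)
    roi_mask = project_to_roi(geom.roi_mask, geom, out_size, order=0)
    return roi_img, roi_mask


def locate(
    image: np.ndarray,
    preproc_cfg=None,
    pupil_spec: PupilSearchSpec | None = None,
) -> tuple[CorneaGeometry, np.ndarray]:
    """Full localization: preprocess, find cornea, clean reflections inside
    it, find pupil, emit the sector geometry.  Returns (geometry,
    reflection_mask)."""
    from .preprocess import preprocess, remove_reflections

    enhanced = preprocess(image, preproc_cfg)
    (cy, cx), R = find_cornea(enhanced)
    H, W = enhanced.shape
    rr, cc = np.mgrid[0:H, 0:W]
    interior = (rr - cy) ** 2 + (cc - cx) ** 2 <= (0.95 * R) ** 2
    cleaned, refl_mask = remove_reflections(enhanced, interior=interior)
    pupil = daugman_pupil(cleaned, ((cy, cx), R), pupil_spec)
    geom = inferior_roi((cy, cx), R, pupil.center, pupil.radius, (H, W))
    return geom, refl_mask
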