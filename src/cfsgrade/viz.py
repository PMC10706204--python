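"""Rendering helpers for visual QC: geometry overlays, confusion heatmaps,
ROC curves.  All functions return a matplotlib Figure and never show it."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .evaluation import ConfusionMatrix
from .roi_locator import CorneaGeometry
from .stain_segmenter import StainMap

__all__ = ["overlay_geometry", "overlay_stains", "confusion_heatmap", "roc_figure"]


def _circle(ax, center, radius, color, label=None):
    th = np.linspace(0, 2 * np.pi, 200)
    ax.plot(center[1] + radius * np.sin(th), center[0] + radius * np.cos(th),
            color=color, lw=1.2, label=label)


def overlay_geometry(image: np.ndarray, geom: CorneaGeometry):
    """Detected cornea (yellow), pupil (green) and sector ROI (red) drawn
    over the photograph."""
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(image)
    _circle(ax, geom.cornea_center, geom.cornea_radius, "yellow", "cornea")
    _circle(ax, geom.pupil_center, geom.pupil_radius, "lime", "pupil")
    pr, pc = geom.pupil_center
    R = geom.sector_radius
    for sgn in (-1, 1):
        ang = np.deg2rad(45.0)
        ax.plot([pc, pc + sgn * R * np.sin(ang)], [pr, pr + R * np.cos(ang)], "r-", lw=1.2)
    th = np.linspace(-np.pi / 4, np.pi / 4, 100)
    ax.plot(pc + R * np.sin(th), pr + R * np.cos(th), "r--", lw=1.2, label="ROI")
    ax.legend(loc="upper right", fontsize=8)
    ax.set_axis_off()
    return fig


def overlay_stains(roi_image: np.ndarray, stains: StainMap):
    """Segmented staining regions outlined on the normalized ROI."""
    from skimage.segmentation import find_boundaries

    fig, ax = plt.subplots(figsize=(8, 4))
    ax.imshow(np.clip(roi_image, 0, 255).astype(np.uint8))
    edges = find_boundaries(stains.labels > 0)
    overlay = np.zeros(roi_image.shape[:2] + (4,))
    overlay[edges] = (1, 0, 0, 1)
    ax.imshow(overlay)
    ax.set_title(f"{stains.n_regions} staining regions")
    ax.set_axis_off()
    return fig


def confusion_heatmap(cm: ConfusionMatrix):
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(cm.counts, cmap="Blues")
    for (i, j), v in np.ndenumerate(cm.counts):
        ax.text(j, i, str(v), ha="center", va="center", fontsize=9)
    ax.set_xticks(range(len(cm.classes)), cm.classes)
    ax.set_yticks(range(len(cm.classes)), cm.classes)
    ax.set_xlabel("predicted grade")
    ax.set_ylabel("true grade")
    fig.colorbar(im, ax=ax)
    return fig


def roc_figure(scores: np.ndarray, y_true, classes):
    """Per-class one-vs-rest ROC curves plus the micro-averaged curve."""
    from sklearn.metrics import roc_curve

    fig, ax = plt.subplots(figsize=(5, 5))
    y_true = np.asarray(y_true)
    pooled_s, pooled_l = [], []
    for k, cls in enumerate(classes):
        binary = (y_true == cls).astype(int)
        pooled_s.append(scores[:, k])
        pooled_l.append(binary)
        if 0 < binary.sum() < len(binary):
            fpr, tpr, _ = roc_curve(binary, scores[:, k])
            ax.plot(fpr, tpr, lw=1, label=f"grade {cls}")
    fpr, tpr, _ = roc_curve(np.concatenate(pooled_l), np.concatenate(pooled_s))
    ax.plot(fpr, tpr, "k--", lw=1.6, label="micro average")
    ax.plot([0, 1], [0, 1], color="0.8", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(fontsize=8)
    return fig
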