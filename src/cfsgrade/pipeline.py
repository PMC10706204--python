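"""End-to-end orchestration: image -> ROI -> stains -> 974 features -> grade.

`extract_features` runs the full single-image chain; `extract_table` maps it
over a cohort into a feature table; `run_train_eval` runs the selection
cascade and the model-x-signature evaluation grid on a labeled table.

The normalized ROI frame defaults to 596 x 1104 px for full-frame
(1944 x 2592) input and scales proportionally for smaller frames, so
structure sizes stay commensurate with the segmentation's structuring
element at any test scale.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .feature_select import FeatureTable, SelectionConfig, build_signatures, run_selection
from .grading import MODEL_KINDS, SplitPlan, evaluate_grid, split
from .preprocess import PreprocConfig
from .radiomic_features import morph_block, texture_block
from .roi_locator import (
    DEFAULT_ROI_SIZE,
    LocalizationError,
    PupilSearchSpec,
    extract_roi,
    locate,
    project_to_roi,
)
from .stain_segmenter import SegmenterConfig, segment_stains
from .topo_features import ScaleSet, topo_block

__all__ = ["RunConfig", "extract_features", "extract_table", "run_extract", "run_train_eval"]

log = logging.getLogger("cfsgrade")

_FULL_FRAME = (1944, 2592)


@dataclass(frozen=True)
class RunConfig:
    """All stage parameters of one reproducible run."""

    roi_size: tuple[int, int] | None = None  # None -> proportional to frame size
    bins: int = 32
    preproc: PreprocConfig = field(default_factory=PreprocConfig)
    pupil: PupilSearchSpec = field(default_factory=PupilSearchSpec)
    segmenter: SegmenterConfig = field(default_factory=SegmenterConfig)
    scales: ScaleSet = field(default_factory=ScaleSet)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    seed: int = 0

    def roi_size_for(self, image_shape) -> tuple[int, int]:
        if self.roi_size is not None:
            return self.roi_size
        H, W = image_shape[:2]
        return (
            max(32, round(DEFAULT_ROI_SIZE[0] * H / _FULL_FRAME[0])),
            max(32, round(DEFAULT_ROI_SIZE[1] * W / _FULL_FRAME[1])),
        )

    def to_json(self) -> str:
        def enc(o):
            if hasattr(o, "__dataclass_fields__"):
                return {k: getattr(o, k) for k in o.__dataclass_fields__}
            return o

        return json.dumps(self, default=enc, indent=1)


def extract_features(image: np.ndarray, cfg: RunConfig | None = None):
    """Full single-image chain; returns (feature dict of 974 values,
    geometry, stain map)."""
    cfg = cfg or RunConfig()
    roi_size = cfg.roi_size_for(image.shape)
    geom, refl = locate(image, cfg.preproc, cfg.pupil)
    roi_img, roi_mask = extract_roi(image, geom, roi_size)
    refl_roi = project_to_roi(refl, geom, roi_size, order=0) if refl.any() else None
    stains = segment_stains(roi_img, roi_mask, cfg.segmenter, exclude_mask=refl_roi)
    green = roi_img[..., 1]
    feats: dict[str, float] = {}
    feats.update(texture_block(green, roi_mask, cfg.bins))
    feats.update(morph_block(stains))
    feats.update(topo_block(stains, cfg.scales))
    assert len(feats) == 974
    return feats, geom, stains


def extract_table(images, cfg: RunConfig | None = None) -> pd.DataFrame:
    """Feature table (one 974-feature row per image).  Images that fail
    localization are logged and yield an all-NaN row flagged for exclusion."""
    cfg = cfg or RunConfig()
    rows = []
    for i, img in enumerate(images):
        try:
            feats, _, _ = extract_features(img, cfg)
        except LocalizationError as e:
            log.warning("image %d: localization failed (%s); row flagged", i, e)
            feats = {}
        rows.append(feats)
    df = pd.DataFrame(rows)
    return df


def run_extract(input_dir, output_csv=None, cfg: RunConfig | None = None) -> pd.DataFrame:
    """Extract features for every readable image in a directory (sorted
    order).  Unreadable files are skipped and logged; the run continues."""
    import imageio.v3 as iio

    cfg = cfg or RunConfig()
    paths = sorted(
        p for p in Path(input_dir).iterdir()
        if p.suffix.lower() in {".png", ".tif", ".tiff", ".jpg", ".jpeg"}
    )
    names, rows = [], []
    for p in paths:
        try:
            img = iio.imread(p)
        except Exception as e:  # unreadable file: skip and continue
            log.warning("skipping unreadable file %s (%s)", p.name, e)
            continue
        try:
            feats, _, _ = extract_features(img, cfg)
        except LocalizationError as e:
            log.warning("%s: localization failed (%s); row flagged", p.name, e)
            feats = {}
        names.append(p.name)
        rows.append(feats)
    df = pd.DataFrame(rows, index=pd.Index(names, name="filename"))
    if output_csv is not None:
        df.to_csv(output_csv)
    return df


def run_train_eval(
    features: pd.DataFrame,
    labels,
    cfg: RunConfig | None = None,
    plan: SplitPlan | None = None,
    kinds=MODEL_KINDS,
    signature_keys=("A-10", "T-5", "NT-5"),
) -> dict:
    """Selection cascade -> signatures -> model-x-signature metric grid.

    Rows with missing features (failed localization) are excluded.  The
    split is stratified 8:2; selection and normalization statistics are
    computed on the training split only.
    """
    cfg = cfg or RunConfig()
    plan = plan or SplitPlan(seed=cfg.seed)
    labels = np.asarray(labels)
    if len(labels) != len(features):
        raise ValueError("labels must align with feature rows")
    ok = ~features.isna().any(axis=1)
    features = features.loc[ok]
    labels = labels[np.asarray(ok)]

    X_tr, X_te, y_tr, y_te = split(features.values, labels, plan)
    train_df = pd.DataFrame(X_tr, columns=features.columns)
    table = FeatureTable.from_raw(train_df, y_tr)
    sig, stages = run_selection(table, cfg.selection)
    signatures = build_signatures(sig)

    # held-out rows normalized with the frozen training statistics
    test_df = table.apply_normalization(pd.DataFrame(X_te, columns=features.columns))
    sig_sets = {}
    for k in signature_keys:
        if not signatures[k].names:
            import warnings

            warnings.warn(f"signature {k} is empty on this cohort; skipped")
            continue
        sig_sets[k] = signatures[k].names
    grid = evaluate_grid(
        table.data.values, y_tr, test_df.values, y_te,
        sig_sets, table.names, seed=cfg.seed, kinds=kinds,
    )
    return {
        "signatures": {k: signatures[k].names for k in signatures},
        "importance": sig.importance,
        "stages": {k: len(v) for k, v in stages.items()},
        "grid": grid,
        "n_train": int(len(y_tr)),
        "n_test": int(len(y_te)),
    }
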