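"""Segment staining regions in the ROI with top-hat by reconstruction.

The top-hat isolates small bright structures in the green channel while
ignoring smooth background, so detection is invariant to illumination
offsets.  Detected region counts are compared against the ground truth.
"""

from cfsgrade.pipeline import RunConfig
from cfsgrade.roi_locator import extract_roi, locate, project_to_roi
from cfsgrade.stain_segmenter import segment_stains
from cfsgrade.synthetic_eye import make_cohort
from cfsgrade.viz import overlay_stains

cfg = RunConfig()
for sample in make_cohort(5, seed=12):
    geom, refl = locate(sample.image)
    size = cfg.roi_size_for(sample.image.shape)
    roi, mask = extract_roi(sample.image, geom, size)
    refl_roi = project_to_roi(refl, geom, size, order=0) if refl.any() else None
    stains = segment_stains(roi, mask, exclude_mask=refl_roi)
    print(
        f"grade {sample.grade}: true regions {sample.truth.region_count:3d}, "
        f"detected {stains.n_regions:3d}"
    )
# Counts match closely because dots are small bright structures the
# structuring element cannot enter; clustered dots that merge in the image
# are counted as one region in both the truth and the detection.

sample = make_cohort(1, grade_mix=[0, 0, 0, 1.0], seed=5)[0]
geom, _ = locate(sample.image)
roi, mask = extract_roi(sample.image, geom, cfg.roi_size_for(sample.image.shape))
fig = overlay_stains(roi, segment_stains(roi, mask))
fig.savefig("scratch/stain_overlay.png", dpi=120)
print("overlay written to scratch/stain_overlay.png")
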