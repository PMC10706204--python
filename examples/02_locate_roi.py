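"""Locate the cornea, the pupil, and the inferior 90-degree sector ROI.

The cornea comes from the Otsu-binarized sclera (widest chord of the
non-sclera region); the pupil from Daugman's integrodifferential operator;
the ROI is the downward sector with its apex at the pupil center.
"""

import numpy as np

from cfsgrade.roi_locator import locate
from cfsgrade.synthetic_eye import make_cohort
from cfsgrade.viz import overlay_geometry

sample = make_cohort(1, grade_mix=[0, 0, 1.0], seed=3)[0]
geom, reflections = locate(sample.image)

print("true cornea center:", tuple(round(v, 1) for v in sample.eye.cornea_center))
print("found cornea center:", tuple(round(v, 1) for v in geom.cornea_center),
      " radius:", round(geom.cornea_radius, 1))
print("true pupil center:", tuple(round(v, 1) for v in sample.eye.pupil_center),
      " radius:", round(sample.eye.pupil_radius, 1))
print("found pupil center:", tuple(round(v, 1) for v in geom.pupil_center),
      " radius:", round(geom.pupil_radius, 1))
err = np.hypot(geom.pupil_center[0] - sample.eye.pupil_center[0],
               geom.pupil_center[1] - sample.eye.pupil_center[1])
print(f"pupil center error: {err:.2f} px (the operator grid is 1 px)")

fig = overlay_geometry(sample.image, geom)
fig.savefig("scratch/roi_overlay.png", dpi=120)
print("overlay written to scratch/roi_overlay.png")
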