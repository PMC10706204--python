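import numpy as np
import pytest

from cfsgrade.stain_segmenter import StainMap
from cfsgrade.synthetic_eye import EyeSpec, StainSpec, render_eye


@pytest.fixture(scope="session")
def small_eye() -> EyeSpec:
    """A 512x512 eye with cornea r=180 at the center and a centered pupil."""
    return EyeSpec(
        image_height=512,
        image_width=512,
        cornea_center=(256.0, 256.0),
        cornea_radius=180.0,
        pupil_center=(256.0, 256.0),
        pupil_radius=45.0,
    )


@pytest.fixture(scope="session")
def three_dot_eye(small_eye):
    """Same eye with three well-separated inferior dots (OSS grade 1)."""
    stain = StainSpec(
        dot_centers=((360.0, 200.0), (380.0, 256.0), (360.0, 312.0)),
        dot_radii=(5.0, 5.0, 5.0),
        seed=7,
    )
    return render_eye(small_eye, stain)


def stain_map_from_points(points, shape=(120, 200), blob_radius=1) -> StainMap:
    """Build a StainMap with small square blobs at given (row, col) points."""
    mask = np.zeros(shape, dtype=bool)
    for r, c in points:
        r, c = int(r), int(c)
        mask[
            max(0, r - blob_radius) : r + blob_radius + 1,
            max(0, c - blob_radius) : c + blob_radius + 1,
        ] = True
    return StainMap.from_mask(mask)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
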