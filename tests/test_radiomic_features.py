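"""Texture and morphology features: count contracts, closed forms, oracles."""

import numpy as np
import pytest
from skimage.draw import disk as draw_disk

from cfsgrade.radiomic_features import (
    FIRST_ORDER_NAMES,
    FORM_NAMES,
    MATRIX_FEATURE_NAMES,
    PER_FORM_NAMES,
    feature_definitions,
    first_order,
    make_forms,
    matrix_features,
    morph_block,
    texture_block,
)
from cfsgrade.stain_segmenter import StainMap
from conftest import stain_map_from_points


def test_count_contract():
    assert len(FIRST_ORDER_NAMES) == 18
    assert len(MATRIX_FEATURE_NAMES) == 75
    assert len(PER_FORM_NAMES) == 93
    assert len(FORM_NAMES) == 9
    rng = np.random.default_rng(0)
    roi = rng.integers(0, 255, (40, 64)).astype(float)
    mask = np.ones((40, 64), bool)
    block = texture_block(roi, mask)
    assert len(block) == 837
    defs = feature_definitions()
    assert len(defs) == 837 + 9 + 128 == 974


def test_nine_forms_canonical_order_and_degenerates():
    flat = np.full((32, 32), 77.0)
    forms = make_forms(flat)
    assert [f.name for f in forms] == list(FORM_NAMES)
    by_name = {f.name: f for f in forms}
    for s in (1, 2, 3):
        # zero up to the truncated-Gaussian kernel residual (~1e-4 relative)
        assert np.abs(by_name[f"log-sigma-{s}"].pixels).max() < 0.05
    for band in ("wavelet-LH", "wavelet-HL", "wavelet-HH"):
        assert np.abs(by_name[band].pixels).max() < 1e-9
    assert np.allclose(by_name["wavelet-LL"].pixels, 2 * 77.0)  # Haar scaling


def test_make_forms_rejects_tiny_roi():
    with pytest.raises(ValueError):
        make_forms(np.zeros((1, 5)))


def test_first_order_constant_region():
    vec = dict(zip(FIRST_ORDER_NAMES, first_order(np.full((10, 10), 42.0), np.ones((10, 10), bool))))
    assert vec["variance"] == 0
    assert vec["skewness"] == 0
    assert vec["kurtosis"] == 0
    assert vec["uniformity"] == 1
    assert vec["mean"] == 42
    assert vec["range"] == 0


def test_first_order_two_value_closed_form():
    img = np.zeros((4, 4))
    img[:, 2:] = 255.0
    vec = dict(zip(FIRST_ORDER_NAMES, first_order(img, np.ones((4, 4), bool))))
    assert vec["mean"] == 127.5
    assert vec["variance"] == 127.5**2
    assert vec["skewness"] == 0
    assert vec["energy"] == 8 * 255.0**2
    assert vec["root_mean_squared"] == pytest.approx(np.sqrt(255.0**2 / 2))


def test_first_order_skewness_matches_moment_formula(rng):
    x = rng.exponential(10.0, (30, 30))  # right-skewed
    vec = dict(zip(FIRST_ORDER_NAMES, first_order(x, np.ones((30, 30), bool))))
    flat = x.ravel()
    m = flat.mean()
    expected = ((flat - m) ** 3).mean() / ((flat - m) ** 2).mean() ** 1.5
    assert vec["skewness"] == pytest.approx(expected)
    assert vec["skewness"] > 0


def test_first_order_rejects_empty_mask():
    with pytest.raises(ValueError):
        first_order(np.zeros((5, 5)), np.zeros((5, 5), bool))


def test_skewness_sits_at_anchor_index_15():
    # the published top-10 list names "texture-4-15" as LoG(sigma 3) skewness
    assert PER_FORM_NAMES[15 - 1] == "skewness"
    assert FORM_NAMES[4 - 1] == "log-sigma-3"
    assert "glszm_large_area_low_gray_level_emphasis" in PER_FORM_NAMES[18:]


def test_glcm_autocorrelation_hand_computed():
    # 4x4 two-level checkerboard-ish worked example, horizontal offset only
    img = np.array(
        [
            [0, 0, 1, 1],
            [0, 0, 1, 1],
            [0, 1, 1, 0],
            [1, 1, 0, 0],
        ],
        dtype=float,
    )
    mask = np.ones((4, 4), bool)
    vec = dict(zip(MATRIX_FEATURE_NAMES, matrix_features(img, mask, bins=2)))
    # hand-built symmetric co-occurrence counts over the 4 directions:
    # with levels {1,2}: autocorrelation = sum_ij i*j*p_ij per direction,
    # computed by explicit pair enumeration below
    def autocorr(offset):
        pairs = []
        H, W = img.shape
        for r in range(H):
            for c in range(W):
                r2, c2 = r + offset[0], c + offset[1]
                if 0 <= r2 < H and 0 <= c2 < W:
                    a, b = img[r, c] + 1, img[r2, c2] + 1
                    pairs += [(a, b), (b, a)]
        return np.mean([a * b for a, b in pairs])

    expected = np.mean([autocorr(o) for o in [(0, 1), (1, 0), (1, 1), (1, -1)]])
    assert vec["glcm_autocorrelation"] == pytest.approx(expected)


def test_glcm_contrast_closed_forms_on_two_level_patterns():
    # direction-averaged contrast of an even checkerboard: horizontal and
    # vertical neighbors always differ by one level, diagonal neighbors never
    # do -> (1 + 1 + 0 + 0) / 4; vertical stripes: (1 + 0 + 1 + 1) / 4
    rr, cc = np.mgrid[0:16, 0:16]
    mask = np.ones((16, 16), bool)
    checker = ((rr + cc) % 2).astype(float)
    v = dict(zip(MATRIX_FEATURE_NAMES, matrix_features(checker, mask, bins=2)))
    assert v["glcm_contrast"] == pytest.approx(0.5)
    stripes = (cc % 2).astype(float)
    v2 = dict(zip(MATRIX_FEATURE_NAMES, matrix_features(stripes, mask, bins=2)))
    assert v2["glcm_contrast"] == pytest.approx(0.75)
    # among same-size two-level images, no pattern beats all-ones contrast 1
    assert v["glcm_contrast"] <= 1.0 and v2["glcm_contrast"] <= 1.0


def test_constant_image_degenerate_matrices_no_nan():
    flat = np.full((20, 20), 9.0)
    mask = np.ones((20, 20), bool)
    vec = matrix_features(flat, mask)
    assert np.isfinite(vec).all()
    named = dict(zip(MATRIX_FEATURE_NAMES, vec))
    # a single gray level means one run per line / one zone overall
    assert named["glrlm_gray_level_nonuniformity_normalized"] == pytest.approx(1.0)
    assert named["glszm_gray_level_nonuniformity_normalized"] == pytest.approx(1.0)


def test_matrix_features_invariant_to_transpose(rng):
    img = rng.normal(size=(24, 24))
    mask = np.ones((24, 24), bool)
    a = matrix_features(img, mask)
    b = matrix_features(img.T, mask.T)
    np.testing.assert_allclose(a, b, rtol=1e-9, atol=1e-9)


def test_first_order_mask_order_invariance(rng):
    img = rng.normal(size=(20, 20))
    mask = rng.random((20, 20)) > 0.4
    base = first_order(img, mask)
    np.testing.assert_allclose(base, first_order(img.copy(order="F"), mask))


def test_morph_disk_circularity_and_counts():
    canvas = np.zeros((80, 80), bool)
    rr, cc = draw_disk((40, 40), 20)
    canvas[rr, cc] = True
    block = morph_block(StainMap.from_mask(canvas))
    assert block["morphology-9"] == 1  # number
    assert 0.9 <= block["morphology-5"] <= 1.1  # near-disk circularity
    assert block["morphology-2"] == pytest.approx(np.pi * 400, rel=0.02)


def test_morph_two_squares_exact():
    canvas = np.zeros((60, 60), bool)
    canvas[5:15, 5:15] = True
    canvas[30:40, 30:40] = True
    block = morph_block(StainMap.from_mask(canvas))
    assert block["morphology-1"] == 100  # mean area
    assert block["morphology-2"] == 200  # total area
    assert block["morphology-9"] == 2
    assert block["morphology-8"] == pytest.approx(1.0, abs=0.05)  # square aspect


def test_morph_empty_map_zeros():
    block = morph_block(StainMap.from_mask(np.zeros((30, 30), bool)))
    assert all(v == 0.0 for v in block.values())
    assert len(block) == 9


def test_morph_elongated_region_low_aspect():
    canvas = np.zeros((40, 80), bool)
    canvas[18:22, 10:70] = True  # 4 x 60 bar
    block = morph_block(StainMap.from_mask(canvas))
    assert block["morphology-8"] < 0.15
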