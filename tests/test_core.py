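"""Unit and property tests for the shared image operations."""

import math

import numpy as np
import pytest
from scipy import ndimage as ndi

from mycovision.core import (
    CalibrationParams,
    ComponentRecord,
    clean_skeleton,
    dilate_3x3,
    filter_components,
    gaussian_background_subtract,
    hysteresis_binarize,
    invert,
    label_and_measure,
    subtract_mask,
    thin_skeleton,
)
from skimage.draw import disk, ellipse


# ---------------------------------------------------------------------------
# CalibrationParams


@pytest.mark.parametrize(
    "kwargs",
    [
        {"b1": 0.3, "b2": 0.5},  # b2 > b1
        {"b1": 1.2},
        {"min_area": 50, "max_area": 10},
        {"elongation_max": 1.5},
        {"gaussian_radius": -1},
        {"min_hyphae": -2},
        {"scale": 0.0},
    ],
)
def test_params_validation_rejects_inconsistent_values(kwargs):
    with pytest.raises(ValueError):
        CalibrationParams(**kwargs)


# ---------------------------------------------------------------------------
# invert


def test_invert_complements_and_is_involutive(rng):
    img = rng.random((16, 16))
    assert np.allclose(invert(img), 1.0 - img)
    assert np.allclose(invert(invert(img)), img)
    assert np.all(invert(np.zeros((3, 3))) == 1.0)


# ---------------------------------------------------------------------------
# gaussian background subtraction


def test_background_subtract_of_uniform_image_is_zero():
    img = np.full((32, 32), 0.6)
    for radius in (1, 5, 20):
        assert np.allclose(gaussian_background_subtract(img, radius), 0.0)


def test_background_subtract_radius_zero_and_negative():
    img = np.random.default_rng(0).random((8, 8))
    assert np.all(gaussian_background_subtract(img, 0) == 0.0)
    with pytest.raises(ValueError):
        gaussian_background_subtract(img, -3)


def test_background_subtract_single_bright_pixel():
    img = np.zeros((21, 21))
    img[10, 10] = 1.0
    out = gaussian_background_subtract(img, 8)
    assert out[10, 10] > 0.5
    assert out[0, 0] < 1e-3


def test_background_subtract_matches_explicit_convolution_oracle():
    """Center of an impulse row equals 1 - normalized kernel center weight.

    Oracle: build the same discrete Gaussian kernel the blur is documented
    to use (sigma = radius/2, support truncated at radius) and convolve by
    hand.
    """
    radius = 2
    sigma = radius / 2.0
    offsets = np.arange(-radius, radius + 1)
    w = np.exp(-(offsets**2) / (2 * sigma**2))
    w = w / w.sum()
    img = np.zeros((5, 5))
    img[2, 2] = 1.0
    # separable 2-D kernel weight at the center is w0^2
    expected_center = 1.0 - w[radius] ** 2
    out = gaussian_background_subtract(img, radius)
    assert out[2, 2] == pytest.approx(expected_center, abs=1e-6)


# ---------------------------------------------------------------------------
# hysteresis binarization


def _bfs_hysteresis_oracle(img, b1, b2):
    """Brute-force flood fill from strong pixels over weak pixels."""
    strong = img > b1
    weak = img > b2
    out = np.zeros_like(weak)
    stack = [tuple(p) for p in np.argwhere(strong)]
    h, w = img.shape
    while stack:
        r, c = stack.pop()
        if out[r, c] or not weak[r, c]:
            continue
        out[r, c] = True
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                rr, cc = r + dr, c + dc
                if 0 <= rr < h and 0 <= cc < w and weak[rr, cc] and not out[rr, cc]:
                    stack.append((rr, cc))
    return out


def test_hysteresis_row_examples():
    row = np.array([[0.9, 0.5, 0.2, 0.5, 0.9]])
    assert hysteresis_binarize(row, 0.8, 0.4).tolist() == [[True, True, False, True, True]]
    row = np.array([[0.0, 0.5, 0.5]])
    assert not hysteresis_binarize(row, 0.8, 0.4).any()


def test_hysteresis_degenerates_to_plain_threshold():
    img = np.random.default_rng(3).random((10, 10))
    t = 0.6
    assert np.array_equal(hysteresis_binarize(img, t, t), img > t)


def test_hysteresis_rejects_inverted_thresholds():
    with pytest.raises(ValueError):
        hysteresis_binarize(np.zeros((3, 3)), 0.3, 0.6)


def test_hysteresis_matches_bfs_oracle_exhaustively():
    """Every 2x4 three-level grid, plus random 4x4 grids, matches a BFS
    flood fill from strong seeds (8-connectivity)."""
    b1, b2 = 0.8, 0.4
    levels = np.array([0.0, 0.5, 0.9])  # below b2 / weak / strong
    for code in range(3**8):
        digits = [(code // 3**k) % 3 for k in range(8)]
        img = levels[np.array(digits)].reshape(2, 4)
        got = hysteresis_binarize(img, b1, b2)
        assert np.array_equal(got, _bfs_hysteresis_oracle(img, b1, b2)), img
    rng = np.random.default_rng(7)
    for _ in range(300):
        img = levels[rng.integers(0, 3, size=(4, 4))]
        got = hysteresis_binarize(img, b1, b2)
        assert np.array_equal(got, _bfs_hysteresis_oracle(img, b1, b2)), img


def test_hysteresis_monotone_in_thresholds(rng):
    img = rng.random((24, 24))
    base = hysteresis_binarize(img, 0.7, 0.4)
    assert np.all(base <= hysteresis_binarize(img, 0.6, 0.4))  # lower b1
    assert np.all(base <= hysteresis_binarize(img, 0.7, 0.3))  # lower b2


# ---------------------------------------------------------------------------
# dilation


def test_dilate_single_pixel_becomes_3x3_block():
    img = np.zeros((5, 5), bool)
    img[2, 2] = True
    out = dilate_3x3(img)
    assert out.sum() == 9
    assert out[1:4, 1:4].all()
    assert not dilate_3x3(np.zeros((4, 4), bool)).any()


def test_dilate_closes_one_pixel_gap():
    img = np.zeros((3, 7), bool)
    img[1, 2] = img[1, 4] = True
    out = dilate_3x3(img)
    _, n = ndi.label(out, structure=np.ones((3, 3)))
    assert n == 1 and out[1, 3]


def test_dilate_is_extensive_and_increasing(rng):
    a = rng.random((20, 20)) > 0.8
    b = a | (rng.random((20, 20)) > 0.8)
    assert np.all(a <= dilate_3x3(a))  # extensive
    assert np.all(dilate_3x3(a) <= dilate_3x3(b))  # increasing


# ---------------------------------------------------------------------------
# thinning


def test_thin_rectangle_to_single_path():
    img = np.zeros((7, 15), bool)
    img[2:5, 2:13] = True  # 3x11 filled rectangle
    sk = thin_skeleton(img)
    # 1-pixel wide: no pixel has a full 2x2 foreground square
    sq = sk[:-1, :-1] & sk[1:, :-1] & sk[:-1, 1:] & sk[1:, 1:]
    assert not sq.any()
    nbrs = ndi.convolve(sk.astype(int), np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]]), mode="constant")
    assert (sk & (nbrs == 1)).sum() == 2  # exactly two endpoints
    _, n = ndi.label(sk, structure=np.ones((3, 3)))
    assert n == 1


def test_thin_preserves_component_count(rng):
    img = np.zeros((60, 60), bool)
    rr, cc = disk((15, 15), 8)
    img[rr, cc] = True
    rr, cc = disk((45, 45), 6)
    img[rr, cc] = True
    img[30, 5:25] = True
    _, n_in = ndi.label(img, structure=np.ones((3, 3)))
    sk = thin_skeleton(img)
    _, n_out = ndi.label(sk, structure=np.ones((3, 3)))
    assert n_in == n_out == 3


def test_thin_leaves_thin_line_unchanged():
    img = np.zeros((5, 12), bool)
    img[2, 1:11] = True
    assert np.array_equal(thin_skeleton(img), img)
    assert not thin_skeleton(np.zeros((4, 4), bool)).any()


# ---------------------------------------------------------------------------
# skeleton cleaning


def _y_skeleton(short_arm=3):
    sk = np.zeros((50, 50), bool)
    sk[25, 25] = True
    for i in range(1, 21):
        sk[25, 25 - i] = True
        sk[25, 25 + i] = True
    for i in range(1, short_arm + 1):
        sk[25 - i, 25] = True
    return sk


def test_clean_removes_small_components():
    sk = np.zeros((20, 20), bool)
    sk[5, 3:8] = True  # 5-pixel path
    assert not clean_skeleton(sk, 10).any()
    assert np.array_equal(clean_skeleton(sk, 5), sk)  # exactly at size -> kept


def test_clean_prunes_short_branch_back_to_junction():
    sk = _y_skeleton(short_arm=3)
    out = clean_skeleton(sk, 5)
    # the short arm's free pixels are gone (at most one pixel of it may
    # survive as part of the 8-connected junction cluster)
    assert not out[21:24, 25].any()
    nbrs = ndi.convolve(out.astype(int), np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]]), mode="constant")
    assert (out & (nbrs == 1)).sum() == 2  # two endpoints remain
    assert sk.sum() - out.sum() >= 2


def test_clean_is_identity_at_zero_and_never_grows(rng):
    sk = thin_skeleton(rng.random((40, 40)) > 0.7)
    assert np.array_equal(clean_skeleton(sk, 0), sk)
    cleaned = clean_skeleton(sk, 6)
    assert cleaned.sum() <= sk.sum()
    assert not (cleaned & ~sk).any()


def test_clean_is_idempotent(rng):
    sk = thin_skeleton(rng.random((50, 50)) > 0.75)
    once = clean_skeleton(sk, 8)
    assert np.array_equal(clean_skeleton(once, 8), once)


# ---------------------------------------------------------------------------
# mask subtraction


def test_subtract_mask_extremes_and_mismatch(rng):
    img = rng.random((10, 10)) > 0.5
    assert not subtract_mask(img, np.ones((10, 10), bool)).any()
    assert np.array_equal(subtract_mask(img, np.zeros((10, 10), bool)), img)
    with pytest.raises(ValueError):
        subtract_mask(img, np.zeros((5, 5), bool))


def test_subtract_mask_border_ring():
    img = np.ones((8, 8), bool)
    ring = np.ones((8, 8), bool)
    ring[1:-1, 1:-1] = False
    out = subtract_mask(img, ring)
    assert out.sum() == 36 and out[1:-1, 1:-1].all()


# ---------------------------------------------------------------------------
# component measurement


def test_measure_rasterized_disk():
    img = np.zeros((64, 64), bool)
    rr, cc = disk((32, 32), 20)
    img[rr, cc] = True
    (rec,) = label_and_measure(img)
    assert rec.area_px == pytest.approx(math.pi * 400, rel=0.02)
    assert rec.circularity >= 0.95
    assert rec.elongation <= 0.05
    assert rec.centroid == pytest.approx((32, 32), abs=0.5)


def test_measure_rasterized_ellipse_axes():
    img = np.zeros((128, 128), bool)
    rr, cc = ellipse(64, 64, 40, 10)
    img[rr, cc] = True
    (rec,) = label_and_measure(img)
    assert rec.major_axis_px == pytest.approx(80, rel=0.05)
    assert rec.minor_axis_px == pytest.approx(20, rel=0.05)
    assert rec.elongation == pytest.approx(0.75, abs=0.05)
    assert rec.minor_axis_px <= rec.major_axis_px


def test_measure_empty_image_and_circularity_decreases_with_axis_ratio():
    assert label_and_measure(np.zeros((10, 10), bool)) == []
    circs = []
    for a, b in [(20, 20), (40, 10), (80, 5)]:
        img = np.zeros((200, 200), bool)
        rr, cc = ellipse(100, 100, a, b)
        img[rr, cc] = True
        circs.append(label_and_measure(img)[0].circularity)
    assert circs[0] > circs[1] > circs[2]


# ---------------------------------------------------------------------------
# component filtering


def _rec(area, elo):
    return ComponentRecord(1, area, 10.0, 5.0, 5.0 * (1 - elo), elo, 0.9, (0, 0))


def test_filter_gates_are_closed_intervals():
    p = CalibrationParams(min_area=10, max_area=100, elongation_max=0.6)
    assert filter_components([_rec(3, 0.1)], p) == []  # below floor
    assert filter_components([_rec(50, 0.9)], p) == []  # hypha-like
    at_bounds = [_rec(10, 0.6), _rec(100, 0.0)]
    assert filter_components(at_bounds, p) == at_bounds  # bounds admissible


def test_filter_is_subset_preserving_and_idempotent(rng):
    p = CalibrationParams(min_area=20, max_area=200, elongation_max=0.5)
    recs = [_rec(float(a), float(e)) for a, e in zip(rng.integers(1, 300, 50), rng.random(50))]
    kept = filter_components(recs, p)
    assert all(r in recs for r in kept)
    assert [recs.index(r) for r in kept] == sorted(recs.index(r) for r in kept)
    assert filter_components(kept, p) == kept
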