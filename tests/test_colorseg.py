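"""Unit tests for the multi-colour-space segmentation pipeline, checked
against independent oracles (closed-form colorimetry, brute-force loops,
alternative morphology implementations)."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import ndimage as ndi

from tgsr.colorseg import (ELLIPSE_5X5, PreprocessParams, clahe8, enhance_ab,
                           filter_small, fuse_masks, hsv_mask, lab_mask,
                           paint_features, preprocess, refine_mask, to_hsv8,
                           to_lab8)
from tgsr.synth import make_leaf_image


# ---------------------------------------------------------------------------
# colour conversions, against closed-form sRGB -> XYZ -> Lab / HSV oracles
# ---------------------------------------------------------------------------

def _lab_oracle(rgb):
    """Independent CIE Lab (D65, 2 deg) via the standard sRGB formulas."""
    rgb = np.asarray(rgb, dtype=np.float64) / 255.0
    lin = np.where(rgb <= 0.04045, rgb / 12.92,
                   ((rgb + 0.055) / 1.055) ** 2.4)
    m = np.array([[0.4124564, 0.3575761, 0.1804375],
                  [0.2126729, 0.7151522, 0.0721750],
                  [0.0193339, 0.1191920, 0.9503041]])
    xyz = m @ lin
    white = np.array([0.95047, 1.0, 1.08883])
    t = xyz / white
    f = np.where(t > (6 / 29) ** 3, np.cbrt(t),
                 t / (3 * (6 / 29) ** 2) + 4 / 29)
    L = 116 * f[1] - 16
    return L, 500 * (f[0] - f[1]), 200 * (f[1] - f[2])


def _hsv_oracle(rgb):
    r, g, b = (v / 255.0 for v in rgb)
    mx, mn = max(r, g, b), min(r, g, b)
    d = mx - mn
    if d == 0:
        h = 0.0
    elif mx == r:
        h = (60 * ((g - b) / d)) % 360
    elif mx == g:
        h = 60 * ((b - r) / d) + 120
    else:
        h = 60 * ((r - g) / d) + 240
    s = 0.0 if mx == 0 else d / mx
    return h, s, mx


@pytest.mark.parametrize("rgb", [(150, 90, 40), (128, 128, 128),
                                 (30, 30, 30), (60, 140, 60), (200, 30, 10)])
def test_lab8_matches_colorimetry_oracle(rgb):
    L, a, b = _lab_oracle(rgb)
    expect = (L * 255 / 100, a + 128, b + 128)
    got = to_lab8(np.array(rgb, np.uint8).reshape(1, 1, 3))[0, 0]
    assert np.allclose(got, expect, atol=1.0)


def test_lab8_named_values():
    # mid-gray is achromatic: a* = b* = 0 -> encoded 128
    gray = to_lab8(np.full((1, 1, 3), 128, np.uint8))[0, 0]
    assert gray[1] == 128 and gray[2] == 128
    # the canonical brown example sits above both gates
    brown = to_lab8(np.array([[[150, 90, 40]]], np.uint8))[0, 0]
    assert abs(int(brown[1]) - 148) <= 1
    assert abs(int(brown[2]) - 167) <= 2


def test_lab8_roundtrip_quantisation_bound(rng):
    from skimage import color as skcolor
    pixels = rng.integers(0, 256, (1000, 1, 3)).astype(np.uint8)
    lab8 = to_lab8(pixels)
    # decode the 8-bit encoding back to float Lab, then to RGB and re-encode
    lab = np.empty(lab8.shape, np.float64)
    lab[..., 0] = lab8[..., 0] * 100.0 / 255.0
    lab[..., 1] = lab8[..., 1].astype(float) - 128.0
    lab[..., 2] = lab8[..., 2].astype(float) - 128.0
    rgb = np.clip(np.rint(skcolor.lab2rgb(lab) * 255), 0, 255).astype(np.uint8)
    lab8_again = to_lab8(rgb)
    assert np.abs(lab8.astype(int) - lab8_again.astype(int)).max() <= 2


@pytest.mark.parametrize("rgb", [(150, 90, 40), (0, 255, 0), (40, 40, 40),
                                 (255, 128, 0), (13, 77, 200)])
def test_hsv8_matches_oracle(rgb):
    h, s, v = _hsv_oracle(rgb)
    got = to_hsv8(np.array(rgb, np.uint8).reshape(1, 1, 3))[0, 0]
    assert abs(int(got[0]) - round(h / 2) % 180) <= 1
    assert abs(int(got[1]) - round(s * 255)) <= 1
    assert abs(int(got[2]) - round(v * 255)) <= 1


# ---------------------------------------------------------------------------
# CLAHE
# ---------------------------------------------------------------------------

def test_clahe_constant_channel_near_identity():
    """With no contrast to stretch the clipped mapping is near-identity."""
    for c in (60, 120, 128, 135, 200):
        ch = np.full((448, 448), c, np.uint8)
        out = clahe8(ch)
        assert np.abs(out.astype(int) - c).max() <= 2


def test_enhance_ab_contract(params, rng):
    lab = rng.integers(0, 256, (96, 96, 3)).astype(np.uint8)
    out = enhance_ab(lab, params)
    assert np.array_equal(out[..., 0], lab[..., 0])      # L untouched
    # deterministic
    assert np.array_equal(out, enhance_ab(lab, params))


def test_enhance_ab_stretches_sparse_region_contrast(params):
    """A sparse brighter a-region (135 on a 120 background, the brown-spot
    regime) gains contrast against the background after equalisation."""
    lab = np.full((128, 128, 3), 128, np.uint8)
    lab[..., 1] = 120
    lab[40:52, 40:52, 1] = 135
    out = enhance_ab(lab, params)
    pre = 135 - 120
    post = out[44:48, 44:48, 1].mean() - out[:16, :16, 1].mean()
    assert post >= pre


# ---------------------------------------------------------------------------
# masks
# ---------------------------------------------------------------------------

def test_lab_mask_strict_thresholds(params):
    lab = np.zeros((1, 3, 3), np.uint8)
    lab[0, :, 1] = [148, 130, 131]
    lab[0, :, 2] = [168, 168, 120]
    m = lab_mask(lab.transpose(1, 0, 2).reshape(1, 3, 3), params)
    # (a=148,b=168) passes; (a=130,.) fails the strict a gate;
    # (a=131,b=120) fails the strict b gate
    assert list(m[0]) == [255, 0, 0]


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 2 ** 31 - 1))
def test_lab_mask_matches_double_loop_oracle(seed):
    rng = np.random.default_rng(seed)
    lab = rng.integers(0, 256, (8, 9, 3)).astype(np.uint8)
    p = PreprocessParams()
    m = lab_mask(lab, p)
    for i in range(8):
        for j in range(9):
            expect = 255 if (lab[i, j, 1] > 130 and lab[i, j, 2] > 120) else 0
            assert m[i, j] == expect


def test_hsv_mask_examples(params):
    img = np.array([[(150, 90, 40), (0, 255, 0), (40, 40, 40)]], np.uint8)
    m = hsv_mask(img, params)
    assert list(m[0]) == [255, 0, 0]   # brown in-gate; green hue out; S=0


def test_fuse_masks_properties(rng):
    a = rng.integers(0, 2, (31, 17)).astype(np.uint8) * 255
    b = rng.integers(0, 2, (31, 17)).astype(np.uint8) * 255
    f = fuse_masks(a, b)
    assert np.array_equal(f, np.minimum(a, b))
    assert (f <= a).all() and (f <= b).all()
    assert np.array_equal(fuse_masks(a, np.zeros_like(a)), np.zeros_like(a))
    full = np.full_like(a, 255)
    assert np.array_equal(fuse_masks(full, full), full)
    with pytest.raises(ValueError):
        fuse_masks(a, a[:-1])


# ---------------------------------------------------------------------------
# morphology and area filtering
# ---------------------------------------------------------------------------

def test_refine_mask_fills_holes_and_removes_specks(params):
    m = np.zeros((40, 40), np.uint8)
    m[5:25, 5:25] = 255
    m[12, 12] = 0                     # 1-px interior hole
    m[35, 35] = 255                   # isolated pixel
    out = refine_mask(m, params)
    assert out[12, 12] == 255         # closing filled the hole
    assert out[35, 35] == 0           # opening removed the speck
    assert set(np.unique(out)) <= {0, 255}
    # body preserved (the elliptical element may round the sharp corners)
    assert (out[7:23, 7:23] == 255).all()
    assert ((out > 0) <= ndi.binary_dilation(m > 0, ELLIPSE_5X5)).all()


def test_refine_mask_matches_independent_morphology(params, rng):
    """Interior-only content: compare against skimage's closing/opening."""
    from skimage.morphology import closing, opening
    m = np.zeros((64, 64), bool)
    blob = rng.random((40, 40)) > 0.45
    m[12:52, 12:52] = blob
    ours = refine_mask(m.astype(np.uint8) * 255, params) > 0
    ref = opening(closing(m, ELLIPSE_5X5), ELLIPSE_5X5)
    assert np.array_equal(ours, ref)


def _flood_areas(mask):
    """Brute-force 8-connected component areas (iterative flood fill)."""
    seen = np.zeros_like(mask, bool)
    areas = []
    h, w = mask.shape
    for si in range(h):
        for sj in range(w):
            if mask[si, sj] and not seen[si, sj]:
                stack, area = [(si, sj)], 0
                seen[si, sj] = True
                while stack:
                    i, j = stack.pop()
                    area += 1
                    for di in (-1, 0, 1):
                        for dj in (-1, 0, 1):
                            ni, nj = i + di, j + dj
                            if (0 <= ni < h and 0 <= nj < w
                                    and mask[ni, nj] and not seen[ni, nj]):
                                seen[ni, nj] = True
                                stack.append((ni, nj))
                areas.append(area)
    return sorted(areas)


def test_filter_small_area_boundaries(params):
    # 10x10 = 100 px survives; 9x9 = 81 px does not
    m = np.zeros((30, 30), np.uint8)
    m[2:12, 2:12] = 255
    assert np.array_equal(filter_small(m, params), m)
    m2 = np.zeros((30, 30), np.uint8)
    m2[2:11, 2:11] = 255
    assert filter_small(m2, params).sum() == 0


def test_filter_small_component_selection(params):
    """Components of 50/99/100/400 px: exactly the last two survive."""
    m = np.zeros((60, 120), np.uint8)
    m[2:7, 2:12] = 255                       # 50
    m[20:29, 2:13] = 255                     # 9 x 11 = 99
    assert (m[20:29, 2:13] > 0).sum() == 99
    m[40:50, 2:12] = 255                     # 100
    m[2:22, 60:80] = 255                     # 400
    out = filter_small(m, params)
    assert _flood_areas(out > 0) == [100, 400]
    assert ((out > 0) <= (m > 0)).all()


def test_filter_small_uses_filled_area(params):
    """Area is measured with interior holes filled; holes are kept verbatim."""
    m = np.zeros((40, 40), np.uint8)
    m[5:16, 5:16] = 255               # 121 px ring+core
    m[8:13, 8:13] = 0                 # 25-px hole -> raw 96, filled 121
    out = filter_small(m, params)
    assert np.array_equal(out, m)     # survives thanks to the filled area


# ---------------------------------------------------------------------------
# painting and full pipeline
# ---------------------------------------------------------------------------

def test_paint_features_exact_and_idempotent(params, rng):
    img = rng.integers(0, 256, (20, 20, 3)).astype(np.uint8)
    m = (rng.random((20, 20)) > 0.7).astype(np.uint8) * 255
    out = paint_features(img, m, params)
    assert (out[m == 255] == (255, 0, 0)).all()
    assert np.array_equal(out[m == 0], img[m == 0])
    assert np.array_equal(paint_features(out, m, params), out)
    assert np.array_equal(paint_features(img, np.zeros_like(m), params), img)
    with pytest.raises(ValueError):
        paint_features(img, m[:-1], params)


def test_preprocess_containment_and_determinism(params, stage_specs):
    """final mask is contained in the fused mask dilated by the element."""
    img, _ = make_leaf_image(stage_specs[5], seed=4)
    painted1, final1 = preprocess(img, params)
    painted2, final2 = preprocess(img, params)
    assert np.array_equal(painted1, painted2)
    assert np.array_equal(final1, final2)

    lm = lab_mask(enhance_ab(to_lab8(img), params), params)
    hm = hsv_mask(img, params)
    fused = fuse_masks(lm, hm)
    dilated = ndi.binary_dilation(fused > 0, ELLIPSE_5X5)
    assert ((final1 > 0) <= dilated).all()


def test_preprocess_no_gate_hits_is_identity(params):
    """An image with no pixel passing both gates is returned unchanged."""
    img = np.zeros((64, 64, 3), np.uint8)
    img[:] = (30, 30, 30)
    img[10:30, 10:30] = (60, 140, 60)        # green blob: hue out of gate
    painted, final = preprocess(img, params)
    assert final.sum() == 0
    assert np.array_equal(painted, img)
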