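"""Multi-colour-space browning segmentation for green-making leaf images.

The pipeline isolates oxidative browning (brown spots on petioles and
blades, reddened leaf margins) and repaints it pure red so downstream
classifiers see an enhanced, colour-separable cue.  Seven steps:

1. convert RGB to 8-bit Lab (D65);
2. CLAHE on the a and b channels only;
3. threshold the enhanced a and b channels (strictly above ``a_threshold``
   and ``b_threshold``) into a Lab mask;
4. threshold the *original* image in 8-bit HSV with inclusive gates on
   hue, saturation and value;
5. fuse the two masks with a pixel-wise AND;
6. refine with a morphological closing then opening (5x5 elliptical
   element) and drop connected components whose filled area is below
   ``min_area``;
7. repaint the masked pixels of the original image with ``paint_rgb``.

All stages are pure functions of (image, parameters); running twice gives
identical bytes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import color as skcolor

__all__ = [
    "PreprocessParams", "ELLIPSE_5X5", "to_lab8", "to_hsv8", "clahe8",
    "enhance_ab", "lab_mask", "hsv_mask", "fuse_masks", "refine_mask",
    "filter_small", "paint_features", "preprocess",
]

# 5x5 elliptical structuring element (the standard discrete ellipse used by
# morphology toolkits: full middle rows, single-pixel caps).
ELLIPSE_5X5 = np.array([
    [0, 0, 1, 0, 0],
    [1, 1, 1, 1, 1],
    [1, 1, 1, 1, 1],
    [1, 1, 1, 1, 1],
    [0, 0, 1, 0, 0],
], dtype=bool)


@dataclass(frozen=True)
class PreprocessParams:
    """Thresholds and structuring parameters of the segmentation pipeline.

    ``a_threshold``/``b_threshold`` act on the 8-bit Lab encoding (a and b
    offset by +128), ``h_range`` on the halved hue scale [0, 179].  The
    per-channel Lab binarisations combine with AND by default (browning is
    simultaneously red- and yellow-shifted); ``lab_gate_mode='or'`` is
    available for sensitivity studies.
    """

    a_threshold: int = 130
    b_threshold: int = 120
    h_range: tuple[int, int] = (10, 30)
    s_range: tuple[int, int] = (50, 255)
    v_range: tuple[int, int] = (50, 255)
    clahe_clip_limit: float = 2.0
    clahe_tile_grid: tuple[int, int] = (8, 8)
    min_area: int = 100
    paint_rgb: tuple[int, int, int] = (255, 0, 0)
    lab_gate_mode: str = "and"
    struct_elem: np.ndarray = field(default_factory=lambda: ELLIPSE_5X5,
                                    repr=False, compare=False)

    def __post_init__(self):
        for name in ("a_threshold", "b_threshold"):
            v = getattr(self, name)
            if not 0 <= v <= 255:
                raise ValueError(f"{name}={v} outside 8-bit range")
        for name in ("h_range", "s_range", "v_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} is not well-ordered: {(lo, hi)}")
        if self.min_area < 0:
            raise ValueError("min_area must be >= 0")
        if self.lab_gate_mode not in ("and", "or"):
            raise ValueError("lab_gate_mode must be 'and' or 'or'")


def _check_rgb8(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected HxWx3 RGB image, got shape {img.shape}")
    return img


def _check_mask(m: np.ndarray) -> np.ndarray:
    m = np.asarray(m)
    if m.ndim != 2:
        raise ValueError(f"expected HxW mask, got shape {m.shape}")
    return m


def to_lab8(img: np.ndarray) -> np.ndarray:
    """8-bit CIE Lab (D65): L scaled to [0,255], a and b offset by +128."""
    img = _check_rgb8(img)
    lab = skcolor.rgb2lab(img.astype(np.float64) / 255.0)
    out = np.empty_like(lab)
    out[..., 0] = lab[..., 0] * 255.0 / 100.0
    out[..., 1] = lab[..., 1] + 128.0
    out[..., 2] = lab[..., 2] + 128.0
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def to_hsv8(img: np.ndarray) -> np.ndarray:
    """8-bit HSV: hue halved to [0,179], S and V scaled to [0,255]."""
    img = _check_rgb8(img)
    hsv = skcolor.rgb2hsv(img.astype(np.float64) / 255.0)
    out = np.empty_like(hsv)
    out[..., 0] = np.rint(hsv[..., 0] * 180.0) % 180
    out[..., 1] = np.rint(hsv[..., 1] * 255.0)
    out[..., 2] = np.rint(hsv[..., 2] * 255.0)
    return out.astype(np.uint8)


def clahe8(channel: np.ndarray, clip_limit: float = 2.0,
           tile_grid: tuple[int, int] = (8, 8)) -> np.ndarray:
    """Contrast-limited adaptive histogram equalisation of a uint8 channel.

    Per-tile histograms are clipped at ``clip_limit`` times the uniform bin
    height, the excess is redistributed evenly, and the per-tile mapping
    functions are blended bilinearly between tile centres (the classical
    CLAHE formulation for integer images).
    """
    channel = np.asarray(channel)
    if channel.ndim != 2 or channel.dtype != np.uint8:
        raise ValueError("clahe8 expects a 2-D uint8 channel")
    h, w = channel.shape
    gy, gx = tile_grid
    th, tw = -(-h // gy), -(-w // gx)          # ceil tile size
    pad_y, pad_x = th * gy - h, tw * gx - w
    padded = np.pad(channel, ((0, pad_y), (0, pad_x)), mode="reflect") \
        if (pad_y or pad_x) else channel

    area = th * tw
    clip = max(int(clip_limit * area / 256.0), 1)
    tiles = padded.reshape(gy, th, gx, tw).transpose(0, 2, 1, 3)
    luts = np.empty((gy, gx, 256), dtype=np.float64)
    scale = 255.0 / area
    for i in range(gy):
        for j in range(gx):
            hist = np.bincount(tiles[i, j].ravel(), minlength=256)
            excess = int(np.maximum(hist - clip, 0).sum())
            hist = np.minimum(hist, clip)
            hist += excess // 256
            residual = excess % 256
            if residual:
                step = max(256 // residual, 1)
                hist[::step][:residual] += 1
            luts[i, j] = np.rint(np.cumsum(hist) * scale)

    yy = (np.arange(h) + 0.5) / th - 0.5
    xx = (np.arange(w) + 0.5) / tw - 0.5
    y0 = np.clip(np.floor(yy).astype(int), 0, gy - 1)
    x0 = np.clip(np.floor(xx).astype(int), 0, gx - 1)
    y1 = np.minimum(y0 + 1, gy - 1)
    x1 = np.minimum(x0 + 1, gx - 1)
    fy = np.clip(yy - y0, 0.0, 1.0)[:, None]
    fx = np.clip(xx - x0, 0.0, 1.0)[None, :]

    v = channel.astype(int)
    g00 = luts[y0[:, None], x0[None, :], v]
    g01 = luts[y0[:, None], x1[None, :], v]
    g10 = luts[y1[:, None], x0[None, :], v]
    g11 = luts[y1[:, None], x1[None, :], v]
    out = ((1 - fy) * ((1 - fx) * g00 + fx * g01)
           + fy * ((1 - fx) * g10 + fx * g11))
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def enhance_ab(lab: np.ndarray, params: PreprocessParams) -> np.ndarray:
    """CLAHE on the a and b channels; L is passed through untouched."""
    lab = np.asarray(lab)
    if lab.ndim != 3 or lab.shape[2] != 3:
        raise ValueError(f"expected HxWx3 Lab image, got {lab.shape}")
    out = lab.copy()
    for c in (1, 2):
        out[..., c] = clahe8(lab[..., c], params.clahe_clip_limit,
                             params.clahe_tile_grid)
    return out


def lab_mask(lab_enhanced: np.ndarray, params: PreprocessParams) -> np.ndarray:
    """Binarise the enhanced a/b channels; strictly-above thresholds."""
    a = lab_enhanced[..., 1].astype(int)
    b = lab_enhanced[..., 2].astype(int)
    if params.lab_gate_mode == "and":
        hit = (a > params.a_threshold) & (b > params.b_threshold)
    else:
        hit = (a > params.a_threshold) | (b > params.b_threshold)
    return hit.astype(np.uint8) * 255


def hsv_mask(img: np.ndarray, params: PreprocessParams) -> np.ndarray:
    """Inclusive HSV gate on the original (unenhanced) image."""
    hsv = to_hsv8(img).astype(int)
    hit = np.ones(hsv.shape[:2], dtype=bool)
    for c, (lo, hi) in enumerate((params.h_range, params.s_range,
                                  params.v_range)):
        hit &= (hsv[..., c] >= lo) & (hsv[..., c] <= hi)
    return hit.astype(np.uint8) * 255


def fuse_masks(lab_m: np.ndarray, hsv_m: np.ndarray) -> np.ndarray:
    """Pixel-wise AND of two {0,255} masks."""
    lab_m, hsv_m = _check_mask(lab_m), _check_mask(hsv_m)
    if lab_m.shape != hsv_m.shape:
        raise ValueError(
            f"mask shapes differ: {lab_m.shape} vs {hsv_m.shape}")
    return np.minimum(lab_m, hsv_m)


def refine_mask(m: np.ndarray, params: PreprocessParams) -> np.ndarray:
    """Morphological closing then opening with the elliptical element.

    Dilations treat the outside as background and erosions as foreground
    (the replicate-border convention), so shapes at the image edge are not
    eaten by the border.
    """
    fg = _check_mask(m) > 0
    se = params.struct_elem
    closed = ndi.binary_erosion(ndi.binary_dilation(fg, se), se,
                                border_value=1)
    opened = ndi.binary_dilation(ndi.binary_erosion(closed, se,
                                                    border_value=1), se)
    return opened.astype(np.uint8) * 255


def filter_small(m: np.ndarray, params: PreprocessParams) -> np.ndarray:
    """Drop 8-connected components whose hole-filled area < ``min_area``.

    Area is the pixel count of the component with interior holes filled
    (the area its external contour encloses); surviving components are kept
    verbatim, holes included.
    """
    fg = _check_mask(m) > 0
    filled = ndi.binary_fill_holes(fg)
    labels, n = ndi.label(filled, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return np.zeros_like(m, dtype=np.uint8)
    areas = np.bincount(labels.ravel())
    keep = areas >= params.min_area
    keep[0] = False
    return (fg & keep[labels]).astype(np.uint8) * 255


def paint_features(img: np.ndarray, m: np.ndarray,
                   params: PreprocessParams) -> np.ndarray:
    """Repaint masked pixels of the original image with ``paint_rgb``."""
    img, m = _check_rgb8(img), _check_mask(m)
    if img.shape[:2] != m.shape:
        raise ValueError(
            f"image {img.shape[:2]} and mask {m.shape} shapes differ")
    out = img.copy()
    out[m == 255] = params.paint_rgb
    return out


def preprocess(img: np.ndarray, params: PreprocessParams | None = None
               ) -> tuple[np.ndarray, np.ndarray]:
    """Full seven-step pipeline; returns (painted image, final mask)."""
    params = params or PreprocessParams()
    img = _check_rgb8(img)
    lab = to_lab8(img)
    enhanced = enhance_ab(lab, params)
    lm = lab_mask(enhanced, params)
    hm = hsv_mask(img, params)
    fused = fuse_masks(lm, hm)
    refined = refine_mask(fused, params)
    final = filter_small(refined, params)
    return paint_features(img, final, params), final
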