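"""Synthetic six-stage green-making leaf images with known browning masks.

The real imagery behind this task is not publicly deposited, so the package
ships a generator that emulates the qualitative progression of the
green-making (ZuoQing) process: green elliptical leaf blades with petiole
strokes on a dark acquisition-box background; from stage 3 onward brown
spots appear and multiply; from stage 4 onward the leaf margins develop a
reddish-brown "red edge" band that widens with stage.  Every brown pixel
uses a colour pre-validated to sit inside the segmentation pipeline's Lab
and HSV gates with margin, and the generator records the exact pixel-level
ground truth, so segmentation quality is measurable without real data.

The generator aims at exercising the pipeline and classifier, not at
photorealism: no venation, no specular gloss, no wilting geometry.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage as ndi
from skimage import draw as skdraw

from .colorseg import PreprocessParams, to_hsv8, to_lab8

__all__ = [
    "StageSpec", "GroundTruth", "validate_brown_color", "DEFAULT_BROWN_GAMUT",
    "default_stage_specs", "make_leaf_image", "make_dataset",
    "read_manifest", "write_manifest",
]


@dataclass(frozen=True)
class StageSpec:
    """Generative parameters of one green-making stage."""

    stage: int
    n_leaves: int = 5
    leaf_hue_range: tuple[float, float] = (100.0, 140.0)   # degrees
    spot_count_range: tuple[int, int] = (0, 0)
    spot_radius_range: tuple[int, int] = (6, 10)            # pixels
    edge_band_width: int = 0                                # pixels
    brown_gamut: tuple[tuple[int, int, int], ...] = ()
    background_rgb: tuple[int, int, int] = (30, 30, 30)
    image_size: tuple[int, int] = (448, 448)

    def __post_init__(self):
        if not 1 <= self.stage <= 6:
            raise ValueError(f"stage must be 1-6, got {self.stage}")
        lo, hi = self.spot_count_range
        if lo > hi or lo < 0:
            raise ValueError(f"bad spot_count_range {self.spot_count_range}")
        lo, hi = self.spot_radius_range
        if lo > hi or lo < 1:
            raise ValueError(f"bad spot_radius_range {self.spot_radius_range}")
        if self.edge_band_width < 0:
            raise ValueError("edge_band_width must be >= 0")


@dataclass
class GroundTruth:
    """Pixel-exact record of what the generator painted."""

    stage_label: int
    brown_mask: np.ndarray          # {0,255}, spots + edge bands
    leaf_mask: np.ndarray           # {0,255}, blades + petioles
    spots: tuple[tuple[int, int, int], ...] = ()   # (row, col, radius)


def validate_brown_color(rgb: tuple[int, int, int],
                         params: PreprocessParams | None = None,
                         *, margin: int = 0) -> bool:
    """True iff a 1x1 image of ``rgb`` passes the Lab gate (8-bit encoding,
    no CLAHE) and the HSV gate, each by at least ``margin`` units.

    Margins apply only to bounds that are not already at a channel's
    physical extreme (a range ending at 255 or starting at 0 cannot be
    crossed, so no margin is demanded there).
    """
    params = params or PreprocessParams()
    rgb = tuple(int(v) for v in rgb)
    if not all(0 <= v <= 255 for v in rgb):
        raise ValueError(f"RGB components outside [0,255]: {rgb}")
    px = np.array(rgb, dtype=np.uint8).reshape(1, 1, 3)
    lab = to_lab8(px)[0, 0].astype(int)
    hsv = to_hsv8(px)[0, 0].astype(int)
    if not (lab[1] > params.a_threshold + margin
            and lab[2] > params.b_threshold + margin):
        return False
    for value, (lo, hi), full in ((hsv[0], params.h_range, 179),
                                  (hsv[1], params.s_range, 255),
                                  (hsv[2], params.v_range, 255)):
        lo_eff = lo + margin if lo > 0 else lo
        hi_eff = hi - margin if hi < full else hi
        if not lo_eff <= value <= hi_eff:
            return False
    return True


# Browns spanning light/dark oxidation tones; each passes both gates with
# >= 5 units of slack per thresholded channel (asserted below) so CLAHE's
# monotone per-tile remapping cannot push a planted pixel out of a gate.
DEFAULT_BROWN_GAMUT: tuple[tuple[int, int, int], ...] = (
    (130, 95, 30), (140, 100, 45), (150, 100, 30),
    (155, 110, 55), (170, 130, 80), (185, 130, 65),
)

GAMUT_MARGIN = 5

# (n_leaves, spot_count_range, edge_band_width) per stage.  Spot counts and
# edge widths are non-decreasing: browning accumulates as shaking/cooling
# cycles proceed.  Stages 1-2 are unbrowned (stage 2 at most one incipient
# spot); spots appear at stage 3, margins redden from stage 4.
_STAGE_TABLE = {
    1: (5, (0, 0), 0),
    2: (5, (0, 1), 0),
    3: (5, (3, 6), 0),
    4: (5, (6, 10), 3),
    5: (5, (10, 14), 6),
    6: (5, (14, 20), 9),
}


def default_stage_specs(image_size: tuple[int, int] = (448, 448),
                        params: PreprocessParams | None = None
                        ) -> list[StageSpec]:
    """The six default stage specifications (validated)."""
    params = params or PreprocessParams()
    for rgb in DEFAULT_BROWN_GAMUT:
        if not validate_brown_color(rgb, params, margin=GAMUT_MARGIN):
            raise AssertionError(
                f"brown gamut colour {rgb} lost its gate margin")
    specs = [
        StageSpec(stage=s, n_leaves=n, spot_count_range=spots,
                  edge_band_width=edge, brown_gamut=DEFAULT_BROWN_GAMUT,
                  image_size=image_size)
        for s, (n, spots, edge) in _STAGE_TABLE.items()
    ]
    for prev, cur in zip(specs, specs[1:]):
        assert cur.spot_count_range >= prev.spot_count_range
        assert cur.edge_band_width >= prev.edge_band_width
    return specs


def _hsv_to_rgb(h_deg: float, s: float, v: float) -> np.ndarray:
    """Single-colour HSV->RGB (h in degrees), returned as float in [0,1]."""
    h = (h_deg % 360.0) / 60.0
    i = int(h) % 6
    f = h - int(h)
    p, q, t = v * (1 - s), v * (1 - s * f), v * (1 - s * (1 - f))
    rgb = [(v, t, p), (q, v, p), (p, v, t), (p, q, v), (t, p, v), (v, p, q)][i]
    return np.array(rgb)


def make_leaf_image(spec: StageSpec, seed: int
                    ) -> tuple[np.ndarray, GroundTruth]:
    """Render one synthetic leaf image plus its ground truth.

    Deterministic for fixed (spec, seed).  Raises ``ValueError`` naming the
    offending field when a spot cannot be placed inside any blade.
    """
    rng = np.random.default_rng(seed)
    h, w = spec.image_size
    img = np.empty((h, w, 3), dtype=np.uint8)
    img[:] = spec.background_rgb

    blades = np.zeros((h, w), dtype=bool)
    petioles = np.zeros((h, w), dtype=bool)
    for _ in range(spec.n_leaves):
        cy = rng.uniform(0.2 * h, 0.8 * h)
        cx = rng.uniform(0.2 * w, 0.8 * w)
        ry = rng.uniform(0.10 * h, 0.16 * h)
        rx = rng.uniform(0.045 * w, 0.075 * w)
        theta = rng.uniform(0, np.pi)
        rr, cc = skdraw.ellipse(cy, cx, ry, rx, shape=(h, w),
                                rotation=theta)
        hue = rng.uniform(*spec.leaf_hue_range)
        sat = rng.uniform(0.50, 0.70)
        val = rng.uniform(0.40, 0.60)
        img[rr, cc] = np.clip(np.rint(_hsv_to_rgb(hue, sat, val) * 255),
                              0, 255).astype(np.uint8)
        blades[rr, cc] = True
        # petiole: a short stroke from the blade tip outward
        tipy = cy + (ry + 2) * np.cos(theta)
        tipx = cx - (ry + 2) * np.sin(theta)
        endy = cy + (ry + 0.09 * h) * np.cos(theta)
        endx = cx - (ry + 0.09 * h) * np.sin(theta)
        lr, lc = skdraw.line(int(round(tipy)), int(round(tipx)),
                             int(round(endy)), int(round(endx)))
        inside = (lr >= 0) & (lr < h) & (lc >= 0) & (lc < w)
        stroke = np.zeros((h, w), dtype=bool)
        stroke[lr[inside], lc[inside]] = True
        stroke = ndi.binary_dilation(stroke, np.ones((3, 3), dtype=bool))
        petioles |= stroke
        pet_rgb = np.clip(np.rint(
            _hsv_to_rgb(hue - 15, sat * 0.8, val * 1.1) * 255), 0, 255)
        img[stroke] = pet_rgb.astype(np.uint8)
    petioles &= ~blades

    brown = np.zeros((h, w), dtype=bool)
    gamut = np.array(spec.brown_gamut, dtype=np.uint8)
    if gamut.size == 0 and (spec.edge_band_width > 0
                            or spec.spot_count_range[1] > 0):
        raise ValueError("brown_gamut is empty but browning is requested")

    # stage-dependent red-edge band along blade margins
    if spec.edge_band_width > 0:
        dist = ndi.distance_transform_edt(blades)
        band = blades & (dist <= spec.edge_band_width)
        img[band] = gamut[rng.integers(len(gamut))]
        brown |= band

    # brown spots fully inside blades (placement via the distance map)
    lo, hi = spec.spot_count_range
    n_spots = int(rng.integers(lo, hi + 1))
    spots: list[tuple[int, int, int]] = []
    if n_spots:
        interior_dist = ndi.distance_transform_edt(blades)
        for _ in range(n_spots):
            radius = int(rng.integers(spec.spot_radius_range[0],
                                      spec.spot_radius_range[1] + 1))
            ok = np.argwhere(interior_dist > radius + 1)
            if len(ok) == 0:
                raise ValueError(
                    "no blade region can hold a spot of radius "
                    f"{radius}: check spot_radius_range="
                    f"{spec.spot_radius_range} against n_leaves/image_size")
            cy, cx = ok[rng.integers(len(ok))]
            rr, cc = skdraw.disk((cy, cx), radius, shape=(h, w))
            img[rr, cc] = gamut[rng.integers(len(gamut))]
            brown[rr, cc] = True
            spots.append((int(cy), int(cx), radius))

    leaf = blades | petioles
    gt = GroundTruth(stage_label=spec.stage,
                     brown_mask=brown.astype(np.uint8) * 255,
                     leaf_mask=leaf.astype(np.uint8) * 255,
                     spots=tuple(spots))
    return img, gt


def _child_seed(master: int, stage: int, index: int) -> int:
    ss = np.random.SeedSequence([int(master), int(stage), int(index)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def write_manifest(rows: list[tuple[str, int]], path: Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["path", "stage"])
        writer.writerows(rows)


def read_manifest(path) -> list[tuple[str, int]]:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        return [(row["path"], int(row["stage"])) for row in reader]


def make_dataset(specs: list[StageSpec], n_per_stage: int, seed: int,
                 out_dir) -> Path:
    """Write ``n_per_stage`` PNGs per stage plus a ``manifest.csv``.

    Per-image seeds derive deterministically from (seed, stage, index), so
    the same master seed always reproduces byte-identical output.  Returns
    the manifest path; manifest paths are relative to ``out_dir``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows: list[tuple[str, int]] = []
    for spec in specs:
        stage_dir = out_dir / f"stage{spec.stage}"
        stage_dir.mkdir(exist_ok=True)
        for i in range(n_per_stage):
            img, _ = make_leaf_image(spec, _child_seed(seed, spec.stage, i))
            rel = f"stage{spec.stage}/img_{i:04d}.png"
            Image.fromarray(img).save(out_dir / rel)
            rows.append((rel, spec.stage))
    manifest = out_dir / "manifest.csv"
    write_manifest(rows, manifest)
    return manifest
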