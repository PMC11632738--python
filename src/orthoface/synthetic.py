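"""Procedural frontal-face image generator with exact landmark ground truth.

Stands in for a clinical photograph database: each synthetic subject is a
schematic face — smooth shaded ellipses for the face outline, brows, eyes,
nose and lips on a 1024x1024 canvas — whose 13 landmark positions are known
exactly by construction, plus a saturated-blue 10 mm fiducial disc on the
forehead with known pixel diameter.

Facial dimensions are drawn per subject from the clinical reference
cohort's caliper statistics (mean +/- SD of the nine measurements, see
:mod:`orthoface.reference`), so the generated population matches the adult
orthognathic-clinic population in scale and variability, including a
configurable fraction of subjects with exaggerated lower-third and lip
proportions emulating dentofacial deformity.

Faces are schematic, not photorealistic: the generator provides a
consistent appearance-to-landmark mapping sufficient to train and validate
the landmark network end to end, with no human data.
"""

from __future__ import annotations

import colorsys
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as oio
from .calibration import DEFAULT_PAD_COLOR, PAD_DIAMETER_MM, Scale
from .io import AnnotationRecord, FaceImage, LandmarkSet
from .measurements import (
    MEASUREMENT_IDS,
    MeasurementVector,
    compute_measurements,
    measurements_to_csv,
)
from .reference import GROUP_STATS

CANVAS = 1024

#: Safety margin: every landmark at least this many px from the border.
BORDER_MARGIN = 32


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class FaceGeometry:
    """Exact landmark layout and appearance parameters for one subject."""

    landmarks: np.ndarray            # (13, 2) px on the canvas
    pad_center: tuple[float, float]  # px
    pad_diameter_px: float
    mm_per_px: float
    skin_tone: tuple[float, float, float]   # base RGB, 0-255
    saturation: float                # palette saturation factor
    face_half_width: float           # px, outline ellipse
    face_top: float                  # px, outline ellipse top
    midline_x: float


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic cohort."""

    n_subjects: int = 80
    seed: int = 0
    mm_per_px_range: tuple[float, float] = (0.18, 0.22)
    deformity_fraction: float = 0.25     # 5 of 20 in the clinical test group
    asymmetry_jitter_px: float = 1.5     # bilateral mirror jitter, <= 3 px
    noise_sigma: float = 4.0             # additive Gaussian, 8-bit units
    caliper_sigma_mm: float = 0.3        # manual-measurement noise on CM
    test_fraction: float = 0.2           # held-out split
    saturation_range: tuple[float, float] = (0.85, 1.15)
    #: Per-measurement (mean, sd) mm used as the population model.
    population: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {m: GROUP_STATS[m]["CM"] for m in MEASUREMENT_IDS}
    )

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ConfigError("n_subjects must be >= 1")
        if not 0.0 <= self.deformity_fraction <= 1.0:
            raise ConfigError("deformity_fraction must be in [0, 1]")
        lo, hi = self.mm_per_px_range
        if not (0 < lo <= hi):
            raise ConfigError("mm_per_px_range must be positive and non-empty")
        if not 0.0 <= self.test_fraction < 1.0:
            raise ConfigError("test_fraction must be in [0, 1)")
        if self.asymmetry_jitter_px < 0 or self.asymmetry_jitter_px > 3:
            raise ConfigError("asymmetry_jitter_px must be in [0, 3]")
        for m in MEASUREMENT_IDS:
            if m not in self.population:
                raise ConfigError(f"population stats missing {m}")


def _truncnorm(rng: np.random.Generator, mean: float, sd: float,
               lo: float, hi: float) -> float:
    """Normal draw clipped by rejection to [lo, hi]."""
    for _ in range(64):
        v = rng.normal(mean, sd)
        if lo <= v <= hi:
            return float(v)
    return float(np.clip(mean, lo, hi))


def sample_geometry(rng: np.random.Generator, config: GeneratorConfig) -> FaceGeometry:
    """Draw one subject's facial geometry.

    Midline landmarks (menton, lip borders, subnasale) share the face
    midline; bilateral pairs are mirror-symmetric about it up to the
    configured jitter.  Vertical spacings are the nine measurements drawn
    from the population model, so anatomy ordering (brows above eyes above
    nose above lips above menton) holds by construction.
    """
    pop = config.population

    def draw(mid: str, lo_frac: float = 0.35) -> float:
        mean, sd = pop[mid]
        return _truncnorm(rng, mean, sd, lo_frac * mean, mean + 3.5 * sd)

    mm = {m: draw(m) for m in ("M1", "M3", "M4", "M5", "M6", "M7", "M8")}
    # interlabial gap may be near zero (lips at rest, possibly in contact)
    g_mean, g_sd = pop["M9"]
    mm["M9"] = max(0.0, rng.normal(g_mean, g_sd))

    deformed = rng.random() < config.deformity_fraction
    if deformed:
        # exaggerated lower third / lip proportions
        mm["M7"] *= rng.uniform(1.15, 1.35)
        mm["M8"] *= rng.uniform(1.1, 1.3)
        mm["M9"] += rng.uniform(1.0, 3.0)

    brow_y = rng.uniform(250.0, 290.0)
    total_mm = mm["M1"] + mm["M5"] + mm["M9"] + mm["M7"]
    lo, hi = config.mm_per_px_range
    mm_per_px = rng.uniform(lo, hi)
    # the photographer frames larger faces slightly wider: keep the menton
    # inside the canvas margin
    min_scale = total_mm / (CANVAS - BORDER_MARGIN - 4 - brow_y)
    mm_per_px = max(mm_per_px, min_scale)
    if mm_per_px > 2 * hi:
        raise ConfigError("face cannot fit canvas at configured scales")
    px = 1.0 / mm_per_px  # px per mm

    midline = CANVAS / 2 + rng.uniform(-25.0, 25.0)
    j = config.asymmetry_jitter_px

    def jit() -> float:
        return rng.uniform(-j, j) if j > 0 else 0.0

    brow_sep = _truncnorm(rng, 22.0, 2.0, 14.0, 30.0) * px
    eye_drop = _truncnorm(rng, 9.0, 1.0, 6.0, 12.0) * px
    alar_rise = _truncnorm(rng, 2.5, 0.5, 1.0, 4.5) * px
    cupid_halfw = _truncnorm(rng, 5.5, 0.7, 3.0, 8.0) * px

    y6 = brow_y + mm["M1"] * px            # subnasale
    y3 = y6 + mm["M5"] * px                # stomion superius
    y45 = y3 - mm["M6"] * px               # Cupid's bow line (midpoint height)
    y2 = y3 + mm["M9"] * px                # stomion inferius
    y1 = y2 + mm["M8"] * px                # lower vermilion border
    y0 = y2 + mm["M7"] * px                # menton
    eye_y = brow_y + eye_drop
    canthal_half = mm["M3"] * px / 2.0
    alar_half = mm["M4"] * px / 2.0

    pts = np.zeros((13, 2))
    pts[0] = (midline, y0)
    pts[1] = (midline, y1)
    pts[2] = (midline, y2)
    pts[3] = (midline, y3)
    pts[4] = (midline - cupid_halfw, y45)            # right Cupid peak
    pts[5] = (midline + cupid_halfw + jit(), y45 + jit())
    pts[6] = (midline, y6)
    pts[7] = (midline - alar_half, y6 - alar_rise)   # right alar base
    pts[8] = (midline + alar_half + jit(), y6 - alar_rise + jit())
    pts[9] = (midline - canthal_half, eye_y)         # right medial canthus
    pts[10] = (midline + canthal_half + jit(), eye_y + jit())
    pts[11] = (midline - brow_sep / 2.0, brow_y)
    pts[12] = (midline + brow_sep / 2.0 + jit(), brow_y + jit())

    if np.any(pts < BORDER_MARGIN) or np.any(pts > CANVAS - BORDER_MARGIN):
        raise ConfigError("sampled geometry violates canvas margins")

    face_half_width = 2.0 * mm["M3"] * px * rng.uniform(0.95, 1.05)
    face_top = max(brow_y - 45.0 * px, 10.0)

    pad_d = PAD_DIAMETER_MM * px
    pad_x = midline + rng.uniform(-55.0, 55.0)
    pad_y = rng.uniform(face_top + pad_d, brow_y - pad_d * 0.75 - 8.0)

    base_h = rng.uniform(0.05, 0.09)     # skin hue: orange band
    base_s = rng.uniform(0.28, 0.42)
    base_v = rng.uniform(0.72, 0.88)
    skin = tuple(255.0 * c for c in colorsys.hsv_to_rgb(base_h, base_s, base_v))

    return FaceGeometry(
        landmarks=pts,
        pad_center=(pad_x, pad_y),
        pad_diameter_px=pad_d,
        mm_per_px=mm_per_px,
        skin_tone=skin,  # type: ignore[arg-type]
        saturation=rng.uniform(*config.saturation_range),
        face_half_width=face_half_width,
        face_top=face_top,
        midline_x=midline,
    )


# ---------------------------------------------------------------------------
# rendering

def _sat(color: tuple[float, float, float], factor: float) -> np.ndarray:
    """Scale a palette colour's HSV saturation by ``factor``."""
    h, s, v = colorsys.rgb_to_hsv(*(c / 255.0 for c in color))
    r, g, b = colorsys.hsv_to_rgb(h, min(1.0, s * factor), v)
    return np.array([r * 255.0, g * 255.0, b * 255.0])


def _draw_ellipse(canvas: np.ndarray, cx: float, cy: float, rx: float, ry: float,
                  color: np.ndarray, soft: float = 1.5, alpha: float = 1.0) -> None:
    """Alpha-composite a soft-edged filled ellipse, windowed to its bbox."""
    h, w = canvas.shape[:2]
    x0 = max(int(cx - rx - 2), 0)
    x1 = min(int(cx + rx + 3), w)
    y0 = max(int(cy - ry - 2), 0)
    y1 = min(int(cy + ry + 3), h)
    if x1 <= x0 or y1 <= y0:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    r = np.sqrt(((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2)
    # soft edge: fully inside at r<=1, fades over ~soft px of the minor axis
    edge = np.clip((1.0 - r) * (min(rx, ry) / soft) + 0.5, 0.0, 1.0)
    a = (edge * alpha)[..., None]
    canvas[y0:y1, x0:x1] = (1 - a) * canvas[y0:y1, x0:x1] + a * color


@dataclass(frozen=True)
class PadTruth:
    center: tuple[float, float]
    diameter_px: float


def render_face(
    geometry: FaceGeometry,
    noise_sigma: float = 4.0,
    rng: np.random.Generator | None = None,
) -> tuple[FaceImage, LandmarkSet, PadTruth]:
    """Render a subject's schematic face to a 1024x1024 RGB image.

    The returned landmark set equals the geometry's landmarks exactly.
    Additive Gaussian pixel noise uses ``rng`` (a fresh seed-0 generator
    when omitted); ``noise_sigma=0`` renders deterministically.
    """
    g = geometry
    sf = g.saturation
    skin = _sat(g.skin_tone, sf)
    dark_skin = skin * 0.82
    brow_c = _sat((70, 50, 40), sf)
    lip_u = _sat((172, 82, 88), sf)
    lip_l = _sat((196, 98, 100), sf)
    mouth_c = _sat((60, 30, 32), sf)
    sclera = np.array([242.0, 240.0, 236.0])
    iris_c = _sat((60, 70, 95), sf)
    pad_c = _sat(DEFAULT_PAD_COLOR, min(sf, 1.0))

    canvas = np.empty((CANVAS, CANVAS, 3), dtype=np.float64)
    canvas[:] = _sat((192, 204, 214), sf)

    pts = g.landmarks
    mid = g.midline_x
    y0_menton = pts[0, 1]
    face_cy = (g.face_top + y0_menton) / 2.0
    face_ry = (y0_menton - g.face_top) / 2.0
    # face outline: darker rim ellipse under the skin ellipse gives a shaded edge
    _draw_ellipse(canvas, mid, face_cy, g.face_half_width + 6, face_ry + 6, dark_skin)
    _draw_ellipse(canvas, mid, face_cy, g.face_half_width, face_ry, skin, soft=14.0)

    # brows: thick dark arcs whose medial END sits exactly on landmarks 11/12
    brow_len = g.face_half_width * 0.42
    for sgn, idx in ((-1, 11), (1, 12)):
        bx, by = pts[idx]
        _draw_ellipse(canvas, bx + sgn * brow_len * 0.6, by,
                      brow_len * 0.6, 7.0, brow_c)

    # eyes: almond with iris; the outline's medial edge is the canthus
    eye_rx = g.face_half_width * 0.22
    eye_ry = eye_rx * 0.38
    for sgn, idx in ((-1, 9), (1, 10)):
        ex, ey = pts[idx]
        ring_rx, ring_ry = eye_rx + 2.5, eye_ry + 2.5
        _draw_ellipse(canvas, ex + sgn * ring_rx, ey, ring_rx, ring_ry,
                      brow_c * 0.9)
        _draw_ellipse(canvas, ex + sgn * ring_rx, ey, eye_rx, eye_ry, sclera)
        _draw_ellipse(canvas, ex + sgn * ring_rx, ey, eye_ry * 0.9,
                      eye_ry * 0.9, iris_c)

    # nose: soft shaded wedge from between the brows to the subnasale,
    # alar wings whose OUTER tip is landmark 7/8, nostril shadows above
    x6, y6 = pts[6]
    nose_len = y6 - pts[11, 1]
    _draw_ellipse(canvas, mid, y6 - nose_len * 0.45, g.face_half_width * 0.10,
                  nose_len * 0.5, dark_skin, soft=8.0, alpha=0.7)
    alar_half = abs(pts[8, 0] - pts[7, 0]) / 2.0
    wing_r = 12.0
    for sgn, idx in ((-1, 7), (1, 8)):
        ax, ay = pts[idx]
        _draw_ellipse(canvas, ax - sgn * wing_r, ay - 2.0, wing_r, 10.0,
                      dark_skin, soft=3.0, alpha=0.95)
        _draw_ellipse(canvas, mid + sgn * alar_half * 0.45, y6 - 8.0, 6.0, 4.0,
                      brow_c, alpha=0.8)
    # nose-base shadow: lower edge pins the subnasale row
    _draw_ellipse(canvas, mid, y6 - 2.5, alar_half * 0.8, 2.5, dark_skin * 0.8,
                  alpha=1.0)

    # lips: upper vermilion between the Cupid's-bow line and stomion
    # superius, lower vermilion between stomion inferius and the lower
    # border; the interlabial seam spans exactly the true gap (a hairline
    # seam remains visible when the lips touch)
    y45 = (pts[4, 1] + pts[5, 1]) / 2.0
    y3 = pts[3, 1]
    y2 = pts[2, 1]
    y1 = pts[1, 1]
    lip_w = alar_half * 2.0 * 0.82
    _draw_ellipse(canvas, mid, (y45 + y3) / 2.0, lip_w,
                  max((y3 - y45) / 2.0, 2.0), lip_u)
    _draw_ellipse(canvas, mid, (y2 + y1) / 2.0, lip_w * 0.94,
                  max((y1 - y2) / 2.0, 2.0), lip_l)
    _draw_ellipse(canvas, mid, (y3 + y2) / 2.0, lip_w * 0.98,
                  max((y2 - y3) / 2.0, 0.6), mouth_c)

    # chin shadow just below the menton
    _draw_ellipse(canvas, mid, y0_menton + 7.0, g.face_half_width * 0.35, 9.0,
                  dark_skin * 0.9, soft=5.0, alpha=0.8)

    # fiducial pad: uniform high-contrast disc, fully on the forehead
    px_r = g.pad_diameter_px / 2.0
    _draw_ellipse(canvas, g.pad_center[0], g.pad_center[1], px_r, px_r, pad_c,
                  soft=1.0)

    if noise_sigma > 0:
        rng = rng if rng is not None else np.random.default_rng(0)
        canvas = canvas + rng.normal(0.0, noise_sigma, canvas.shape)

    image = FaceImage(np.clip(canvas, 0, 255).astype(np.uint8))
    landmarks = LandmarkSet(pts.copy(), (CANVAS, CANVAS))
    return image, landmarks, PadTruth(g.pad_center, g.pad_diameter_px)


# ---------------------------------------------------------------------------
# dataset generation

def ground_truth_measurements(
    geometry: FaceGeometry, subject_id: str, method: str = "GT"
) -> MeasurementVector:
    """Noiseless measurements from the true landmarks and true scale."""
    lms = LandmarkSet(geometry.landmarks.copy(), (CANVAS, CANVAS))
    scale = Scale(mm_per_px=geometry.mm_per_px, source="manifest")
    return compute_measurements(lms, scale, subject_id=subject_id,
                                method=method, round_mm=False)


def generate_dataset(config: GeneratorConfig, outdir: str | Path) -> Path:
    """Write a full synthetic cohort: images, annotations, manifest, tables.

    Produces n PNG images with landmark annotations, a train/test split
    manifest, a noiseless ground-truth measurement table (method GT) and a
    synthetic "conventional" caliper table (method CM = GT plus Gaussian
    noise of ``caliper_sigma_mm``).  Returns the manifest path.
    """
    outdir = Path(outdir)
    (outdir / "images").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    n_test = int(round(config.n_subjects * config.test_fraction))
    split_tags = ["train"] * (config.n_subjects - n_test) + ["test"] * n_test

    records: list[AnnotationRecord] = []
    entries = []
    gt_rows: list[MeasurementVector] = []
    cm_rows: list[MeasurementVector] = []
    for i in range(config.n_subjects):
        sid = f"subj{i:04d}"
        geom = sample_geometry(rng, config)
        image, landmarks, pad = render_face(geom, config.noise_sigma, rng)
        image.id = sid
        rel = f"images/{sid}.png"
        oio.write_image(image, outdir / rel)

        gt = ground_truth_measurements(geom, sid)
        gt_rows.append(gt)
        cm_vals = {
            m: max(0.0, gt.values[m] + rng.normal(0.0, config.caliper_sigma_mm))
            for m in MEASUREMENT_IDS
        }
        cm_rows.append(MeasurementVector(sid, "CM", cm_vals))

        records.append(AnnotationRecord(
            image_id=sid,
            landmarks=landmarks,
            pad_center=pad.center,
            pad_diameter_px=pad.diameter_px,
            mm_per_px=geom.mm_per_px,
            conventional_mm=cm_rows[-1].values,
        ))
        entries.append({"id": sid, "image": rel, "split": split_tags[i]})

    oio.write_annotations(records, outdir / "annotations.json")
    measurements_to_csv(gt_rows, outdir / "ground_truth.csv")
    measurements_to_csv(cm_rows, outdir / "conventional.csv")

    manifest = {
        "version": 1,
        "seed": config.seed,
        "n_subjects": config.n_subjects,
        "annotations": "annotations.json",
        "ground_truth": "ground_truth.csv",
        "conventional": "conventional.csv",
        "images": entries,
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return manifest_path


def load_manifest(path: str | Path) -> dict:
    path = Path(path)
    doc = json.loads(path.read_text())
    doc["_root"] = str(path.parent)
    return doc
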