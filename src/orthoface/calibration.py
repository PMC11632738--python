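"""Pixel-to-millimetre calibration from a 10 mm circular fiducial pad.

A silicone adhesive pad of known 10 mm diameter is affixed to the upper
third of the face at capture time.  Detecting its pixel diameter gives the
mm-per-pixel factor used to convert landmark distances to caliper units.

Detection: colour-threshold against the configured pad colour, label
connected components in the search region, keep components that are
sufficiently circular (4*pi*area/perimeter^2 >= 0.8), and take the largest.
The equivalent (area-based) diameter 2*sqrt(area/pi) is robust to mild
anti-aliasing at the disc rim.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure

from .io import FaceImage

#: Physical pad diameter in millimetres.
PAD_DIAMETER_MM = 10.0

#: Default pad colour (RGB) matched during thresholding: a saturated blue
#: that does not occur in skin, lip or background tones.
DEFAULT_PAD_COLOR = (30, 90, 220)

#: Default Euclidean RGB distance threshold for pad-colour matching.
DEFAULT_COLOR_TOL = 80.0

#: Minimum circularity 4*pi*A/P^2 for a component to count as the pad.
CIRCULARITY_MIN = 0.8

#: Minimum component area (px) considered; rejects speckle noise.
MIN_PAD_AREA = 40


class PadDetectionError(RuntimeError):
    """No component in the search region passes the circularity filter."""


class PadAmbiguityError(RuntimeError):
    """More than one equally plausible pad candidate."""


@dataclass(frozen=True)
class PadDetection:
    center: tuple[float, float]   # (x, y) px in the full image frame
    diameter_px: float            # equivalent diameter 2*sqrt(area/pi)
    area_px: int

    def __post_init__(self) -> None:
        if not self.diameter_px > 0:
            raise ValueError("pad diameter must be positive")


@dataclass(frozen=True)
class Scale:
    mm_per_px: float
    source: str = "pad"  # "pad" | "manifest"

    def __post_init__(self) -> None:
        if not (np.isfinite(self.mm_per_px) and self.mm_per_px > 0):
            raise ValueError(f"mm_per_px must be positive and finite, got {self.mm_per_px}")


def detect_pad(
    image: FaceImage,
    search_region: tuple[int, int, int, int] | None = None,
    pad_color: tuple[int, int, int] = DEFAULT_PAD_COLOR,
    color_tol: float = DEFAULT_COLOR_TOL,
) -> PadDetection:
    """Locate the fiducial disc and measure its equivalent diameter.

    ``search_region`` is (x0, y0, x1, y1); default is the upper third of the
    frame, where the pad is placed clinically.
    """
    if search_region is None:
        search_region = (0, 0, image.width, image.height // 3)
    x0, y0, x1, y1 = search_region
    window = image.pixels[y0:y1, x0:x1].astype(np.float64)
    dist = np.linalg.norm(window - np.asarray(pad_color, dtype=np.float64), axis=-1)
    mask = dist <= color_tol
    labels = measure.label(mask, connectivity=2)
    candidates = []
    for p in measure.regionprops(labels):
        if p.area < MIN_PAD_AREA or p.perimeter == 0:
            continue
        circularity = 4.0 * np.pi * p.area / p.perimeter**2
        if circularity >= CIRCULARITY_MIN:
            candidates.append(p)
    if not candidates:
        raise PadDetectionError(
            "no sufficiently circular pad-coloured component in search region"
        )
    candidates.sort(key=lambda p: p.area, reverse=True)
    if len(candidates) > 1 and candidates[1].area >= 0.9 * candidates[0].area:
        raise PadAmbiguityError(
            f"{len(candidates)} comparable pad candidates in search region"
        )
    best = candidates[0]
    cy, cx = best.centroid
    diameter = 2.0 * float(np.sqrt(best.area / np.pi))
    return PadDetection(
        center=(cx + x0, cy + y0), diameter_px=diameter, area_px=int(best.area)
    )


def scale_from_pad(det: PadDetection, known_mm: float = PAD_DIAMETER_MM) -> Scale:
    """mm-per-pixel from the detected pad: known_mm / diameter_px."""
    if det.diameter_px <= 0:
        raise ValueError("non-positive pad diameter")
    return Scale(mm_per_px=known_mm / det.diameter_px, source="pad")


def px_to_mm(d_px: float, scale: Scale) -> float:
    """Convert a pixel distance to millimetres."""
    if d_px < 0:
        raise ValueError("distance must be >= 0")
    return d_px * scale.mm_per_px
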