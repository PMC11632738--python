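"""Image and landmark-annotation I/O plus fixed geometric preprocessing.

The analysis operates on frontal facial photographs cropped to a square frame
with the face centred, and on 13 named soft-tissue landmarks per image.  The
canonical annotation is a coordinate set; binarized landmark masks (the
training gold standard) are an export/import format, since a mask alone
cannot encode landmark identity.

Coordinate convention: origin at the top-left corner, x rightward, y
downward, 0-based, coordinates refer to pixel centres.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError
from skimage import measure
from skimage.transform import resize as _sk_resize

#: Fixed landmark schema: index -> anatomical name.
LANDMARK_NAMES: tuple[str, ...] = (
    "Mentoniano",          # 0  soft-tissue menton (chin)
    "UnderLipBotton",      # 1  lower border of lower-lip vermilion
    "UnderLipTop",         # 2  stomion inferius
    "UpperLipBottom",      # 3  stomion superius
    "UpperLipTopRight",    # 4  Cupid's bow, right peak
    "UpperLipTopLeft",     # 5  Cupid's bow, left peak
    "Subnasal",            # 6  subnasale
    "NoseRightAlarOutTip", # 7  right alar base
    "NoseLeftAlarOutTip",  # 8  left alar base
    "EyeRightInner",       # 9  right medial canthus
    "EyeLeftInner",        # 10 left medial canthus
    "EyebrowRightInner",   # 11 right eyebrow, medial end
    "EyebrowLeftInner",    # 12 left eyebrow, medial end
)

N_LANDMARKS = len(LANDMARK_NAMES)

#: Bilateral (right, left) index pairs swapped under a horizontal mirror.
BILATERAL_PAIRS: tuple[tuple[int, int], ...] = ((4, 5), (7, 8), (9, 10), (11, 12))

#: Network input side length in pixels.
NET_INPUT_SIZE = 40

#: Precision (decimal places, px) at which annotations are serialised.
ANNOTATION_PRECISION = 2


class FormatError(ValueError):
    """Raised for undecodable images or malformed annotation documents."""


class SchemaError(ValueError):
    """Raised when an annotation violates the 13-landmark schema."""


class MaskError(ValueError):
    """Raised when a landmark mask has the wrong component count."""


@dataclass
class FaceImage:
    """An 8-bit RGB image with an opaque identifier."""

    pixels: np.ndarray  # (H, W, 3) uint8
    id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim == 2:  # tolerate grayscale input, promote to RGB
            px = np.stack([px] * 3, axis=-1)
        if px.ndim != 3 or px.shape[2] != 3:
            raise FormatError(f"expected (H, W, 3) pixel grid, got {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise FormatError("image must be at least 1x1")
        self.pixels = np.ascontiguousarray(px, dtype=np.uint8)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class LandmarkSet:
    """13 named (x, y) pixel coordinates in a declared image frame."""

    points: np.ndarray          # (13, 2) float64, columns (x, y)
    frame: tuple[int, int]      # (width, height) of the reference image

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=np.float64)
        if pts.shape != (N_LANDMARKS, 2):
            raise SchemaError(
                f"expected {N_LANDMARKS} (x, y) points, got shape {pts.shape}"
            )
        if not np.all(np.isfinite(pts)):
            raise SchemaError("landmark coordinates must be finite")
        self.points = pts
        self.frame = (int(self.frame[0]), int(self.frame[1]))

    def __getitem__(self, index: int) -> np.ndarray:
        return self.points[index]

    def shifted(self, dx: float, dy: float) -> "LandmarkSet":
        return LandmarkSet(self.points + np.array([dx, dy]), self.frame)

    def scaled(self, sx: float, sy: float, frame: tuple[int, int]) -> "LandmarkSet":
        return LandmarkSet(self.points * np.array([sx, sy]), frame)

    def as_dict(self) -> dict[str, list[float]]:
        return {
            name: [round(float(x), ANNOTATION_PRECISION),
                   round(float(y), ANNOTATION_PRECISION)]
            for name, (x, y) in zip(LANDMARK_NAMES, self.points)
        }

    @classmethod
    def from_dict(cls, d: dict, frame: tuple[int, int]) -> "LandmarkSet":
        missing = [n for n in LANDMARK_NAMES if n not in d]
        if missing:
            raise SchemaError(f"{missing[0]} missing")
        extra = [n for n in d if n not in LANDMARK_NAMES]
        if extra:
            raise SchemaError(f"unknown landmark name {extra[0]!r}")
        pts = np.array([d[n] for n in LANDMARK_NAMES], dtype=np.float64)
        return cls(pts, frame)


@dataclass
class AnnotationRecord:
    """Everything known about one annotated subject image."""

    image_id: str
    landmarks: LandmarkSet
    pad_center: tuple[float, float] | None = None
    pad_diameter_px: float | None = None
    mm_per_px: float | None = None
    conventional_mm: dict[str, float] | None = None  # caliper measurements

    def to_json_obj(self) -> dict:
        obj: dict = {
            "image_id": self.image_id,
            "frame": list(self.landmarks.frame),
            "landmarks": self.landmarks.as_dict(),
        }
        if self.pad_center is not None:
            obj["pad_center"] = [float(self.pad_center[0]), float(self.pad_center[1])]
        if self.pad_diameter_px is not None:
            obj["pad_diameter_px"] = float(self.pad_diameter_px)
        if self.mm_per_px is not None:
            obj["mm_per_px"] = float(self.mm_per_px)
        if self.conventional_mm is not None:
            obj["conventional_mm"] = {k: float(v) for k, v in self.conventional_mm.items()}
        return obj

    @classmethod
    def from_json_obj(cls, obj: dict) -> "AnnotationRecord":
        frame = tuple(obj.get("frame", (0, 0)))
        return cls(
            image_id=str(obj["image_id"]),
            landmarks=LandmarkSet.from_dict(obj["landmarks"], frame),
            pad_center=tuple(obj["pad_center"]) if "pad_center" in obj else None,
            pad_diameter_px=obj.get("pad_diameter_px"),
            mm_per_px=obj.get("mm_per_px"),
            conventional_mm=obj.get("conventional_mm"),
        )


# ---------------------------------------------------------------------------
# image I/O

def read_image(path: str | Path) -> FaceImage:
    """Read a PNG/JPEG file into a :class:`FaceImage`.

    The image id is the filename stem.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        with Image.open(path) as im:
            pixels = np.asarray(im.convert("RGB"))
    except (UnidentifiedImageError, OSError) as exc:
        raise FormatError(f"cannot decode {path}: {exc}") from exc
    return FaceImage(pixels=pixels, id=path.stem)


def write_image(image: FaceImage, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(image.pixels).save(path)
    return path


# ---------------------------------------------------------------------------
# annotation I/O

def write_annotations(records: list[AnnotationRecord], path: str | Path) -> Path:
    ids = [r.image_id for r in records]
    dup = {i for i in ids if ids.count(i) > 1}
    if dup:
        raise SchemaError(f"duplicated image id {sorted(dup)[0]!r}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    doc = [r.to_json_obj() for r in records]
    path.write_text(json.dumps(doc, indent=1, sort_keys=True))
    return path


def read_annotations(path: str | Path) -> list[AnnotationRecord]:
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"malformed annotation file {path}: {exc}") from exc
    if not isinstance(doc, list):
        raise FormatError("annotation document must be a JSON list")
    records = [AnnotationRecord.from_json_obj(obj) for obj in doc]
    ids = [r.image_id for r in records]
    dup = {i for i in ids if ids.count(i) > 1}
    if dup:
        raise SchemaError(f"duplicated image id {sorted(dup)[0]!r}")
    return records


def annotations_to_csv(records: list[AnnotationRecord], path: str | Path) -> Path:
    """Flat CSV mirror of the JSON schema: image_id, name, x, y."""
    import csv

    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["image_id", "name", "x", "y"])
        for r in records:
            for name, (x, y) in zip(LANDMARK_NAMES, r.landmarks.points):
                w.writerow([r.image_id, name,
                            f"{x:.{ANNOTATION_PRECISION}f}",
                            f"{y:.{ANNOTATION_PRECISION}f}"])
    return path


# ---------------------------------------------------------------------------
# geometric preprocessing

def crop_centered(
    image: FaceImage, center: tuple[float, float], size: int
) -> tuple[FaceImage, tuple[int, int]]:
    """Crop a ``size``x``size`` window centred on ``center``.

    Regions outside the source are filled with black.  Returns the cropped
    image and the (dx, dy) offset to ADD to source coordinates to express
    them in the crop frame.
    """
    if size < 1:
        raise ValueError("crop size must be >= 1")
    cx, cy = center
    x0 = int(round(cx)) - size // 2
    y0 = int(round(cy)) - size // 2
    out = np.zeros((size, size, 3), dtype=np.uint8)
    sx0, sy0 = max(x0, 0), max(y0, 0)
    sx1 = min(x0 + size, image.width)
    sy1 = min(y0 + size, image.height)
    if sx1 > sx0 and sy1 > sy0:
        out[sy0 - y0 : sy1 - y0, sx0 - x0 : sx1 - x0] = image.pixels[
            sy0:sy1, sx0:sx1
        ]
    return FaceImage(out, id=image.id), (-x0, -y0)


def resize_to_input(
    image: FaceImage, landmarks: LandmarkSet | None = None, size: int = NET_INPUT_SIZE
) -> FaceImage | tuple[FaceImage, LandmarkSet]:
    """Bilinear-resize to the square network input (default 40x40).

    If ``landmarks`` are given they are rescaled by the same factors and
    returned alongside the image.
    """
    if image.height == size and image.width == size:
        resized = FaceImage(image.pixels.copy(), id=image.id)
    else:
        arr = _sk_resize(
            image.pixels, (size, size), order=1, mode="edge",
            anti_aliasing=False, preserve_range=True,
        )
        resized = FaceImage(np.clip(arr, 0, 255).astype(np.uint8), id=image.id)
    if landmarks is None:
        return resized
    sx = size / image.width
    sy = size / image.height
    return resized, landmarks.scaled(sx, sy, (size, size))


# ---------------------------------------------------------------------------
# binarized gold-standard masks

def render_mask(
    landmarks: LandmarkSet, dims: tuple[int, int], radius: int = 1
) -> np.ndarray:
    """Render landmarks as a binary mask (one small disc per landmark).

    ``dims`` is (width, height).  Raises :class:`SchemaError` for a
    wrong-cardinality landmark set (enforced by LandmarkSet itself) and a
    range error when a landmark falls outside the mask.
    """
    w, h = dims
    pts = landmarks.points
    if np.any(pts[:, 0] < 0) or np.any(pts[:, 0] > w - 1) or \
       np.any(pts[:, 1] < 0) or np.any(pts[:, 1] > h - 1):
        raise ValueError("landmark outside mask dimensions")
    mask = np.zeros((h, w), dtype=bool)
    yy, xx = np.mgrid[0:h, 0:w]
    for x, y in pts:
        if radius <= 1:
            mask[int(round(y)), int(round(x))] = True
        else:
            mask |= (xx - x) ** 2 + (yy - y) ** 2 <= radius**2
    return mask


def mask_to_landmarks(
    mask: np.ndarray, ordering: list[int] | np.ndarray
) -> LandmarkSet:
    """Recover landmark coordinates from a binary mask.

    ``ordering`` maps connected components, sorted by (y, x) of their
    centroids, back to schema indices: ``ordering[k]`` is the schema index of
    the k-th component in that scan order.  A sidecar ordering is required
    because the mask alone cannot encode landmark identity.
    """
    labels = measure.label(np.asarray(mask, dtype=bool), connectivity=2)
    props = measure.regionprops(labels)
    if len(props) != N_LANDMARKS:
        raise MaskError(
            f"expected {N_LANDMARKS} mask components, found {len(props)}"
        )
    cents = np.array([p.centroid for p in props])  # (row, col) = (y, x)
    order = np.lexsort((cents[:, 1], cents[:, 0]))  # by y then x
    ordering = np.asarray(ordering, dtype=int)
    if sorted(ordering.tolist()) != list(range(N_LANDMARKS)):
        raise SchemaError("ordering must be a permutation of 0..12")
    pts = np.empty((N_LANDMARKS, 2))
    for k, comp in enumerate(order):
        pts[ordering[k]] = cents[comp][::-1]  # to (x, y)
    h, w = mask.shape
    return LandmarkSet(pts, (w, h))


def mask_ordering(landmarks: LandmarkSet) -> np.ndarray:
    """The sidecar ordering record for :func:`mask_to_landmarks`.

    Sorts the landmark set by (y, x) and records which schema index lands at
    each scan position.
    """
    pts = landmarks.points
    order = np.lexsort((pts[:, 0], pts[:, 1]))
    return order
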