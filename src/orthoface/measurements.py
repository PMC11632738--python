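"""The nine facial measurements (M1-M9) derived from the 13-landmark schema.

Each measurement is the Euclidean caliper distance (mm) between two
soft-tissue points; an endpoint is either a single landmark or the midpoint
of a bilateral pair (the eyebrow-inner midpoint serves as a glabella proxy
for the middle third, the Cupid's-bow midpoint as labiale superius for the
upper-lip vermilion).  The registry is data-driven so alternative endpoint
pairings can be supplied as a JSON override.

M1 middle third        glabella proxy -> subnasale
M2 lower third         subnasale -> menton
M3 intercanthal        right medial canthus -> left medial canthus
M4 alar base           right alar base -> left alar base
M5 upper lip           subnasale -> stomion superius
M6 upper lip vermilion labiale superius proxy -> stomion superius
M7 lower lip           stomion inferius -> menton
M8 lower lip vermilion stomion inferius -> lower vermilion border
M9 interlabial gap     stomion superius -> stomion inferius
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .calibration import Scale
from .io import N_LANDMARKS, LandmarkSet

Endpoint = tuple[int, ...]  # one index, or two indices meaning their midpoint

MEASUREMENT_IDS = tuple(f"M{i}" for i in range(1, 10))

#: Reported precision in mm (digital-caliper resolution).
MM_PRECISION = 2


@dataclass(frozen=True)
class MeasurementDef:
    id: str
    name: str
    a: Endpoint
    b: Endpoint

    def __post_init__(self) -> None:
        for ep in (self.a, self.b):
            if not 1 <= len(ep) <= 2 or any(
                not 0 <= i < N_LANDMARKS for i in ep
            ):
                raise ValueError(f"invalid endpoint {ep} in {self.id}")


_DEFAULT_REGISTRY: tuple[MeasurementDef, ...] = (
    MeasurementDef("M1", "middle third", (11, 12), (6,)),
    MeasurementDef("M2", "lower third", (6,), (0,)),
    MeasurementDef("M3", "intercanthal distance", (9,), (10,)),
    MeasurementDef("M4", "alar base", (7,), (8,)),
    MeasurementDef("M5", "upper lip", (6,), (3,)),
    MeasurementDef("M6", "upper lip vermilion", (4, 5), (3,)),
    MeasurementDef("M7", "lower lip", (2,), (0,)),
    MeasurementDef("M8", "lower lip vermilion", (2,), (1,)),
    MeasurementDef("M9", "interlabial gap", (3,), (2,)),
)


def measurement_registry(
    override_path: str | Path | None = None,
) -> tuple[MeasurementDef, ...]:
    """The nine measurement definitions, optionally from a JSON override.

    Override format: ``[{"id", "name", "a": [idx...], "b": [idx...]}, ...]``.
    """
    if override_path is None:
        return _DEFAULT_REGISTRY
    doc = json.loads(Path(override_path).read_text())
    return tuple(
        MeasurementDef(d["id"], d["name"], tuple(d["a"]), tuple(d["b"]))
        for d in doc
    )


@dataclass
class MeasurementVector:
    """Nine mm-valued measurements for one subject under one method."""

    subject_id: str
    method: str  # "CM" | "AM1" | "AM2" | "GT" | ...
    values: dict[str, float]  # keyed M1..M9

    def __post_init__(self) -> None:
        for mid in MEASUREMENT_IDS:
            if mid not in self.values:
                raise ValueError(f"measurement {mid} missing")
            v = float(self.values[mid])
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{mid} must be finite and >= 0, got {v}")
            self.values[mid] = v

    def as_array(self) -> np.ndarray:
        return np.array([self.values[m] for m in MEASUREMENT_IDS])


def _resolve(pts: np.ndarray, ep: Endpoint) -> np.ndarray:
    return pts[list(ep)].mean(axis=0)


def compute_measurements(
    landmarks: LandmarkSet,
    scale: Scale,
    subject_id: str = "",
    method: str = "AM",
    registry: tuple[MeasurementDef, ...] | None = None,
    round_mm: bool = True,
) -> MeasurementVector:
    """Euclidean pixel distance between resolved endpoints times mm/px.

    Values are reported to 0.01 mm (caliper resolution) unless
    ``round_mm=False``, which keeps full float precision for self-consistency
    checks.
    """
    pts = landmarks.points
    if not np.all(np.isfinite(pts)):
        raise ValueError("non-finite landmark coordinate")
    registry = registry or _DEFAULT_REGISTRY
    values: dict[str, float] = {}
    for mdef in registry:
        d_px = float(np.linalg.norm(_resolve(pts, mdef.a) - _resolve(pts, mdef.b)))
        mm = d_px * scale.mm_per_px
        values[mdef.id] = round(mm, MM_PRECISION) if round_mm else mm
    return MeasurementVector(subject_id=subject_id, method=method, values=values)


def measurements_to_csv(vectors: list[MeasurementVector], path: str | Path) -> Path:
    import csv

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["subject_id", "method", *MEASUREMENT_IDS])
        for v in vectors:
            w.writerow(
                [v.subject_id, v.method]
                + [f"{v.values[m]:.{MM_PRECISION}f}" for m in MEASUREMENT_IDS]
            )
    return path


def measurements_from_csv(path: str | Path) -> list[MeasurementVector]:
    import csv

    out: list[MeasurementVector] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(
                MeasurementVector(
                    subject_id=row["subject_id"],
                    method=row["method"],
                    values={m: float(row[m]) for m in MEASUREMENT_IDS},
                )
            )
    return out
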