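"""Domain types for alveolar bone defect annotations.

A sagittal CBCT slice of one tooth can carry up to four annotated bone
defects, one per :class:`DefectClass`.  Each defect is marked by a pair of
landmark endpoints in pixel coordinates; the clinical length of the defect is
the Euclidean distance between the endpoints converted to millimetres through
the slice's pixel pitch.

Coordinate convention: ``x`` is the column and ``y`` the row of the raster,
both 0-based with the origin at the top-left corner, so increasing ``y``
moves apically (toward the root apex) in the rendered slices.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "DefectClass",
    "LandmarkPair",
    "SliceAnnotation",
    "AnnotationError",
    "px_to_mm",
    "read_annotations",
    "write_annotations",
    "DEHISCENCE_THRESHOLD_MM",
    "FENESTRATION_THRESHOLD_MM",
]

#: Clinical positivity thresholds (strict inequalities): a dehiscence is
#: positive when the ARC-CEJ distance exceeds 2 mm, a fenestration when the
#: bone interruption is greater than 2.2 mm.
DEHISCENCE_THRESHOLD_MM = 2.0
FENESTRATION_THRESHOLD_MM = 2.2


class AnnotationError(ValueError):
    """Raised for malformed or invariant-violating annotation records."""


class DefectClass(Enum):
    """The four defect classes, ordered as the model's channel groups.

    Group ``g`` owns prediction channels ``3g .. 3g+2`` (0-based): the first
    channel of a group is the defect mask (or endpoint heatmap), the other two
    the components of the apex-to-crown direction field.
    """

    BUCCAL_DEHISCENCE = "buccal_dehiscence"
    LINGUAL_DEHISCENCE = "lingual_dehiscence"
    BUCCAL_FENESTRATION = "buccal_fenestration"
    LINGUAL_FENESTRATION = "lingual_fenestration"

    @property
    def group(self) -> int:
        """Channel-group index 0-3 (channels ``3*group .. 3*group+2``)."""
        return _GROUP_ORDER.index(self)

    @property
    def is_dehiscence(self) -> bool:
        return self in (DefectClass.BUCCAL_DEHISCENCE, DefectClass.LINGUAL_DEHISCENCE)

    @property
    def is_buccal(self) -> bool:
        return self in (DefectClass.BUCCAL_DEHISCENCE, DefectClass.BUCCAL_FENESTRATION)

    @property
    def roles(self) -> tuple[str, str]:
        """Endpoint role names ``(role of p1, role of p2)``.

        Dehiscence endpoints are the alveolar ridge crest (ARC) and the
        cementoenamel junction (CEJ); fenestration endpoints are the coronal
        (CB) and apical (AB) borders of the bone window.
        """
        return ("ARC", "CEJ") if self.is_dehiscence else ("CB", "AB")

    @property
    def apical_role(self) -> str:
        """Role of the endpoint nearer the root apex (larger ``y``)."""
        return "ARC" if self.is_dehiscence else "AB"

    @property
    def coronal_role(self) -> str:
        return "CEJ" if self.is_dehiscence else "CB"

    @property
    def threshold_mm(self) -> float:
        """Strict positivity threshold for this class, in mm."""
        return DEHISCENCE_THRESHOLD_MM if self.is_dehiscence else FENESTRATION_THRESHOLD_MM


_GROUP_ORDER = (
    DefectClass.BUCCAL_DEHISCENCE,
    DefectClass.LINGUAL_DEHISCENCE,
    DefectClass.BUCCAL_FENESTRATION,
    DefectClass.LINGUAL_FENESTRATION,
)


def px_to_mm(distance_px: float, pixel_pitch_mm: float) -> float:
    """Convert a pixel distance to millimetres.

    Parameters
    ----------
    distance_px
        Nonnegative distance in pixels.
    pixel_pitch_mm
        Physical edge length of one pixel in mm (0.25 mm for the CBCT
        export regime this package targets).
    """
    if distance_px < 0 or pixel_pitch_mm < 0:
        raise AnnotationError(
            f"px_to_mm requires nonnegative inputs, got {distance_px}, {pixel_pitch_mm}"
        )
    return distance_px * pixel_pitch_mm


@dataclass
class LandmarkPair:
    """Endpoint pair of one annotated defect, in pixel coordinates.

    ``p1``/``p2`` follow the class's role order (:attr:`DefectClass.roles`):
    (ARC, CEJ) for dehiscence, (CB, AB) for fenestration.
    """

    defect_class: DefectClass
    p1: np.ndarray  # (x, y)
    p2: np.ndarray

    def __post_init__(self) -> None:
        self.p1 = np.asarray(self.p1, dtype=float)
        self.p2 = np.asarray(self.p2, dtype=float)
        if self.p1.shape != (2,) or self.p2.shape != (2,):
            raise AnnotationError("landmark points must be length-2 (x, y)")
        if np.allclose(self.p1, self.p2):
            raise AnnotationError("degenerate landmark pair: p1 == p2")

    @property
    def apical_point(self) -> np.ndarray:
        """Endpoint carrying the class's apical role."""
        return self.p1 if self.defect_class.roles[0] == self.defect_class.apical_role else self.p2

    @property
    def coronal_point(self) -> np.ndarray:
        return self.p2 if self.defect_class.roles[0] == self.defect_class.apical_role else self.p1

    def length_px(self) -> float:
        return float(np.hypot(*(self.p1 - self.p2)))

    def length_mm(self, pixel_pitch_mm: float) -> float:
        return px_to_mm(self.length_px(), pixel_pitch_mm)

    def validate_bounds(self, shape: tuple[int, int]) -> None:
        """Check both endpoints lie inside an ``(H, W)`` image."""
        h, w = shape
        for p in (self.p1, self.p2):
            if not (0 <= p[0] <= w - 1 and 0 <= p[1] <= h - 1):
                raise AnnotationError(f"landmark {p} outside {h}x{w} image")


@dataclass
class SliceAnnotation:
    """Ground-truth defect annotation for one sagittal slice.

    Slices come in triplets per tooth (``slice_index`` 0, 1, 2 ordered
    mesial to distal); at most one landmark pair per defect class.
    """

    patient_id: str
    tooth_id: str
    slice_index: int
    pixel_pitch_mm: float
    defects: list[LandmarkPair] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.slice_index not in (0, 1, 2):
            raise AnnotationError(f"slice_index must be 0, 1 or 2, got {self.slice_index}")
        if self.pixel_pitch_mm <= 0:
            raise AnnotationError("pixel_pitch_mm must be positive")
        classes = [d.defect_class for d in self.defects]
        if len(classes) != len(set(classes)):
            raise AnnotationError("at most one landmark pair per class per slice")

    def get(self, defect_class: DefectClass) -> LandmarkPair | None:
        for d in self.defects:
            if d.defect_class is defect_class:
                return d
        return None

    def length_mm(self, defect_class: DefectClass) -> float | None:
        pair = self.get(defect_class)
        return None if pair is None else pair.length_mm(self.pixel_pitch_mm)

    def slice_label(self, defect_class: DefectClass) -> bool:
        """Threshold-based per-slice label (strict inequality)."""
        length = self.length_mm(defect_class)
        return length is not None and length > defect_class.threshold_mm

    def to_record(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "tooth_id": self.tooth_id,
            "slice_index": self.slice_index,
            "pixel_pitch_mm": self.pixel_pitch_mm,
            "defects": [
                {
                    "class": d.defect_class.value,
                    "p1": [float(d.p1[0]), float(d.p1[1])],
                    "p2": [float(d.p2[0]), float(d.p2[1])],
                }
                for d in self.defects
            ],
        }


_KNOWN_KEYS = {"patient_id", "tooth_id", "slice_index", "pixel_pitch_mm", "defects"}
_KNOWN_DEFECT_KEYS = {"class", "p1", "p2"}


def _annotation_from_record(record: dict, index: int) -> SliceAnnotation:
    unknown = set(record) - _KNOWN_KEYS
    if unknown:
        warnings.warn(f"annotation record {index}: ignoring unknown keys {sorted(unknown)}")
    try:
        defects = []
        for d in record.get("defects", []):
            extra = set(d) - _KNOWN_DEFECT_KEYS
            if extra:
                warnings.warn(f"annotation record {index}: ignoring defect keys {sorted(extra)}")
            defects.append(
                LandmarkPair(DefectClass(d["class"]), np.asarray(d["p1"]), np.asarray(d["p2"]))
            )
        return SliceAnnotation(
            patient_id=str(record["patient_id"]),
            tooth_id=str(record["tooth_id"]),
            slice_index=int(record["slice_index"]),
            pixel_pitch_mm=float(record["pixel_pitch_mm"]),
            defects=defects,
        )
    except (KeyError, TypeError, ValueError) as exc:
        if isinstance(exc, AnnotationError):
            raise AnnotationError(f"annotation record {index}: {exc}") from exc
        raise AnnotationError(f"annotation record {index} is malformed: {exc!r}") from exc


def read_annotations(path) -> list[SliceAnnotation]:
    """Read a JSON annotation file (a list of per-slice records)."""
    with open(path) as fh:
        payload = json.load(fh)
    if not isinstance(payload, list):
        raise AnnotationError("annotation file must contain a JSON list")
    return [_annotation_from_record(rec, i) for i, rec in enumerate(payload)]


def write_annotations(annotations: Iterable[SliceAnnotation], path) -> None:
    with open(path, "w") as fh:
        json.dump([a.to_record() for a in annotations], fh, indent=1, sort_keys=True)


def lengths_table(annotations: Sequence[SliceAnnotation]):
    """Per-defect length table (one row per slice x annotated class)."""
    import pandas as pd

    rows = []
    for a in annotations:
        for d in a.defects:
            rows.append(
                {
                    "patient_id": a.patient_id,
                    "tooth_id": a.tooth_id,
                    "slice_index": a.slice_index,
                    "class": d.defect_class.value,
                    "length_mm": d.length_mm(a.pixel_pitch_mm),
                    "positive": a.slice_label(d.defect_class),
                }
            )
    return pd.DataFrame(rows)
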