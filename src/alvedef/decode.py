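"""Geometric decoding of the 12-channel prediction into detections and
diagnoses.

Decoding follows the heatmap-then-endpoints order: first the region carrying
a defect is localised (thresholded mask probability, or heatmap peaks), then
the two defect endpoints are recognised at its extremes, the endpoint
separation is converted to mm, and the clinical thresholds plus the
three-slice consensus rule turn lengths into per-slice and per-tooth labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .annotations import DefectClass, px_to_mm
from .encoder import HeatmapSpec

__all__ = [
    "Detection",
    "SliceResult",
    "ToothDiagnosis",
    "extract_endpoints",
    "decode_slice",
    "measure_length",
    "classify_slice",
    "diagnose_tooth",
]

logger = logging.getLogger(__name__)


@dataclass
class Detection:
    """One decoded defect on one slice: endpoint pair, mm length, confidence.

    ``p1``/``p2`` follow the class's role order, like annotations:
    (ARC, CEJ) for dehiscence, (CB, AB) for fenestration.
    """

    defect_class: DefectClass
    p1: np.ndarray  # (x, y)
    p2: np.ndarray
    length_mm: float
    score: float

    def __post_init__(self) -> None:
        self.p1 = np.asarray(self.p1, dtype=float)
        self.p2 = np.asarray(self.p2, dtype=float)
        if not 0.0 <= self.score <= 1.0:
            raise ValueError("score must lie in [0, 1]")

    def point_for_role(self, role: str) -> np.ndarray:
        roles = self.defect_class.roles
        if role == roles[0]:
            return self.p1
        if role == roles[1]:
            return self.p2
        raise KeyError(f"{self.defect_class} has roles {roles}, not {role!r}")


@dataclass
class SliceResult:
    """Per-slice decode outcome for all four classes."""

    detections: dict[DefectClass, Detection | None]
    labels: dict[DefectClass, bool]
    scores: dict[DefectClass, float]


@dataclass
class ToothDiagnosis:
    """Three-slice consensus diagnosis for one tooth."""

    slice_labels: dict[DefectClass, tuple[bool, bool, bool]]
    tooth_label: dict[DefectClass, bool]
    tooth_score: dict[DefectClass, float]

    def __post_init__(self) -> None:
        for c, labels in self.slice_labels.items():
            if self.tooth_label[c] != all(labels):
                raise ValueError("tooth_label must be the AND of the slice labels")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def _mean_direction(dx: np.ndarray, dy: np.ndarray, pixels: tuple[np.ndarray, np.ndarray]):
    rows, cols = pixels
    v = np.array([dx[rows, cols].mean(), dy[rows, cols].mean()])
    n = float(np.hypot(*v))
    if n < 1e-6:
        return None
    return v / n


def _principal_axis(rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    pts = np.stack([cols, rows], axis=1).astype(float)
    pts -= pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts, full_matrices=False)
    axis = vt[0]
    # orient toward the crown (decreasing y) as an anatomical tie-break
    return -axis if axis[1] > 0 else axis


def _assign_roles(
    defect_class: DefectClass, e_lo: np.ndarray, e_hi: np.ndarray, direction: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Order endpoints by role: ``direction`` points apical -> coronal, so the
    endpoint with the larger projection onto it takes the coronal role."""
    if (e_hi - e_lo) @ direction >= 0:
        apical, coronal = e_lo, e_hi
    else:
        apical, coronal = e_hi, e_lo
    if defect_class.roles[0] == defect_class.apical_role:
        return apical, coronal
    return coronal, apical


def extract_endpoints(
    group_channels: np.ndarray,
    defect_class: DefectClass,
    pixel_pitch_mm: float,
    mode: str = "mask_direction",
    mask_threshold: float = 0.5,
    from_logits: bool = True,
    heatmap_spec: HeatmapSpec | None = None,
) -> Detection | None:
    """Decode one channel group (3 channels) into a detection, or ``None``.

    Mask mode: pixels with mask probability >= ``mask_threshold`` form the
    candidate region; the largest connected component (row-major tie-break)
    is kept, its direction field is averaged to a unit vector, member pixels
    are projected onto that axis and the extreme-projection pixels become the
    endpoints; the score is the maximum mask probability.

    Heatmap mode: the two highest non-adjacent local maxima (non-maximum
    suppression radius ``2 sigma``) become the endpoints; the score is the
    higher peak normalised by the single-Gaussian peak value 1.

    An absent or degenerate (single-pixel) region yields ``None``.
    """
    loc, dx, dy = group_channels
    if mode == "mask_direction":
        prob = _sigmoid(loc) if from_logits else loc
        region = prob >= mask_threshold
        if not region.any():
            return None
        lab, n = ndimage.label(region, structure=np.ones((3, 3), dtype=int))
        if n == 0:
            return None
        sizes = np.bincount(lab.ravel())[1:]
        best = int(np.flatnonzero(sizes == sizes.max())[0]) + 1  # row-major tie-break
        rows, cols = np.nonzero(lab == best)
        if rows.size < 2:
            logger.debug("degenerate single-pixel detection for %s", defect_class)
            return None
        direction = _mean_direction(dx, dy, (rows, cols))
        if direction is None:
            direction = _principal_axis(rows, cols)
        proj = cols * direction[0] + rows * direction[1]
        # sub-pixel endpoints: lateral position from the whole-component line
        # fit (centroid + axis), longitudinal position from the extreme
        # projection band, plus a half-raster outward correction — this
        # cancels both the lateral spread of the band and the rasterisation
        # bias at its ends
        centroid = np.array([cols.mean(), rows.mean()])
        lo_band = proj <= proj.min() + 1.0
        hi_band = proj >= proj.max() - 1.0
        c_lo = np.array([cols[lo_band].mean(), rows[lo_band].mean()])
        c_hi = np.array([cols[hi_band].mean(), rows[hi_band].mean()])
        e_lo = centroid + direction * ((c_lo - centroid) @ direction - 0.25)
        e_hi = centroid + direction * ((c_hi - centroid) @ direction + 0.25)
        if np.allclose(e_lo, e_hi):
            logger.debug("degenerate detection (coincident endpoints) for %s", defect_class)
            return None
        score = float(prob[rows, cols].max())
        p1, p2 = _assign_roles(defect_class, e_lo, e_hi, direction)
    else:
        from skimage.feature import peak_local_max

        spec = heatmap_spec or HeatmapSpec()
        nms = max(1, int(np.ceil(2 * spec.sigma_px)))
        floor = max(0.05, mask_threshold * 0.2)
        peaks = peak_local_max(loc, min_distance=nms, threshold_abs=floor)
        if len(peaks) < 2:
            return None
        heights = loc[peaks[:, 0], peaks[:, 1]]
        order = np.argsort(-heights)[:2]
        (r0, c0), (r1, c1) = peaks[order[0]], peaks[order[1]]
        e_lo = np.array([c0, r0], dtype=float)
        e_hi = np.array([c1, r1], dtype=float)
        if np.allclose(e_lo, e_hi):
            return None
        direction = _mean_direction(dx, dy, (np.array([r0, r1]), np.array([c0, c1])))
        if direction is None:
            direction = _principal_axis(np.array([r0, r1]), np.array([c0, c1]))
        score = float(min(1.0, heights[order[0]]))
        p1, p2 = _assign_roles(defect_class, e_lo, e_hi, direction)
    length = measure_length(p1, p2, pixel_pitch_mm)
    return Detection(defect_class, p1, p2, length, score)


def measure_length(p1, p2, pixel_pitch_mm: float) -> float:
    """Euclidean endpoint distance converted to mm via the pixel pitch."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    return px_to_mm(float(np.hypot(*(p1 - p2))), pixel_pitch_mm)


def classify_slice(
    detections: dict[DefectClass, Detection | None],
    thresholds_mm: dict[DefectClass, float] | None = None,
) -> tuple[dict[DefectClass, bool], dict[DefectClass, float]]:
    """Threshold-based per-slice labels and confidence scores.

    Dehiscence is positive when its length strictly exceeds 2 mm,
    fenestration when it strictly exceeds 2.2 mm (overridable per class via
    ``thresholds_mm``); an absent detection is negative with score 0,
    otherwise the detection's score is passed through.
    """
    labels: dict[DefectClass, bool] = {}
    scores: dict[DefectClass, float] = {}
    for c in DefectClass:
        det = detections.get(c)
        threshold = (thresholds_mm or {}).get(c, c.threshold_mm)
        if det is None:
            labels[c], scores[c] = False, 0.0
        else:
            labels[c] = det.length_mm > threshold
            scores[c] = det.score
    return labels, scores


def decode_slice(
    prediction: np.ndarray,
    pixel_pitch_mm: float,
    mode: str = "mask_direction",
    mask_threshold: float | dict[DefectClass, float] = 0.5,
    from_logits: bool = True,
    heatmap_spec: HeatmapSpec | None = None,
    thresholds_mm: dict[DefectClass, float] | None = None,
) -> SliceResult:
    """Decode a full 12-channel prediction map into a :class:`SliceResult`.

    ``mask_threshold`` may be a single probability cut-off or a per-class
    mapping (e.g. from validation-split calibration).
    """
    if prediction.shape[0] != 12:
        raise ValueError("prediction must have 12 channels")
    if not isinstance(mask_threshold, dict):
        mask_threshold = {c: mask_threshold for c in DefectClass}
    detections = {
        c: extract_endpoints(
            prediction[3 * c.group : 3 * c.group + 3],
            c,
            pixel_pitch_mm,
            mode=mode,
            mask_threshold=mask_threshold.get(c, 0.5),
            from_logits=from_logits,
            heatmap_spec=heatmap_spec,
        )
        for c in DefectClass
    }
    labels, scores = classify_slice(detections, thresholds_mm)
    return SliceResult(detections, labels, scores)


def diagnose_tooth(slice_results: list[SliceResult]) -> ToothDiagnosis:
    """Three-slice consensus: a tooth is positive for a class only when all
    three slices are positive; the tooth score is the minimum slice score
    (mirroring the AND rule)."""
    if len(slice_results) != 3:
        raise ValueError(f"tooth diagnosis requires exactly 3 slices, got {len(slice_results)}")
    slice_labels: dict[DefectClass, tuple[bool, bool, bool]] = {}
    tooth_label: dict[DefectClass, bool] = {}
    tooth_score: dict[DefectClass, float] = {}
    for c in DefectClass:
        labels = tuple(r.labels[c] for r in slice_results)
        slice_labels[c] = labels  # type: ignore[assignment]
        tooth_label[c] = all(labels)
        tooth_score[c] = min(r.scores[c] for r in slice_results)
    return ToothDiagnosis(slice_labels, tooth_label, tooth_score)
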