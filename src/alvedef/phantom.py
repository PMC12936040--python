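"""Synthetic sagittal-slice phantom with annotated bone defects.

Real training data for this task are sagittal CBCT crops of single teeth in
which the cortical bone rim hugging the root surface is interrupted where a
dehiscence (crestal, V-shaped, measured ARC-to-CEJ) or fenestration
(window-like, measured CB-to-AB) is present.  The phantom renders that
contrast structure schematically: a tapered bright root with crown, a
surrounding cancellous bone slab, a bright cortical rim along the root
contour, and per-defect gaps in the rim whose ground-truth endpoints are
recorded in pixel coordinates.  It is deliberately not photorealistic — the
downstream pipeline consumes the root/rim intensity contrast, which the
schematic rendering provides.

Teeth come as triplets of consecutive slices (mesial, central, distal) with
small geometric jitter between slices; a tooth is positive for a class only
when all three slices exceed the clinical threshold, and the generator also
produces discordant teeth (two positive slices, one negative) so the
three-slice consensus rule is exercised.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .annotations import (
    DefectClass,
    LandmarkPair,
    SliceAnnotation,
    write_annotations,
)

__all__ = [
    "PhantomSpec",
    "SliceImage",
    "ToothSeries",
    "PhantomDataset",
    "generate_tooth_series",
    "generate_dataset",
    "write_dataset",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic slice generator.

    Defaults mirror the imaging regime the detector targets: 320 x 224 px
    sagittal crops at 0.25 mm pixel pitch, defect lengths spanning the
    2 mm / 2.2 mm decision thresholds.
    """

    image_height_px: int = 320
    image_width_px: int = 224
    pixel_pitch_mm: float = 0.25
    #: per-class probability that a tooth carries that defect (annotated,
    #: whether or not it exceeds the diagnostic threshold)
    class_prevalence: dict[DefectClass, float] = field(
        default_factory=lambda: {c: 0.35 for c in DefectClass}
    )
    #: interval the true endpoint separations are drawn from
    length_range_mm: tuple[float, float] = (0.5, 6.0)
    #: lengths are kept this far away from the class threshold so that
    #: sub-pixel quantisation cannot flip a slice label
    threshold_margin_mm: float = 0.4
    #: fraction of defect-bearing teeth rendered discordant: two slices above
    #: threshold, one below, making the tooth consensus-negative
    discordant_frac: float = 0.15
    noise_sd: float = 0.03  # additive Gaussian noise, fraction of intensity range
    blur_sigma_px: float = 0.7
    #: force these defects (class -> exact length in mm) on every tooth,
    #: overriding prevalence sampling; used for controlled experiments
    forced_defects: tuple[tuple[DefectClass, float], ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_height_px <= 0 or self.image_width_px <= 0:
            raise ValueError("image dimensions must be positive")
        if self.pixel_pitch_mm <= 0:
            raise ValueError("pixel_pitch_mm must be positive")
        for c, p in self.class_prevalence.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence of {c} must be in [0, 1], got {p}")
        lo, hi = self.length_range_mm
        if lo <= 0 or hi < lo:
            raise ValueError("length_range_mm must satisfy 0 < lo <= hi")


@dataclass
class SliceImage:
    """One rendered grayscale slice (8-bit intensities)."""

    pixels: np.ndarray  # (H, W) uint8
    pixel_pitch_mm: float

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.pixels.astype(float))):
            raise ValueError("slice intensities must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class ToothSeries:
    """Three consecutive annotated slices of one tooth (mesial to distal)."""

    patient_id: str
    tooth_id: str
    slices: list[tuple[SliceImage, SliceAnnotation]]
    #: the generator's intended tooth-level label per class
    intended_labels: dict[DefectClass, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.slices) != 3:
            raise ValueError("a tooth series holds exactly 3 slices")
        shapes = {img.shape for img, _ in self.slices}
        pitches = {img.pixel_pitch_mm for img, _ in self.slices}
        if len(shapes) != 1 or len(pitches) != 1:
            raise ValueError("all slices of a series share dimensions and pixel pitch")

    @property
    def annotations(self) -> list[SliceAnnotation]:
        return [ann for _, ann in self.slices]

    def derived_labels(self) -> dict[DefectClass, bool]:
        """Tooth labels derived from stored lengths and the thresholds."""
        return {
            c: all(ann.slice_label(c) for ann in self.annotations) for c in DefectClass
        }


@dataclass
class PhantomDataset:
    series: list[ToothSeries]
    spec: PhantomSpec
    seed: int

    def manifest(self):
        import pandas as pd

        rows = []
        for s in self.series:
            row = {"patient_id": s.patient_id, "tooth_id": s.tooth_id}
            for c in DefectClass:
                row[f"label_{c.value}"] = s.intended_labels.get(c, False)
            rows.append(row)
        return pd.DataFrame(rows)

    @property
    def patient_ids(self) -> list[str]:
        return sorted({s.patient_id for s in self.series})


# ---------------------------------------------------------------------------
# geometry helpers

# rendered intensities (8-bit)
_I_BACKGROUND = 25
_I_BONE = 110
_I_ROOT = 185
_I_CROWN = 230
_I_RIM = 255


class _Geometry:
    """Per-slice schematic tooth geometry in pixel coordinates."""

    def __init__(self, h: int, w: int, rng: np.random.Generator):
        j = lambda s: float(rng.uniform(-s, s))  # noqa: E731
        self.h, self.w = h, w
        self.cx = w / 2 + j(0.02 * w)
        self.y_cej = 0.24 * h + j(0.01 * h)
        self.y_apex = 0.84 * h + j(0.01 * h)
        self.w_top = 0.11 * w + j(1.0)
        self.w_tip = max(2.0, 0.02 * w)
        self.y_crown = max(3.0, self.y_cej - 0.16 * h)

    def contour(self, buccal: bool) -> tuple[np.ndarray, np.ndarray, float]:
        """Start point (CEJ level), unit direction and length of one side's
        root contour.  The buccal side is rendered on the left."""
        sign = -1.0 if buccal else 1.0
        a = np.array([self.cx + sign * self.w_top, self.y_cej])
        b = np.array([self.cx + sign * self.w_tip, self.y_apex])
        u = b - a
        length = float(np.hypot(*u))
        return a, u / length, length


def _sample_length_mm(
    rng: np.random.Generator, spec: PhantomSpec, sign: int | None, threshold: float
) -> float:
    """Draw a defect length avoiding the margin band around the threshold.

    ``sign`` +1 forces above-threshold, -1 below, None draws from the union
    of both admissible intervals in proportion to their measure.
    """
    lo, hi = spec.length_range_mm
    m = spec.threshold_margin_mm
    below = (lo, min(hi, threshold - m))
    above = (max(lo, threshold + m), hi)
    below_len = max(0.0, below[1] - below[0])
    above_len = max(0.0, above[1] - above[0])
    if sign is None:
        if below_len + above_len <= 0:
            raise ValueError("length_range_mm leaves no admissible lengths")
        sign = 1 if rng.uniform(0, below_len + above_len) < above_len else -1
    interval = above if sign > 0 else below
    if interval[1] <= interval[0]:
        interval = above if above_len > 0 else below
    return float(rng.uniform(*interval))


def _plan_tooth(
    rng: np.random.Generator, spec: PhantomSpec
) -> tuple[dict[DefectClass, list[float | None]], dict[DefectClass, bool]]:
    """Decide per class which slices carry a defect and at what length.

    Returns per-class lists of 3 lengths (None = no defect on that slice)
    and the intended tooth-level labels.
    """
    plan: dict[DefectClass, list[float | None]] = {}
    labels: dict[DefectClass, bool] = {}
    forced = dict(spec.forced_defects or ())
    for c in DefectClass:
        if c in forced:
            length = float(forced[c])
            plan[c] = [length, length, length]
            labels[c] = length > c.threshold_mm
            continue
        if rng.uniform() >= spec.class_prevalence.get(c, 0.0):
            plan[c] = [None, None, None]
            labels[c] = False
            continue
        if rng.uniform() < spec.discordant_frac:
            pos = _sample_length_mm(rng, spec, +1, c.threshold_mm)
            neg = _sample_length_mm(rng, spec, -1, c.threshold_mm)
            lengths: list[float | None] = [pos, pos, neg]
            rng.shuffle(lengths)
            plan[c] = lengths
            labels[c] = False
        else:
            length = _sample_length_mm(rng, spec, None, c.threshold_mm)
            plan[c] = [length, length, length]
            labels[c] = length > c.threshold_mm
    return plan, labels


class _FitError(Exception):
    """A planned defect does not fit this tooth's root contour."""

    def __init__(self, defect_class: DefectClass):
        self.defect_class = defect_class


def _place_defects(
    geo: _Geometry,
    plan_slice: dict[DefectClass, float | None],
    spec: PhantomSpec,
    rng: np.random.Generator,
) -> list[LandmarkPair]:
    """Place each planned defect's endpoints on the root contour."""
    pitch = spec.pixel_pitch_mm
    pairs: list[LandmarkPair] = []
    # crest offset along the contour, per side (set by the dehiscence if any)
    crest_t = {True: 0.0, False: 0.0}  # keyed by `buccal`
    for c in (DefectClass.BUCCAL_DEHISCENCE, DefectClass.LINGUAL_DEHISCENCE):
        length = plan_slice.get(c)
        if length is None:
            continue
        a, u, contour_len = geo.contour(c.is_buccal)
        l_px = length / pitch
        if l_px > contour_len - 4:
            raise _FitError(c)
        arc = a + u * l_px
        pairs.append(LandmarkPair(c, arc, a.copy()))  # roles (ARC, CEJ)
        crest_t[c.is_buccal] = l_px
    for c in (DefectClass.BUCCAL_FENESTRATION, DefectClass.LINGUAL_FENESTRATION):
        length = plan_slice.get(c)
        if length is None:
            continue
        a, u, contour_len = geo.contour(c.is_buccal)
        l_px = length / pitch
        t_min = crest_t[c.is_buccal] + 5.0
        t_max = contour_len - 4.0 - l_px
        if t_max <= t_min:
            raise _FitError(c)
        t0 = float(rng.uniform(t_min, t_max))
        cb = a + u * t0
        ab = a + u * (t0 + l_px)
        pairs.append(LandmarkPair(c, cb, ab))  # roles (CB, AB)
    return pairs


def _band_mask(shape: tuple[int, int], p1, p2, radius: float) -> np.ndarray:
    """Pixels within `radius` of the segment p1-p2, truncated at the segment
    ends, so the region's longitudinal extent equals the endpoint distance
    (the window borders are the annotated endpoints)."""
    h, w = shape
    ys, xs = np.mgrid[0:h, 0:w]
    p = np.stack([xs, ys], axis=-1).astype(float)
    d = np.asarray(p2, float) - np.asarray(p1, float)
    length = float(np.hypot(*d))
    u = d / length
    rel = p - np.asarray(p1, float)
    lon = rel @ u
    lat = np.abs(rel @ np.array([-u[1], u[0]]))
    return (lat <= radius) & (lon >= 0.0) & (lon <= length)


def _render_slice(
    geo: _Geometry,
    pairs: list[LandmarkPair],
    spec: PhantomSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    from skimage.draw import polygon as _polygon
    from skimage.morphology import dilation, disk

    h, w = geo.h, geo.w
    canvas = np.full((h, w), float(_I_BACKGROUND))
    ys, xs = np.mgrid[0:h, 0:w]

    # root + crown polygons
    a_l, u_l, len_l = geo.contour(True)
    a_r, u_r, len_r = geo.contour(False)
    tip_l, tip_r = a_l + u_l * len_l, a_r + u_r * len_r
    root_poly_x = [a_l[0], a_r[0], tip_r[0], geo.cx, tip_l[0]]
    root_poly_y = [a_l[1], a_r[1], tip_r[1], geo.y_apex + 3, tip_l[1]]
    rr, cc = _polygon(root_poly_y, root_poly_x, shape=(h, w))
    root = np.zeros((h, w), dtype=bool)
    root[rr, cc] = True
    crown_x = [a_l[0] + 1, a_r[0] - 1, geo.cx + 0.6 * geo.w_top, geo.cx - 0.6 * geo.w_top]
    crown_y = [geo.y_cej, geo.y_cej, geo.y_crown, geo.y_crown]
    rr, cc = _polygon(crown_y, crown_x, shape=(h, w))
    crown = np.zeros((h, w), dtype=bool)
    crown[rr, cc] = True

    # per-side crest level: the ARC of a dehiscence lowers it from the CEJ
    crest_y = {True: geo.y_cej + 1.5, False: geo.y_cej + 1.5}
    for p in pairs:
        if p.defect_class.is_dehiscence:
            crest_y[p.defect_class.is_buccal] = float(p.apical_point[1])
    side_is_buccal = xs < geo.cx
    below_crest = np.where(side_is_buccal, ys >= crest_y[True], ys >= crest_y[False])

    rim_band = dilation(root, disk(2)) & ~root
    bone = below_crest & ~dilation(root, disk(4)) & (ys <= geo.y_apex + 8)
    rim = rim_band & below_crest

    # fenestration windows: carve rim and bone along the CB-AB segment; the
    # window's coronal/apical borders sit exactly at the annotated endpoints
    for p in pairs:
        if not p.defect_class.is_dehiscence:
            hole = _band_mask((h, w), p.p1, p.p2, radius=3.0)
            rim &= ~hole
            bone &= ~hole

    canvas[bone] = _I_BONE
    canvas[root] = _I_ROOT
    canvas[crown] = _I_CROWN
    canvas[rim] = _I_RIM

    if spec.blur_sigma_px and spec.blur_sigma_px > 0:
        canvas = gaussian_filter(canvas, spec.blur_sigma_px)
    if spec.noise_sd and spec.noise_sd > 0:
        canvas = canvas + rng.normal(0.0, spec.noise_sd * 255.0, size=canvas.shape)
    return np.clip(canvas, 0, 255).astype(np.uint8)


def _check_sizing(spec: PhantomSpec) -> None:
    # worst-case contour length on the default geometry, minus placement slack
    h, w = spec.image_height_px, spec.image_width_px
    contour_px = np.hypot(0.09 * w, 0.60 * h) - 6
    if spec.length_range_mm[1] / spec.pixel_pitch_mm > contour_px:
        raise ValueError(
            f"length_range_mm upper bound {spec.length_range_mm[1]} mm exceeds the "
            f"~{contour_px * spec.pixel_pitch_mm:.1f} mm root contour of a "
            f"{h}x{w} px image at {spec.pixel_pitch_mm} mm/px"
        )


def generate_tooth_series(
    spec: PhantomSpec,
    rng: np.random.Generator,
    patient_id: str = "P000",
    tooth_id: str = "P000_T00",
) -> ToothSeries:
    """Render one annotated three-slice tooth series.

    The three slices share the tooth's defect plan (same classes, same
    lengths unless the tooth was drawn discordant) but differ by small
    geometric jitter.  Stored endpoints lie exactly on the rendered root
    contour, so the recorded mm length equals the Euclidean endpoint
    distance times the pixel pitch by construction.
    """
    _check_sizing(spec)
    plan, labels = _plan_tooth(rng, spec)
    forced = {c for c, _ in (spec.forced_defects or ())}
    # place the three slices; a class whose defect cannot fit this tooth's
    # contour (e.g. a long fenestration under a deep dehiscence) is dropped
    # from the whole tooth so slice and tooth labels stay consistent
    while True:
        geos = [_Geometry(spec.image_height_px, spec.image_width_px, rng) for _ in range(3)]
        try:
            placed = [
                _place_defects(geo, {c: plan[c][i] for c in DefectClass}, spec, rng)
                for i, geo in enumerate(geos)
            ]
        except _FitError as err:
            if err.defect_class in forced:
                raise ValueError(
                    f"forced {err.defect_class.value} does not fit the root contour; "
                    "enlarge the image or shorten the defect"
                ) from err
            plan[err.defect_class] = [None, None, None]
            labels[err.defect_class] = False
            continue
        break
    slices: list[tuple[SliceImage, SliceAnnotation]] = []
    for slice_index in range(3):
        geo = geos[slice_index]
        pairs = placed[slice_index]
        pixels = _render_slice(geo, pairs, spec, rng)
        ann = SliceAnnotation(
            patient_id=patient_id,
            tooth_id=tooth_id,
            slice_index=slice_index,
            pixel_pitch_mm=spec.pixel_pitch_mm,
            defects=pairs,
        )
        for p in pairs:
            p.validate_bounds(pixels.shape)
        slices.append((SliceImage(pixels, spec.pixel_pitch_mm), ann))
    return ToothSeries(patient_id, tooth_id, slices, intended_labels=labels)


def generate_dataset(
    n_patients: int,
    teeth_per_patient: int,
    spec: PhantomSpec,
    seed: int | None = None,
) -> PhantomDataset:
    """Generate ``n_patients x teeth_per_patient`` tooth series.

    Patient ids are unique; every tooth belongs to exactly one patient.  The
    dataset is a deterministic function of ``(spec, seed)``.
    """
    if n_patients < 1 or teeth_per_patient < 1:
        raise ValueError("n_patients and teeth_per_patient must be >= 1")
    seed = spec.seed if seed is None else seed
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_patients * teeth_per_patient)
    series = []
    k = 0
    for p in range(n_patients):
        patient_id = f"P{p:04d}"
        for t in range(teeth_per_patient):
            rng = np.random.default_rng(children[k])
            k += 1
            series.append(
                generate_tooth_series(spec, rng, patient_id, f"{patient_id}_T{t:02d}")
            )
    return PhantomDataset(series=series, spec=spec, seed=seed)


def write_dataset(dataset: PhantomDataset, out_dir) -> None:
    """Write PNG slices, a JSON annotation file and a CSV manifest."""
    from PIL import Image

    out = Path(out_dir)
    img_dir = out / "images"
    img_dir.mkdir(parents=True, exist_ok=True)
    annotations = []
    for s in dataset.series:
        for img, ann in s.slices:
            Image.fromarray(img.pixels, mode="L").save(
                img_dir / f"{s.tooth_id}_s{ann.slice_index}.png"
            )
            annotations.append(ann)
    write_annotations(annotations, out / "annotations.json")
    dataset.manifest().to_csv(out / "manifest.csv", index=False)
    meta = {
        "seed": dataset.seed,
        "n_series": len(dataset.series),
        "image_height_px": dataset.spec.image_height_px,
        "image_width_px": dataset.spec.image_width_px,
        "pixel_pitch_mm": dataset.spec.pixel_pitch_mm,
    }
    (out / "dataset.json").write_text(json.dumps(meta, indent=1, sort_keys=True))
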