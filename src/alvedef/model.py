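"""Model/Results interface tying the pipeline together.

:class:`DefectDetector` is built from an annotated slice dataset plus the
architecture and optimization configs; ``fit()`` trains the Swin-UNETR
landmark network on the patient-level training split and returns a
:class:`DetectorResults` carrying the fitted weights, the training history
and the evaluation machinery (per-slice prediction, three-slice consensus
diagnosis, and the full metric report with a ``summary()`` table).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .annotations import DefectClass, SliceAnnotation
from .decode import SliceResult, ToothDiagnosis, decode_slice, diagnose_tooth
from .metrics import (
    ConfusionCounts,
    bland_altman,
    classification_stats,
    keypoint_stats,
    length_stats,
    match_keypoints,
    roc_auc,
)
from .nn import NetConfig, no_grad
from .phantom import PhantomDataset, PhantomSpec, ToothSeries, generate_dataset
from .train import SplitSpec, TrainConfig, TrainResult, split_patients, standardize, train_model

__all__ = ["DefectDetector", "DetectorResults"]


def _series_slices(series_list: list[ToothSeries]):
    return [pair for s in series_list for pair in s.slices]


class DefectDetector:
    """Alveolar bone dehiscence/fenestration detector.

    Parameters
    ----------
    series
        Annotated three-slice tooth series (e.g. a phantom dataset's
        ``.series``).
    net_config, train_config
        Architecture and optimization settings; defaults are the full-size
        model and the reference training schedule.
    split_ratios, split_seed
        Patient-level train/val/test proportions (default 7:2:1).
    """

    def __init__(
        self,
        series: list[ToothSeries] | PhantomDataset,
        net_config: NetConfig | None = None,
        train_config: TrainConfig | None = None,
        split_ratios: tuple[float, float, float] = (7, 2, 1),
        split_seed: int | None = None,
    ):
        self.series = series.series if isinstance(series, PhantomDataset) else list(series)
        if not self.series:
            raise ValueError("empty dataset")
        self.net_config = net_config or NetConfig()
        self.train_config = train_config or TrainConfig()
        seed = self.train_config.seed if split_seed is None else split_seed
        patient_ids = sorted({s.patient_id for s in self.series})
        self.split: SplitSpec = split_patients(patient_ids, split_ratios, seed)

    @classmethod
    def from_phantom(
        cls,
        n_patients: int,
        teeth_per_patient: int,
        phantom_spec: PhantomSpec | None = None,
        seed: int = 0,
        **kwargs,
    ) -> "DefectDetector":
        """Build the detector on a freshly generated phantom dataset."""
        spec = phantom_spec or PhantomSpec()
        dataset = generate_dataset(n_patients, teeth_per_patient, spec, seed=seed)
        return cls(dataset, **kwargs)

    def subset(self, name: str) -> list[ToothSeries]:
        wanted = set(self.split.patients(name))
        return [s for s in self.series if s.patient_id in wanted]

    def fit(self) -> "DetectorResults":
        """Train the network and return the fitted results object."""
        train_result = train_model(
            _series_slices(self.subset("train")),
            self.net_config,
            self.train_config,
            val_data=_series_slices(self.subset("val")),
        )
        train_result.restore_best()
        return DetectorResults(self, train_result)


@dataclass
class _PredictionSettings:
    mask_threshold: float = 0.5
    recognition_tolerance_mm: float = 2.0


class DetectorResults:
    """Fitted detector: weights, history, prediction and evaluation."""

    def __init__(
        self,
        model: DefectDetector,
        train_result: TrainResult,
        settings: _PredictionSettings | None = None,
    ):
        self.model = model
        self.net = train_result.model
        self.history = train_result.history
        self.train_result = train_result
        self.settings = settings or _PredictionSettings()

    # -- prediction --------------------------------------------------------
    def predict_slices(self, images: list[np.ndarray], pixel_pitch_mm: float) -> list[SliceResult]:
        """Run the network and geometric decoding on raw grayscale slices."""
        cfg = self.model.train_config
        batch = np.stack([standardize(np.asarray(img, dtype=np.float32)) for img in images])
        with no_grad():
            pred = self.net(batch).data
        return [
            decode_slice(
                pred[i],
                pixel_pitch_mm,
                mode=cfg.landmark_mode,
                mask_threshold=self.settings.mask_threshold,
                from_logits=(cfg.landmark_mode == "mask_direction"),
                heatmap_spec=cfg.heatmap_spec,
            )
            for i in range(len(images))
        ]

    def predict_series(self, series: ToothSeries) -> tuple[list[SliceResult], ToothDiagnosis]:
        images = [img.pixels for img, _ in series.slices]
        results = self.predict_slices(images, series.slices[0][0].pixel_pitch_mm)
        return results, diagnose_tooth(results)

    def calibrate_mask_threshold(
        self,
        thresholds=(0.15, 0.25, 0.35, 0.5),
        subset: str = "val",
        batch_size: int = 16,
    ) -> dict[DefectClass, float]:
        """Pick per-class mask probability cut-offs on the validation split.

        For each defect class the candidate threshold maximising, in order,
        that class's slice accuracy, its endpoint recognition rate (at the
        configured tolerance) and the smaller length error is selected, with
        remaining ties broken toward the default 0.5.  Candidates never
        exceed the 0.5 default: raising the cut-off above the decision
        boundary silently drops low-confidence detections of small defects,
        and missed defects cost more than the marginal length-error gain
        (sensitivity first).  The chosen mapping is stored in
        ``settings.mask_threshold`` and returned.  The test split is never
        touched.
        """
        series = self.model.subset(subset)
        if not series:
            raise ValueError(f"no series in subset {subset!r}")
        cfg = self.model.train_config
        pitch = series[0].slices[0][0].pixel_pitch_mm
        images = [img.pixels for s in series for img, _ in s.slices]
        annotations = [ann for s in series for _, ann in s.slices]
        preds = []
        for i in range(0, len(images), batch_size):
            batch = np.stack(
                [standardize(np.asarray(im, dtype=np.float32)) for im in images[i : i + batch_size]]
            )
            with no_grad():
                preds.append(self.net(batch).data)
        preds = np.concatenate(preds, axis=0)
        n = len(annotations)
        tol = self.settings.recognition_tolerance_mm
        # score every (threshold, class) pair in one decoding pass per threshold
        best: dict[DefectClass, tuple] = {}
        for thr in thresholds:
            correct = {c: 0 for c in DefectClass}
            abs_err = {c: [] for c in DefectClass}
            recognized = {c: 0 for c in DefectClass}
            n_truth = {c: 0 for c in DefectClass}
            for pred, ann in zip(preds, annotations):
                res = decode_slice(
                    pred,
                    pitch,
                    mode=cfg.landmark_mode,
                    mask_threshold=thr,
                    from_logits=(cfg.landmark_mode == "mask_direction"),
                    heatmap_spec=cfg.heatmap_spec,
                )
                for c in DefectClass:
                    if res.labels[c] == ann.slice_label(c):
                        correct[c] += 1
                    det, pair = res.detections[c], ann.get(c)
                    if pair is not None:
                        n_truth[c] += 2
                    if det is not None and pair is not None:
                        abs_err[c].append(abs(det.length_mm - pair.length_mm(pitch)))
                        for role, truth in zip(c.roles, (pair.p1, pair.p2)):
                            d = np.hypot(*(det.point_for_role(role) - truth)) * pitch
                            recognized[c] += int(d <= tol)
            for c in DefectClass:
                mae = float(np.mean(abs_err[c])) if abs_err[c] else np.inf
                rate = recognized[c] / n_truth[c] if n_truth[c] else 0.0
                key = (correct[c] / n, rate, -mae, -abs(thr - 0.5))
                if c not in best or key > best[c][0]:
                    best[c] = (key, thr)
        chosen = {c: float(best[c][1]) for c in DefectClass}
        self.settings.mask_threshold = chosen
        return chosen

    # -- evaluation --------------------------------------------------------
    def evaluate(
        self,
        subset: str = "test",
        series: list[ToothSeries] | None = None,
        tolerance_mm: float | None = None,
        batch_size: int = 16,
    ) -> dict:
        """Full evaluation report on a subset (default: held-out test split).

        Covers, per defect class: endpoint recognition rate and distance
        statistics (with a tolerance sweep), length agreement (MAE/RMSE/MRE/
        PCC and Bland–Altman), and detection performance at slice and tooth
        level (accuracy, recall, precision, specificity, F1, AUC).
        """
        series = self.model.subset(subset) if series is None else series
        if not series:
            raise ValueError(f"no series in subset {subset!r}")
        tol = tolerance_mm or self.settings.recognition_tolerance_mm
        per_slice: list[tuple[SliceAnnotation, SliceResult]] = []
        per_tooth: list[tuple[ToothSeries, ToothDiagnosis]] = []
        # batch across teeth for throughput
        pitch = series[0].slices[0][0].pixel_pitch_mm
        all_images = [img.pixels for s in series for img, _ in s.slices]
        results: list[SliceResult] = []
        for i in range(0, len(all_images), batch_size):
            results.extend(self.predict_slices(all_images[i : i + batch_size], pitch))
        k = 0
        for s in series:
            triplet = results[k : k + 3]
            k += 3
            for (_, ann), res in zip(s.slices, triplet):
                per_slice.append((ann, res))
            per_tooth.append((s, diagnose_tooth(triplet)))
        return build_report(per_slice, per_tooth, pitch, tol)

    def summary(self, subset: str = "test") -> str:
        """statsmodels-style text summary of the held-out evaluation."""
        report = self.evaluate(subset)
        lines = [
            "Alveolar defect detection - Swin-UNETR landmark model",
            "=" * 72,
            f"parameters: {self.net.n_parameters():,}   "
            f"epochs: {len(self.history)}   subset: {subset}",
            f"teeth: {report['n_teeth']}   slices: {report['n_slices']}   "
            f"recognition tolerance: {report['tolerance_mm']} mm",
            "-" * 72,
            f"{'metric':<24}" + "".join(f"{c.value[:14]:>15}" for c in DefectClass),
        ]

        def row(name, getter, fmt="{:.4f}"):
            vals = []
            for c in DefectClass:
                v = getter(report["classes"][c.value])
                vals.append("   --" .rjust(15) if v is None else fmt.format(v).rjust(15))
            lines.append(f"{name:<24}" + "".join(vals))

        row("recognition rate", lambda d: d["keypoints"]["recognition_rate"])
        row("AED (mm)", lambda d: d["keypoints"]["aed_mm"])
        row("median dist (mm)", lambda d: d["keypoints"]["median_mm"])
        row("length MAE (mm)", lambda d: d["lengths"]["mae"])
        row("length PCC", lambda d: d["lengths"]["pcc"])
        row("BA bias (mm)", lambda d: d["agreement"]["bias"])
        row("slice accuracy", lambda d: d["slice_detection"]["accuracy"])
        row("slice recall", lambda d: d["slice_detection"]["recall"])
        row("slice AUC", lambda d: d["slice_detection"]["auc"])
        row("tooth accuracy", lambda d: d["tooth_detection"]["accuracy"])
        row("tooth AUC", lambda d: d["tooth_detection"]["auc"])
        lines.append("=" * 72)
        return "\n".join(lines)

    def save(self, path) -> None:
        self.net.save(path)


# ---------------------------------------------------------------------------
# report assembly


def _safe(v):
    return None if v is None or (isinstance(v, float) and not np.isfinite(v)) else float(v)


def build_report(
    per_slice: list[tuple[SliceAnnotation, SliceResult]],
    per_tooth: list[tuple[ToothSeries, ToothDiagnosis]],
    pixel_pitch_mm: float,
    tolerance_mm: float,
    tolerance_sweep=(0.5, 1.0, 2.0, 3.0, 4.0),
) -> dict:
    """Assemble the evaluation report from decoded predictions."""
    report: dict = {
        "n_slices": len(per_slice),
        "n_teeth": len(per_tooth),
        "tolerance_mm": tolerance_mm,
        "classes": {},
    }
    for c in DefectClass:
        truth_points, pred_points = [], []
        true_len, pred_len = [], []
        slice_truth, slice_pred, slice_scores = [], [], []
        for idx, (ann, res) in enumerate(per_slice):
            det = res.detections.get(c)
            pair = ann.get(c)
            if pair is not None:
                for role in c.roles:
                    p = pair.apical_point if role == c.apical_role else pair.coronal_point
                    truth_points.append(
                        ((idx, role), p[0] * pixel_pitch_mm, p[1] * pixel_pitch_mm)
                    )
            if det is not None:
                for role in c.roles:
                    q = det.point_for_role(role)
                    pred_points.append(
                        ((idx, role), q[0] * pixel_pitch_mm, q[1] * pixel_pitch_mm)
                    )
            if pair is not None and det is not None:
                true_len.append(pair.length_mm(ann.pixel_pitch_mm))
                pred_len.append(det.length_mm)
            slice_truth.append(ann.slice_label(c))
            slice_pred.append(res.labels[c])
            slice_scores.append(res.scores[c])

        entry: dict = {}
        rate, dists = match_keypoints(pred_points, truth_points, tolerance_mm)
        if dists.size:
            ks = keypoint_stats(dists, rate, len(truth_points))
            entry["keypoints"] = {
                "recognition_rate": rate,
                "aed_mm": ks.aed_mm,
                "sd_mm": ks.sd_mm,
                "q1_mm": ks.q1_mm,
                "median_mm": ks.median_mm,
                "q3_mm": ks.q3_mm,
                "n_recognized": ks.n_recognized,
                "n_truth": ks.n_truth,
            }
        else:
            entry["keypoints"] = {
                "recognition_rate": rate,
                "aed_mm": None,
                "sd_mm": None,
                "q1_mm": None,
                "median_mm": None,
                "q3_mm": None,
                "n_recognized": 0,
                "n_truth": len(truth_points),
            }
        entry["keypoints"]["tolerance_sweep"] = {
            str(t): match_keypoints(pred_points, truth_points, t)[0] for t in tolerance_sweep
        }
        if len(true_len) >= 2:
            ls = length_stats(pred_len, true_len)
            ba = bland_altman(pred_len, true_len)
            entry["lengths"] = {
                "mae": ls.mae,
                "rmse": ls.rmse,
                "mre": ls.mre,
                "pcc": _safe(ls.pcc),
                "n": ls.n,
            }
            entry["agreement"] = {
                "bias": ba.bias,
                "loa_low": ba.loa_low,
                "loa_high": ba.loa_high,
            }
        else:
            entry["lengths"] = {"mae": None, "rmse": None, "mre": None, "pcc": None, "n": len(true_len)}
            entry["agreement"] = {"bias": None, "loa_low": None, "loa_high": None}
        entry["slice_detection"] = _detection_block(slice_truth, slice_pred, slice_scores)
        tooth_truth = [all(a.slice_label(c) for a in s.annotations) for s, _ in per_tooth]
        tooth_pred = [d.tooth_label[c] for _, d in per_tooth]
        tooth_scores = [d.tooth_score[c] for _, d in per_tooth]
        entry["tooth_detection"] = _detection_block(tooth_truth, tooth_pred, tooth_scores)
        report["classes"][c.value] = entry
    return report


def _detection_block(truth, pred, scores) -> dict:
    counts = ConfusionCounts.from_labels(pred, truth)
    block = dict(classification_stats(counts))
    block.update(tp=counts.tp, tn=counts.tn, fp=counts.fp, fn=counts.fn)
    truth_arr = np.asarray(truth, dtype=bool)
    if truth_arr.any() and not truth_arr.all():
        curve, auc = roc_auc(np.asarray(scores, dtype=float), truth_arr)
        block["auc"] = auc
        block["roc_points"] = [[float(a), float(b)] for a, b in curve]
    else:
        block["auc"] = None
        block["roc_points"] = None
    return block


def report_to_json(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)


def report_tables(report: dict):
    """Metric-by-class tables (one DataFrame per metric family)."""
    import pandas as pd

    tables = {}
    for family, keys in {
        "keypoints": ["recognition_rate", "aed_mm", "sd_mm", "q1_mm", "median_mm", "q3_mm"],
        "lengths": ["mae", "rmse", "mre", "pcc"],
        "agreement": ["bias", "loa_low", "loa_high"],
        "slice_detection": ["accuracy", "recall", "precision", "specificity", "f1", "auc"],
        "tooth_detection": ["accuracy", "recall", "precision", "specificity", "f1", "auc"],
    }.items():
        data = {
            c.value: [report["classes"][c.value][family].get(k) for k in keys]
            for c in DefectClass
        }
        tables[family] = pd.DataFrame(data, index=keys)
    return tables
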