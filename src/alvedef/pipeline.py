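"""End-to-end reproducible pipeline: generate -> split -> train -> predict
-> decode -> evaluate, driven by a single YAML configuration.

Every stage's randomness is derived from one master seed; the output
directory receives the evaluation report (JSON + CSV tables), per-slice
detections, ROC points, Bland–Altman and overlay figures, and a manifest
with the config hash so a run can be reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .annotations import DefectClass
from .encoder import HeatmapSpec
from .model import DefectDetector, DetectorResults, report_tables, report_to_json
from .nn import NetConfig
from .phantom import PhantomSpec, generate_dataset, write_dataset
from .train import AugmentSpec, TrainConfig

__all__ = ["PipelineConfig", "run_pipeline", "PipelineError"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Everything one run needs: data source, model, training, thresholds."""

    output_dir: str = "alvedef_run"
    dataset_dir: str | None = None  # load instead of generating when set
    n_patients: int = 60
    teeth_per_patient: int = 2
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    net: NetConfig = field(default_factory=NetConfig.tiny)
    train: TrainConfig = field(default_factory=TrainConfig)
    split_ratios: tuple[float, float, float] = (7, 2, 1)
    dehiscence_threshold_mm: float = 2.0
    fenestration_threshold_mm: float = 2.2
    recognition_tolerance_mm: float = 2.0
    #: pick the mask probability cut-off on the validation split after
    #: training (the default 0.5 is used when disabled)
    calibrate_mask_threshold: bool = True
    master_seed: int = 0
    write_images: bool = False
    write_figures: bool = True

    def __post_init__(self) -> None:
        if self.dehiscence_threshold_mm <= 0 or self.fenestration_threshold_mm <= 0:
            raise ValueError("diagnostic thresholds must be positive")
        if self.dataset_dir is None and self.n_patients < 3:
            raise ValueError("need >= 3 phantom patients for a 3-way split")

    # -- (de)serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["phantom"]["class_prevalence"] = {
            c.value: p for c, p in self.phantom.class_prevalence.items()
        }
        if self.phantom.forced_defects:
            d["phantom"]["forced_defects"] = [
                [c.value, l] for c, l in self.phantom.forced_defects
            ]
        return d

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        if "phantom" in raw:
            ph = dict(raw["phantom"])
            if "class_prevalence" in ph:
                ph["class_prevalence"] = {
                    DefectClass(k): float(v) for k, v in ph["class_prevalence"].items()
                }
            if ph.get("forced_defects"):
                ph["forced_defects"] = tuple(
                    (DefectClass(c), float(l)) for c, l in ph["forced_defects"]
                )
            if "length_range_mm" in ph:
                ph["length_range_mm"] = tuple(ph["length_range_mm"])
            raw["phantom"] = PhantomSpec(**ph)
        if "net" in raw:
            nt = dict(raw["net"])
            for k in ("depths", "num_heads"):
                if k in nt:
                    nt[k] = tuple(nt[k])
            raw["net"] = NetConfig(**nt)
        if "train" in raw:
            tr = dict(raw["train"])
            if isinstance(tr.get("augment_spec"), dict):
                tr["augment_spec"] = AugmentSpec(
                    **{k: tuple(v) for k, v in tr["augment_spec"].items()}
                )
            if isinstance(tr.get("heatmap_spec"), dict):
                tr["heatmap_spec"] = HeatmapSpec(**tr["heatmap_spec"])
            raw["train"] = TrainConfig(**tr)
        if "split_ratios" in raw:
            raw["split_ratios"] = tuple(raw["split_ratios"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        import yaml

        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def scaled_study_config(seed: int = 0, output_dir: str = "scaled_study") -> PipelineConfig:
    """The package's reference scaled-down end-to-end study.

    Tiny network, 180 phantom teeth (540 slices) at 96 x 64 px, patient-level
    7:2:1 split, 32 epochs with 2 warmup epochs — sized so the whole study
    (generate, train,
    calibrate, evaluate) completes on a single CPU in minutes while keeping
    every stage of the full pipeline exercised.
    """
    return PipelineConfig(
        output_dir=output_dir,
        n_patients=90,
        teeth_per_patient=2,
        phantom=PhantomSpec(image_height_px=96, image_width_px=64),
        net=NetConfig.tiny(),
        train=TrainConfig(
            epochs=32,
            warmup_epochs=2,
            initial_lr=3e-3,
            batch_size=8,
            seed=seed,
            bce_pos_weight=5.0,
            augment_spec=AugmentSpec(),
        ),
        master_seed=seed,
    )


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                logger.info("stage %s ...", name)
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - reported with stage context
                raise PipelineError(name, exc) from exc

        return inner

    return wrap


@_stage("generate")
def _make_dataset(config: PipelineConfig):
    from .annotations import read_annotations

    if config.dataset_dir is not None:
        raise PipelineError(
            "generate", NotImplementedError("external dataset loading: use the library API")
        )
    seed = int(np.random.SeedSequence(config.master_seed).spawn(1)[0].generate_state(1)[0] % 2**31)
    return generate_dataset(config.n_patients, config.teeth_per_patient, config.phantom, seed)


@_stage("train")
def _fit(config: PipelineConfig, dataset) -> DetectorResults:
    detector = DefectDetector(
        dataset,
        net_config=config.net,
        train_config=config.train,
        split_ratios=config.split_ratios,
        split_seed=config.master_seed,
    )
    results = detector.fit()
    if config.calibrate_mask_threshold:
        thr = results.calibrate_mask_threshold()
        logger.info(
            "calibrated mask thresholds on validation split: %s",
            {c.value: t for c, t in thr.items()},
        )
    return results


@_stage("evaluate")
def _evaluate(config: PipelineConfig, results: DetectorResults) -> dict:
    return results.evaluate("test", tolerance_mm=config.recognition_tolerance_mm)


@_stage("report")
def _write_outputs(config: PipelineConfig, dataset, results: DetectorResults, report: dict):
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report_to_json(report, out / "report.json")
    for family, table in report_tables(report).items():
        table.to_csv(out / f"metrics_{family}.csv")
    _write_detections_csv(results, out / "detections.csv")
    _write_roc_csv(report, out / "roc_points.csv")
    if config.write_images:
        write_dataset(dataset, out / "dataset")
    if config.write_figures:
        _write_figures(report, results, out)
    results.history.to_csv(out / "training_history.csv", index=False)
    results.save(out / "checkpoint.npz")
    thr = results.settings.mask_threshold
    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "mask_thresholds": {c.value: t for c, t in thr.items()}
        if isinstance(thr, dict)
        else thr,
        "master_seed": config.master_seed,
        "versions": _versions(),
        "n_series": len(results.model.series),
        "split": {k: results.model.split.patients(k) for k in ("train", "val", "test")},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True, default=str))
    return out


def _versions() -> dict:
    import matplotlib
    import pandas
    import scipy
    import skimage

    return {
        "python": sys.version.split()[0],
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
        "scikit-image": skimage.__version__,
        "matplotlib": matplotlib.__version__,
    }


def _write_detections_csv(results: DetectorResults, path) -> None:
    import pandas as pd

    rows = []
    for series in results.model.subset("test"):
        slice_results, diagnosis = results.predict_series(series)
        for (img, ann), res in zip(series.slices, slice_results):
            for c in DefectClass:
                det = res.detections[c]
                truth = ann.get(c)
                rows.append(
                    {
                        "patient_id": series.patient_id,
                        "tooth_id": series.tooth_id,
                        "slice_index": ann.slice_index,
                        "class": c.value,
                        "detected": det is not None,
                        "pred_length_mm": None if det is None else det.length_mm,
                        "true_length_mm": None
                        if truth is None
                        else truth.length_mm(ann.pixel_pitch_mm),
                        "pred_label": res.labels[c],
                        "true_label": ann.slice_label(c),
                        "score": res.scores[c],
                        "tooth_label": diagnosis.tooth_label[c],
                    }
                )
    pd.DataFrame(rows).to_csv(path, index=False)


def _write_roc_csv(report: dict, path) -> None:
    import pandas as pd

    rows = []
    for c in DefectClass:
        for level in ("slice_detection", "tooth_detection"):
            pts = report["classes"][c.value][level].get("roc_points")
            if pts:
                for fpr, tpr in pts:
                    rows.append({"class": c.value, "level": level, "fpr": fpr, "tpr": tpr})
    pd.DataFrame(rows).to_csv(path, index=False)


def _write_overlays(results: DetectorResults, out: Path, n_series: int = 2) -> None:
    """Endpoint-marker overlays for a few held-out teeth."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {
        DefectClass.BUCCAL_DEHISCENCE: "red",
        DefectClass.LINGUAL_DEHISCENCE: "blue",
        DefectClass.BUCCAL_FENESTRATION: "yellow",
        DefectClass.LINGUAL_FENESTRATION: "lime",
    }
    for series in results.model.subset("test")[:n_series]:
        slice_results, _ = results.predict_series(series)
        fig, axes = plt.subplots(1, 3, figsize=(9, 4))
        for ax, (img, ann), res in zip(axes, series.slices, slice_results):
            ax.imshow(img.pixels, cmap="gray")
            for c in DefectClass:
                pair = ann.get(c)
                if pair is not None:
                    ax.plot(*zip(pair.p1, pair.p2), color=colors[c], lw=1.0, alpha=0.6)
                det = res.detections[c]
                if det is not None:
                    for p in (det.p1, det.p2):
                        ax.plot(p[0], p[1], "x", color=colors[c], ms=6, mew=1.5)
            ax.set_axis_off()
            ax.set_title(f"slice {ann.slice_index}", fontsize=8)
        fig.suptitle(f"{series.tooth_id}: line = truth, x = predicted endpoints", fontsize=9)
        fig.tight_layout()
        fig.savefig(out / f"overlay_{series.tooth_id}.png", dpi=120)
        plt.close(fig)


def _write_figures(report: dict, results: DetectorResults, out: Path) -> None:
    _write_overlays(results, out)
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    # ROC curves (slice level)
    fig, ax = plt.subplots(figsize=(5, 5))
    for c in DefectClass:
        block = report["classes"][c.value]["slice_detection"]
        if block.get("roc_points"):
            pts = np.asarray(block["roc_points"])
            ax.plot(pts[:, 0], pts[:, 1], label=f"{c.value} (AUC {block['auc']:.3f})")
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.set_title("Per-slice ROC")
    if ax.get_legend_handles_labels()[1]:
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out / "roc_slice.png", dpi=120)
    plt.close(fig)

    # Bland-Altman per class from detections
    import pandas as pd

    det = pd.read_csv(out / "detections.csv")
    fig, axes = plt.subplots(2, 2, figsize=(9, 7))
    for ax, c in zip(axes.ravel(), DefectClass):
        sub = det[(det["class"] == c.value) & det["pred_length_mm"].notna() & det["true_length_mm"].notna()]
        if len(sub) >= 2:
            mean = (sub.pred_length_mm + sub.true_length_mm) / 2
            diff = sub.pred_length_mm - sub.true_length_mm
            ax.scatter(mean, diff, s=8, alpha=0.6)
            agr = report["classes"][c.value]["agreement"]
            if agr["bias"] is not None:
                for y, ls in ((agr["bias"], "-"), (agr["loa_low"], "--"), (agr["loa_high"], "--")):
                    ax.axhline(y, color="r", ls=ls, lw=0.8)
        ax.set_title(c.value, fontsize=9)
        ax.set_xlabel("mean length (mm)")
        ax.set_ylabel("pred - true (mm)")
    fig.tight_layout()
    fig.savefig(out / "bland_altman.png", dpi=120)
    plt.close(fig)

    # training curves
    fig, ax = plt.subplots(figsize=(5, 3.5))
    h = results.history
    ax.plot(h["epoch"], h["train_loss"], label="train")
    if h["val_loss"].notna().any():
        ax.plot(h["epoch"], h["val_loss"], label="val")
    ax.set_xlabel("epoch")
    ax.set_ylabel("loss")
    ax.set_yscale("log")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out / "training_loss.png", dpi=120)
    plt.close(fig)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns the evaluation report."""
    dataset = _make_dataset(config)
    results = _fit(config, dataset)
    report = _evaluate(config, results)
    _write_outputs(config, dataset, results, report)
    return report
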