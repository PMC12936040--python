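"""Patient-level splitting, augmentation, normalization, the composite loss
and the training loop.

Supervision is multi-task: the four mask channels carry binary cross-entropy
on logits, the eight direction channels (and, in heatmap mode, the four
heatmap channels) carry mean squared error.  Training uses AdamW with cosine
learning-rate annealing; the checkpoint with the lowest validation loss is
retained.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .annotations import LandmarkPair, SliceAnnotation
from .encoder import HeatmapSpec, build_target_stack
from .nn import AdamW, SwinUNETR2D, Tensor, NetConfig, cosine_lr, no_grad

__all__ = [
    "SplitSpec",
    "AugmentSpec",
    "TrainConfig",
    "TrainResult",
    "split_patients",
    "augment",
    "standardize",
    "loss",
    "train_model",
]

logger = logging.getLogger(__name__)

_MASK_CHANNELS = [0, 3, 6, 9]
_DIRECTION_CHANNELS = [1, 2, 4, 5, 7, 8, 10, 11]


@dataclass(frozen=True)
class SplitSpec:
    """Patient-level train/val/test assignment."""

    ratios: tuple[float, float, float]
    seed: int
    assignment: dict[str, str]  # patient_id -> {"train", "val", "test"}

    def patients(self, subset: str) -> list[str]:
        return sorted(p for p, s in self.assignment.items() if s == subset)


def split_patients(
    patient_ids, ratios: tuple[float, float, float] = (7, 2, 1), seed: int = 0
) -> SplitSpec:
    """Assign whole patients to train/val/test in the given proportions.

    Subset sizes are the rounded proportional shares (largest-remainder
    apportionment, summing to n); each nonzero-ratio subset receives at
    least one patient.  All slices of a patient follow its assignment, so
    the split is patient-disjoint by construction.
    """
    ids = sorted(set(map(str, patient_ids)))
    n = len(ids)
    names = ("train", "val", "test")
    nonzero = [i for i, r in enumerate(ratios) if r > 0]
    if n < len(nonzero):
        raise ValueError(f"{n} patients cannot fill {len(nonzero)} subsets")
    total = float(sum(ratios))
    shares = [n * r / total for r in ratios]
    sizes = [int(np.floor(s)) for s in shares]
    remainders = [s - z for s, z in zip(shares, sizes)]
    for i in np.argsort([-r for r in remainders], kind="stable")[: n - sum(sizes)]:
        sizes[int(i)] += 1
    for i in nonzero:  # guarantee nonemptiness
        if sizes[i] == 0:
            sizes[int(np.argmax(sizes))] -= 1
            sizes[i] = 1
    order = np.random.default_rng(seed).permutation(n)
    assignment: dict[str, str] = {}
    start = 0
    for name, size in zip(names, sizes):
        for j in order[start : start + size]:
            assignment[ids[int(j)]] = name
        start += size
    return SplitSpec(ratios=tuple(ratios), seed=seed, assignment=assignment)


@dataclass(frozen=True)
class AugmentSpec:
    """Geometric + photometric augmentation ranges (identity is included)."""

    scale_range: tuple[float, float] = (0.9, 1.1)
    rotation_range_deg: tuple[float, float] = (-10.0, 10.0)
    translation_range_frac: tuple[float, float] = (-0.05, 0.05)
    blur_sigma_range_px: tuple[float, float] = (0.0, 1.5)
    noise_sd_range: tuple[float, float] = (0.0, 0.05)

    def __post_init__(self) -> None:
        if not (self.scale_range[0] <= 1.0 <= self.scale_range[1]):
            raise ValueError("scale_range must contain 1")
        for r in (self.rotation_range_deg, self.translation_range_frac):
            if not (r[0] <= 0.0 <= r[1]):
                raise ValueError("rotation/translation ranges must contain 0")

    @classmethod
    def identity(cls) -> "AugmentSpec":
        return cls((1.0, 1.0), (0.0, 0.0), (0.0, 0.0), (0.0, 0.0), (0.0, 0.0))


def _affine_params(spec: AugmentSpec, rng: np.random.Generator):
    s = float(rng.uniform(*spec.scale_range))
    theta = float(np.deg2rad(rng.uniform(*spec.rotation_range_deg)))
    tx = float(rng.uniform(*spec.translation_range_frac))
    ty = float(rng.uniform(*spec.translation_range_frac))
    return s, theta, tx, ty


def augment(
    image: np.ndarray,
    annotation: SliceAnnotation,
    spec: AugmentSpec,
    rng: np.random.Generator,
) -> tuple[np.ndarray, SliceAnnotation]:
    """Apply one random augmentation to an image and its annotation.

    Landmarks are moved by exactly the same affine map as the pixels;
    blur and noise leave them untouched.  Pairs pushed outside the image
    are dropped from the returned annotation (logged).
    """
    h, w = image.shape
    s, theta, tx, ty = _affine_params(spec, rng)
    # forward map in (x, y): p' = A (p - c) + c + t
    a = s * np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    c = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    t = np.array([tx * w, ty * h])
    out = image.astype(np.float32)
    if not (s == 1.0 and theta == 0.0 and np.all(t == 0)):
        a_inv = np.linalg.inv(a)
        # scipy maps output (row, col) -> input: swap axes of the xy matrix
        m_rc = a_inv[::-1, ::-1]
        offset_xy = -a_inv @ (c + t) + c
        out = ndimage.affine_transform(
            out, m_rc, offset=offset_xy[::-1], order=1, mode="constant", cval=float(out.min())
        )
    defects: list[LandmarkPair] = []
    dropped = 0
    for pair in annotation.defects:
        p1 = a @ (pair.p1 - c) + c + t
        p2 = a @ (pair.p2 - c) + c + t
        if all(0 <= p[0] <= w - 1 and 0 <= p[1] <= h - 1 for p in (p1, p2)):
            defects.append(LandmarkPair(pair.defect_class, p1, p2))
        else:
            dropped += 1
    if dropped:
        logger.info("augment dropped %d out-of-bounds landmark pair(s)", dropped)
    sigma = float(rng.uniform(*spec.blur_sigma_range_px))
    if sigma > 0:
        out = ndimage.gaussian_filter(out, sigma)
    noise_sd = float(rng.uniform(*spec.noise_sd_range))
    if noise_sd > 0:
        out = out + rng.normal(0.0, noise_sd * 255.0, size=out.shape).astype(np.float32)
    new_ann = SliceAnnotation(
        patient_id=annotation.patient_id,
        tooth_id=annotation.tooth_id,
        slice_index=annotation.slice_index,
        pixel_pitch_mm=annotation.pixel_pitch_mm / s,  # scale changes mm per pixel
        defects=defects,
    )
    return out, new_ann


def standardize(image: np.ndarray) -> np.ndarray:
    """Per-image z-score normalization (zero mean, unit SD)."""
    img = image.astype(np.float32)
    sd = float(img.std())
    if sd == 0:
        warnings.warn("standardize: constant image, returning zeros")
        return np.zeros_like(img)
    return (img - img.mean()) / sd


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings.

    Defaults follow the target training regime (AdamW, initial learning
    rate 1e-4, cosine annealing, 200 epochs); small-scale phantom runs
    override ``epochs``/``initial_lr`` through this config.
    """

    epochs: int = 200
    initial_lr: float = 1e-4
    lr_min: float = 0.0
    #: linear learning-rate warmup over this many initial epochs (0 = none)
    warmup_epochs: int = 0
    batch_size: int = 8
    weight_decay: float = 1e-4
    seed: int = 0
    landmark_mode: str = "mask_direction"  # or "heatmap"
    heatmap_spec: HeatmapSpec = field(default_factory=HeatmapSpec)
    mask_width_px: int = 3
    #: loss weights; the per-term sum is unweighted by default
    mask_loss_weight: float = 1.0
    direction_loss_weight: float = 1.0
    #: BCE positive-class weight for the thin defect masks
    bce_pos_weight: float = 1.0
    augment_spec: AugmentSpec | None = field(default_factory=AugmentSpec)

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.initial_lr <= 0:
            raise ValueError("initial_lr must be positive")


def loss(
    prediction: Tensor,
    target: np.ndarray,
    mode: str = "mask_direction",
    mask_weight: float = 1.0,
    direction_weight: float = 1.0,
    bce_pos_weight: float = 1.0,
) -> Tensor:
    """Composite supervision loss over a (B, 12, H, W) prediction.

    ``mask_direction``: BCE-with-logits on the four mask channels (mean per
    pixel) plus MSE on the eight direction channels.  ``heatmap``: MSE on
    all localisation and direction channels.
    """
    if prediction.shape[-3:] != np.asarray(target).shape[-3:]:
        raise ValueError("prediction/target shape mismatch")
    target = np.asarray(target, dtype=np.float32)
    pred = prediction if prediction.ndim == 4 else prediction.reshape(1, *prediction.shape)
    tgt = target if target.ndim == 4 else target[None]
    loc = (slice(None), _MASK_CHANNELS)
    direc = (slice(None), _DIRECTION_CHANNELS)
    if mode == "mask_direction":
        loc_term = pred[loc].bce_with_logits(tgt[loc], pos_weight=bce_pos_weight)
    elif mode == "heatmap":
        loc_term = pred[loc].mse(tgt[loc])
    else:
        raise ValueError(f"unknown landmark mode {mode!r}")
    dir_term = pred[direc].mse(tgt[direc])
    return mask_weight * loc_term + direction_weight * dir_term


@dataclass
class TrainResult:
    model: SwinUNETR2D
    best_state: dict[str, np.ndarray]
    history: "object"  # pandas DataFrame: epoch, lr, train_loss, val_loss

    def restore_best(self) -> SwinUNETR2D:
        self.model.load_state_dict(self.best_state)
        return self.model


def _prepare_batch(samples, config: TrainConfig, rng: np.random.Generator | None):
    images, targets = [], []
    for img, ann in samples:
        pixels = img.pixels if hasattr(img, "pixels") else img
        if rng is not None and config.augment_spec is not None:
            pixels, ann = augment(np.asarray(pixels), ann, config.augment_spec, rng)
        stack = build_target_stack(
            ann,
            np.asarray(pixels).shape,
            mode=config.landmark_mode,
            heatmap_spec=config.heatmap_spec,
            mask_width_px=config.mask_width_px,
        )
        images.append(standardize(np.asarray(pixels)))
        targets.append(stack.channels)
    return np.stack(images), np.stack(targets)


def _epoch_loss(model, data, config, batch_size) -> float:
    total, count = 0.0, 0
    with no_grad():
        for i in range(0, len(data), batch_size):
            images, targets = _prepare_batch(data[i : i + batch_size], config, rng=None)
            pred = model(images)
            val = loss(
                pred,
                targets,
                mode=config.landmark_mode,
                mask_weight=config.mask_loss_weight,
                direction_weight=config.direction_loss_weight,
                bce_pos_weight=config.bce_pos_weight,
            )
            total += float(val.data) * len(images)
            count += len(images)
    return total / max(count, 1)


def train_model(
    train_data,
    net_config: NetConfig | SwinUNETR2D,
    config: TrainConfig,
    val_data=None,
) -> TrainResult:
    """Train the landmark network on (image, annotation) pairs.

    ``train_data``/``val_data`` are sequences of ``(SliceImage, SliceAnnotation)``
    tuples (or plain ``(ndarray, SliceAnnotation)``).  Returns the model, the
    best-validation-loss state dict, and the per-epoch history (train/val
    loss and the cosine-annealed learning rate).
    """
    import pandas as pd

    train_data = list(train_data)
    if not train_data:
        raise ValueError("empty training split")
    val_data = list(val_data) if val_data else []
    model = net_config if isinstance(net_config, SwinUNETR2D) else SwinUNETR2D(net_config)
    opt = AdamW(model.parameters(), lr=config.initial_lr, weight_decay=config.weight_decay)
    rng = np.random.default_rng(config.seed)
    history = []
    best_val = np.inf
    best_state = model.state_dict()
    for epoch in range(config.epochs):
        if epoch < config.warmup_epochs:
            lr = config.initial_lr * (epoch + 1) / (config.warmup_epochs + 1)
        else:
            lr = cosine_lr(
                epoch - config.warmup_epochs,
                config.epochs - config.warmup_epochs,
                config.initial_lr,
                config.lr_min,
            )
        opt.lr = lr
        order = rng.permutation(len(train_data))
        epoch_total, seen = 0.0, 0
        for i in range(0, len(order), config.batch_size):
            batch = [train_data[j] for j in order[i : i + config.batch_size]]
            images, targets = _prepare_batch(batch, config, rng)
            pred = model(images)
            val = loss(
                pred,
                targets,
                mode=config.landmark_mode,
                mask_weight=config.mask_loss_weight,
                direction_weight=config.direction_loss_weight,
                bce_pos_weight=config.bce_pos_weight,
            )
            opt.zero_grad()
            val.backward()
            opt.step()
            epoch_total += float(val.data) * len(batch)
            seen += len(batch)
        train_loss = epoch_total / seen
        val_loss = _epoch_loss(model, val_data, config, config.batch_size) if val_data else np.nan
        history.append(
            {"epoch": epoch, "lr": lr, "train_loss": train_loss, "val_loss": val_loss}
        )
        monitor = val_loss if val_data else train_loss
        if monitor < best_val:
            best_val = monitor
            best_state = model.state_dict()
        logger.info(
            "epoch %d: lr %.2e train %.4f val %s", epoch, lr, train_loss,
            f"{val_loss:.4f}" if val_data else "-",
        )
    return TrainResult(model=model, best_state=best_state, history=pd.DataFrame(history))
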