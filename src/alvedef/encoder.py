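"""Build the 12-channel supervision maps from slice annotations.

The network predicts, per defect class (channel group), a localisation
channel plus a two-channel direction field:

* ``mask_direction`` mode (default): channel ``a`` is a binary rasterised
  segment mask joining the two endpoints; channels ``b, c`` hold the
  components of the unit apex-to-crown direction vector on mask pixels.
* ``heatmap`` mode: channel ``a`` is a sum of unnormalised Gaussians, one
  per endpoint,

      h(x, y) = sum_i exp(-((x - x_i)^2 + (y - y_i)^2) / (2 sigma^2)),

  evaluated literally (no clipping), so coincident landmarks sum to 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.draw import line as _draw_line
from skimage.morphology import dilation as _dilation, disk as _disk

from .annotations import DefectClass, LandmarkPair, SliceAnnotation

__all__ = [
    "HeatmapSpec",
    "TargetStack",
    "encode_heatmap",
    "encode_mask",
    "encode_direction",
    "build_target_stack",
    "MODES",
]

MODES = ("mask_direction", "heatmap")


@dataclass(frozen=True)
class HeatmapSpec:
    """Gaussian spread of the endpoint heatmaps, in pixels."""

    sigma_px: float = 2.0

    def __post_init__(self) -> None:
        if self.sigma_px <= 0:
            raise ValueError(f"sigma_px must be positive, got {self.sigma_px}")


def encode_heatmap(landmarks, shape: tuple[int, int], spec: HeatmapSpec) -> np.ndarray:
    """Sum-of-Gaussians landmark heatmap on an ``(H, W)`` grid.

    Each landmark ``(x_i, y_i)`` contributes ``exp(-(dx^2 + dy^2)/(2 sigma^2))``;
    contributions are summed without clipping, so the peak of ``k`` coincident
    landmarks is ``k``.
    """
    sigma = spec.sigma_px
    h, w = shape
    out = np.zeros((h, w), dtype=np.float32)
    if len(landmarks) == 0:
        return out
    ys = np.arange(h, dtype=np.float64)[:, None]
    xs = np.arange(w, dtype=np.float64)[None, :]
    for p in landmarks:
        x0, y0 = float(p[0]), float(p[1])
        out += np.exp(-((xs - x0) ** 2 + (ys - y0) ** 2) / (2.0 * sigma**2)).astype(np.float32)
    return out


def encode_mask(pair: LandmarkPair, shape: tuple[int, int], width_px: int = 3) -> np.ndarray:
    """Rasterise the endpoint segment, dilated to ``width_px``, as a 0/1 mask."""
    if width_px < 1:
        raise ValueError("width_px must be >= 1")
    pair.validate_bounds(shape)
    h, w = shape
    r0, c0 = int(round(pair.p1[1])), int(round(pair.p1[0]))
    r1, c1 = int(round(pair.p2[1])), int(round(pair.p2[0]))
    if (r0, c0) == (r1, c1):
        raise ValueError("degenerate segment: endpoints rasterise to the same pixel")
    mask = np.zeros((h, w), dtype=bool)
    rr, cc = _draw_line(r0, c0, r1, c1)
    mask[rr.clip(0, h - 1), cc.clip(0, w - 1)] = True
    radius = (width_px - 1) // 2
    if radius > 0:
        mask = _dilation(mask, _disk(radius))
        # dilation also extends the band past the endpoints; trim it so the
        # extreme mask pixels along the segment direction stay within +-1 px
        # of the annotated endpoints
        rows, cols = np.nonzero(mask)
        u = (pair.p2 - pair.p1) / np.hypot(*(pair.p2 - pair.p1))
        proj = (cols - pair.p1[0]) * u[0] + (rows - pair.p1[1]) * u[1]
        length = float(np.hypot(*(pair.p2 - pair.p1)))
        keep = (proj >= -0.5) & (proj <= length + 0.5)
        mask = np.zeros((h, w), dtype=bool)
        mask[rows[keep], cols[keep]] = True
    return mask.astype(np.float32)


def encode_direction(pair: LandmarkPair, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unit apex-to-crown direction field on the mask support.

    The vector points from the class's apical-role endpoint (AB for
    fenestration, ARC for dehiscence) toward its coronal-role endpoint, and
    is zero off the mask.
    """
    if not np.any(mask):
        raise ValueError("direction encoding requires a nonempty mask")
    vec = pair.coronal_point - pair.apical_point
    norm = float(np.hypot(*vec))
    if norm == 0:
        raise ValueError("zero-length landmark pair")
    dx, dy = vec / norm
    support = (mask > 0).astype(np.float32)
    return support * np.float32(dx), support * np.float32(dy)


@dataclass
class TargetStack:
    """The 12 supervision channels for one slice (4 groups x 3 channels).

    ``channels[3g]`` localises the class of group ``g`` (binary mask or
    Gaussian heatmap depending on ``mode``); ``channels[3g+1:3g+3]`` hold the
    direction field ``(d_x, d_y)``, unit-norm wherever nonzero.
    """

    channels: np.ndarray  # (12, H, W) float32
    mode: str = "mask_direction"
    heatmap_spec: HeatmapSpec = field(default_factory=HeatmapSpec)

    def __post_init__(self) -> None:
        if self.channels.shape[0] != 12:
            raise ValueError("a target stack has exactly 12 channels")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")

    def group(self, g: int) -> np.ndarray:
        return self.channels[3 * g : 3 * g + 3]

    def save_npy(self, path) -> None:
        np.save(path, self.channels)


def build_target_stack(
    annotation: SliceAnnotation,
    shape: tuple[int, int],
    mode: str = "mask_direction",
    heatmap_spec: HeatmapSpec | None = None,
    mask_width_px: int = 3,
) -> TargetStack:
    """Encode one slice annotation into its 12 supervision channels.

    Channel groups with no annotated defect are all-zero.  In heatmap mode
    the localisation channel is the two-endpoint Gaussian heatmap; the
    direction channels are identical in both modes.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    spec = heatmap_spec or HeatmapSpec()
    h, w = shape
    channels = np.zeros((12, h, w), dtype=np.float32)
    for defect_class in DefectClass:
        pair = annotation.get(defect_class)
        if pair is None:
            continue
        g = defect_class.group
        mask = encode_mask(pair, shape, mask_width_px)
        if mode == "mask_direction":
            channels[3 * g] = mask
        else:
            channels[3 * g] = encode_heatmap([pair.p1, pair.p2], shape, spec)
        dx, dy = encode_direction(pair, mask)
        channels[3 * g + 1] = dx
        channels[3 * g + 2] = dy
    return TargetStack(channels=channels, mode=mode, heatmap_spec=spec)
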