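# Methods

`alvedef` detects and measures two kinds of alveolar bone defect on 2D
sagittal CBCT slices of single teeth: **dehiscence** (a crestal, V-shaped
bone loss measured between the alveolar ridge crest, ARC, and the
cementoenamel junction, CEJ) and **fenestration** (a window-like defect
apical to the crest, measured between its coronal border, CB, and apical
border, AB), each on the buccal/labial and lingual/palatal surfaces — four
defect classes in total.  This note describes the model, its assumptions,
the synthetic data it is validated on, and the numerical choices made where
the design was genuinely open.

## Problem and decision rules

Each tooth is represented by three consecutive sagittal slices (one slice
thickness apart, mesial/central/distal).  On a slice, a defect of class *c*
is described by a landmark endpoint pair; its clinical magnitude is the
Euclidean distance between the endpoints converted to millimetres through
the pixel pitch (0.25 mm/px in the target imaging regime; the pitch is an
explicit per-slice field, never assumed).  Diagnosis uses strict
thresholds — dehiscence positive when the ARC–CEJ distance **exceeds
2.0 mm**, fenestration positive when the interruption is **greater than
2.2 mm** — applied per slice, and a tooth is positive only when **all three
slices** are positive (logical AND).  The tooth-level confidence is the
minimum of the three slice confidences, mirroring the AND rule.

## Network

The landmark model is a 2D Swin-UNETR: a four-stage hierarchical
shifted-window transformer encoder with patch merging between stages, and a
convolutional decoder that upsamples with stride-2 transposed convolutions
and concatenates the matching encoder features at each level (skip
connections).  Window attention uses a learned relative position bias;
alternate blocks shift the windows by half their extent with masked
attention across the wrap-around seam.  Feature maps not divisible by the
window or merging factor are zero-padded and cropped back,
deterministically.

The head emits 12 channels, three per defect class, ordered
buccal dehiscence, lingual dehiscence, buccal fenestration, lingual
fenestration.  Per group: one localisation channel (a binary segment mask
in the default `mask_direction` mode, or a sum-of-Gaussians endpoint
heatmap `h(x,y) = Σᵢ exp(−((x−xᵢ)² + (y−yᵢ)²)/(2σ²))` in `heatmap` mode,
evaluated literally with no clipping) and two channels for the unit
direction vector pointing from the apical-role endpoint (ARC or AB) toward
the coronal-role endpoint (CEJ or CB), supervised as a spatially constant
field on the mask support and zero outside it.

Because the network must run (training included) on a plain CPU scientific
stack, the package carries its own compact reverse-mode automatic
differentiation engine over numpy float32 arrays (`alvedef.nn.autograd`)
with exactly the primitives the architecture needs; convolutions use
im2col, the transposed convolution is expressed as a linear map plus
depth-to-space (algebraically identical for kernel 2 / stride 2).
Gradient correctness is checked against finite differences, and windowed
attention against a brute-force global-attention oracle, in the test suite.

Defaults: patch size 2, embed dim 24, depths (2,2,2,2), heads (3,6,12,24),
window 7, MLP ratio 4.  The `tiny` preset (embed dim 12, window 4,
~0.4 M parameters) is used for CPU-scale studies and tests.  The
architecture hyperparameters are config surface: nothing in the problem
fixes them.

## Training

Patient-level 7:2:1 train/validation/test split: all slices of a patient
share one subset (largest-remainder apportionment of the rounded
proportional shares, each nonzero-ratio subset guaranteed at least one
patient).  Inputs are standardized per image to zero mean and unit SD.
Training augmentation applies random scaling (±10%), rotation (±10°),
translation (±5% of extent), Gaussian blur (σ ≤ 1.5 px) and additive noise
(SD ≤ 5% of range); landmark coordinates are transformed by exactly the
same affine map as the pixels (scaling also rescales the mm-per-pixel
factor), and pairs pushed out of bounds are dropped from the transformed
annotation.

The loss sums, unweighted by default, binary cross-entropy (on logits)
over the four mask channels and mean squared error over the eight
direction channels (heatmap mode replaces the BCE with MSE on the heatmap
channels; which channels the original recipe treated as heatmaps is
ambiguous, so both modes are implemented and `mask_direction` is the
default).  Because the 3-px-wide defect masks cover well under 1% of the
pixels, the BCE positive-class weight is exposed in the config; the
reference scaled study uses 5.  Optimization is AdamW (initial learning
rate 1e-4, 200 epochs by default; the scaled study uses 3e-3 for 32 epochs
on the tiny net) with cosine annealing to zero and batch size 8.  An
optional linear warmup over the first epochs (2 in the scaled study,
0 by default) stabilises early transformer training — without it,
occasional runs leave one class head under-fitted.  The checkpoint with
the lowest validation loss is kept.  All randomness flows
from explicit seeds; a run is bit-reproducible on CPU.

## Decoding and calibration

Decoding is localisation-then-endpoints.  In mask mode the sigmoid
probability map is thresholded (default 0.5), the largest 8-connected
component is kept (row-major tie-break), the direction field is averaged
over the component into a unit axis (principal axis as fallback), member
pixels are projected onto that axis, and the two endpoints are estimated
sub-pixel: lateral position from the whole-component line fit, longitudinal
position as the centroid of the extreme 1-px projection band plus a 0.25-px
outward correction that cancels the rasterisation bias of the band ends.
Endpoint roles are assigned by the projection sense of the direction
vector.  The detection score is the maximum mask probability; an empty or
single-pixel region decodes as "absent" (a valid outcome, label negative,
score 0).  In heatmap mode the endpoints are the two highest local maxima
with a non-maximum-suppression radius of 2σ.

After fitting, per-class mask probability cut-offs can be calibrated on the
**validation** split (`DetectorResults.calibrate_mask_threshold`): for each
class the candidate threshold maximising, in order, that class's slice
accuracy, its endpoint recognition rate and the smaller length error is
selected.  Candidates never exceed the 0.5 default — raising the cut-off
above the decision boundary silently drops low-confidence detections of
small defects, and in this application a missed defect costs more than a
marginal length-error gain (sensitivity first).  The test split is never
touched during calibration.  The continuous score fed to ROC analysis is the mask
probability (slice level) and its minimum over the three slices (tooth
level); no canonical definition exists for this quantity, so it is a
documented package choice.

## Synthetic phantom

No clinical data ship with the package; every quantitative claim is made on
a synthetic phantom whose geometry encodes the defect definitions.  A slice
renders, at 8-bit intensities: a tapered bright root with a crown, a
cancellous bone slab on both sides starting at the per-side alveolar crest,
and a bright 2-px cortical rim hugging the root contour — the structure the
detector actually reads.  A dehiscence of length L recedes that side's
crest to distance L along the root contour from the CEJ (endpoints ARC and
CEJ, bare root in between); a fenestration carves a rectangular window of
longitudinal extent exactly L through rim and bone (endpoints CB and AB at
the window borders).  Endpoints are stored in float pixel coordinates lying
exactly on the contour, so the recorded mm length equals the endpoint
distance times the pixel pitch by construction.  Rendering adds Gaussian
blur (σ 0.7 px) and additive noise (SD 3% of range).

Per tooth and class, a defect is present with prevalence 0.35; lengths are
uniform on [0.5, 6.0] mm excluding a ±0.4 mm band around the class
threshold, so that sub-pixel decoding error cannot flip a slice label and
the generated labels are well defined.  15% of defect-bearing teeth are
rendered *discordant* — two slices above threshold, one below — making the
tooth consensus-negative and exercising the AND rule.  The three slices of
a tooth share the defect plan but differ by small geometric jitter.
Defects that cannot fit a particular tooth's contour (e.g. a long
fenestration under a deep dehiscence on a small image) are dropped from the
whole tooth so slice and tooth labels stay consistent.

What the phantom does **not** emulate: true CBCT noise texture and partial
volume effects, anatomical variability of root and bone shape, metal and
motion artifacts, neighbouring teeth, and observer disagreement.  Passing
the phantom study therefore demonstrates that the architecture, encoding,
decoding, measurement and evaluation machinery are correct and learnable
end-to-end — not that the reported clinical accuracy transfers to real
scanners.

## Scaled reference study

The bundled end-to-end study (`alvedef.pipeline.scaled_study_config`, also
what `scripts/acceptance.py` runs) uses the tiny network on 180 phantom
teeth (540 slices, 90 patients) at 96 × 64 px and 0.25 mm pitch, 32 epochs
(2 warmup) — problem sizes chosen so the full study runs in minutes on one
CPU core.
The held-out test patients yield, per class, endpoint recognition rate at
2 mm tolerance, AED/SD/quartiles of the endpoint distances, length
MAE/RMSE/MRE/PCC, Bland–Altman bias with 95% limits of agreement
(bias ± 1.96 SD), and accuracy/recall/precision/specificity/F1/AUC at
slice and tooth level.  The recognition tolerance (2.0 mm) has no canonical
value; it is reported together with a tolerance sweep (0.5–4 mm) so the
choice is transparent.

## Numerical choices and edge cases

- Coordinates are 0-based (x = column, y = row, origin top-left).
- Quartiles use linear interpolation; SD is the sample (n−1) estimator by
  default (configurable).  AED statistics cover matched endpoints only;
  the recognition rate reports the unmatched remainder separately.
- Undefined ratios (zero denominators) are reported as absent, never 0;
  PCC is absent for n < 2 or constant inputs; mean relative error uses
  ground-truth denominators (true lengths are positive by construction).
- AUC is trapezoidal over all thresholds and equals the pairwise
  concordance probability with ties counted ½.
- Heatmap σ defaults to 2 px; two landmarks merge into one maximum below
  ≈ 4σ separation, so heatmap-mode decoding is only reliable for defects
  longer than that (one reason `mask_direction` is the default).
- Masks rasterise the endpoint segment 3 px wide, trimmed longitudinally to
  the segment extent so the extreme mask pixels stay within ±1 px of the
  annotated endpoints.
- Constant images standardize to zeros with a warning; degenerate
  (single-pixel) detections are dropped and logged.

## Known limitations

- The phantom's schematic appearance makes the learning task easier than
  clinical CBCT; quality floors proven here are necessary, not sufficient,
  for clinical performance.
- Only endpoint-to-endpoint lengths are measured; area-based defect
  quantification and severity grading are out of scope.
- The model is strictly 2D; volumetric context is not used.
- Heatmap mode shares the direction-field decoder but has no sub-pixel
  refinement; its endpoints are grid-snapped peaks.
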