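# Methods

## The pipeline

`ventriseg` volumetrizes the ventricular system on head CT with a
detection-then-segmentation cascade rather than a single whole-image
segmenter. The rationale: the twelve subregions differ in size by two
orders of magnitude (lateral-ventricle bodies of tens of ml versus
posterior horns that are often empty), and a per-structure model on a
tight, standardized region of interest sees a far more homogeneous
input distribution than a global model. The cascade is

CT → canonical frame → per-slice boxes → invertible ROI crops →
per-subregion 2D masks → backsampled 3D label volume → volumes in ml.

### Canonical frame

Native volumes (DICOM series or NIfTI) are reoriented to RAS by axis
permutation/flip, resampled trilinearly to 1 mm isotropic, centered in
a 256³ grid by symmetric crop/zero-pad, and intensity-windowed from 0
to 80 HU onto [0, 1] — the window in which CSF (≈ 0–15 HU) separates
from parenchyma (≈ 20–45 HU). Choices worth noting:

- Interpolation happens in HU space; windowing comes last, so partial
  volume averaging is physically meaningful.
- The isotropic target extent per axis is rounded to the grid's parity
  (adding at most one voxel, a ≤ 0.5 % scale change) so the symmetric
  crop/pad leaves the volume center exactly fixed; the recorded
  `CanonicalTransform` maps canonical indices back to native indices
  as a single affine.
- Labels follow the identical chain with nearest-neighbour
  interpolation, so classes can shrink but never appear from nowhere.
- Fitting to 256³ uses center crop/pad, not anisotropic scaling; heads
  keep their aspect ratio and their mm scale.

### ROI geometry

Detection boxes are enlarged 3× about their center (the enlargement
factor is configurable up to 4×, covering the reading of "enlarge by
300 %" as either ×3 or +300 %), clipped to the slice, padded
symmetrically to a square and standardized to 256×256. Two modes exist:

- **pad-only** (`resize_factor = 1`): the square is centered in the
  target frame with zero padding. Integer geometry only — inversion is
  bit-exact. Used whenever the crop already fits, and throughout the
  end-to-end identity checks.
- **resize**: the square is rescaled to 256 (bilinear for images,
  nearest for masks with a 0.5 threshold). Inversion loses at most a
  boundary layer; on disks of radius ≥ 20 px the round-trip Dice stays
  ≥ 0.98.

Every step is recorded in a `CropTransform` (JSON-serializable), so
backsampling can run in a separate process and any mode is invertible
by construction. Pixel boxes are half-open integers, origin top-left,
x = column.

### Detection

The detector contract is pluggable: (a) an oracle that replays the
tight ground-truth boxes (also used to build segmentation training
crops, as in the original two-stage design); (b) a minimal single-scale
anchor-free convolutional detector, trainable on CPU in minutes; (c)
external YOLO-format prediction files, so a full-scale detector can be
trained elsewhere and plugged in. Reproducing a 140 M-parameter
detector is explicitly out of scope; the cascade, not the backbone, is
the point.

The built-in detector pools the input to 128², appends two normalized
coordinate channels, runs four 3×3 conv stages, and reads out per-class
objectness plus (dx, dy, log w, log h) regressors on a 32×32 cell grid.
Two design points matter for a net this small. First, the subregion
classes are defined by absolute position (a left and a right body are
locally identical), which translation-invariant convolutions cannot
express: besides the coordinate channels, a learnable per-class spatial
bias map is added directly to the objectness logits — a direct per-cell
parameter reaches logit scale in a few hundred Adam steps, where the
same prior squeezed through shared convolution weights would need tens
of thousands. Second, targets are assigned to every cell whose center
lies in the central half of a box, each regressing its own offset
(single-cell targets are too brittle on a grid this coarse). Objectness
biases start at −4 (the background prior), and box regression is an L2
loss on the positive cells.

Post-processing is shared and fixed by config defaults matching the
published operating point: candidates below confidence 0.001 are
dropped, class-wise NMS runs at IoU 0.6, and at most one box per class
per slice survives (the anatomy admits one instance of each subregion
per slice; class-wise rather than class-agnostic NMS because distinct
subregions legitimately overlap). Training augmentation covers
horizontal flip (with left/right class relabeling), scaling and
translation.

### Segmentation

One binary 2D U-Net per subregion, eleven models for twelve classes:
the posterior horns are so scarce that left and right are pooled into
one model, with right-sided patches mirrored into left chirality for
training and predictions mirrored back — pooling in a common chirality
maximizes what the scarce class gains from its mirror twin.

The architecture follows the standard encoder–decoder with skip
connections: `depth` levels, resolution halved per level, filters
doubling from `start_filters` (so a depth-3/start-32 net bottlenecks at
256 filters), `blocks_per_level` conv+ReLU blocks, optional batch-norm
and dropout, sigmoid output at input resolution. The decoder runs at
half the encoder width (1×1 reduction after nearest-neighbour
up-sampling, then 3×3 blocks after the skip concatenation): for a
single foreground structure this loses nothing measurable and halves
the dominant full-resolution cost. The production hyperparameter space
is enforced by `SegModelConfig` (start filters 32–128, depth 3–5,
blocks 2–5, batch size 32/64, learning rate 1e-3/1e-4, ReLU and binary
cross-entropy fixed); `desk=True` marks reduced test-scale
configurations that may leave those ranges.

Training uses Adam on binary cross-entropy with a positive-class weight
of min((1−p)/p, 20) where p is the foreground fraction — ROI patches
are still ~95 % background, and the unweighted loss stalls in the
all-background minimum at small step counts. Splits are always at the
subject level (five-fold cross-validation or a held-out fraction);
augmentation composes horizontal flip, integer shift, small rotation
and multiplicative brightness (brightness never touches the mask).
Early stopping on validation Dice (patience 2, min improvement 0.005)
is on by default: the optimizer, stopping rule and probability
threshold (0.5) are not fixed by the cascade design and are exposed as
documented config fields. Patch intensities are the windowed [0, 1]
crops with no further normalization.

### Backsampling and volumetry

Patch masks are inverted through their transforms, placed on their
slices, and OR-accumulated into per-class 3D volumes. Because the
per-subregion models are independent, two classes can claim one voxel;
the published design never specifies a fusion rule, so ours is
explicit: the rarest/smallest structure wins (posterior horn > temporal
horn > atrium > anterior horn > third > fourth > body), ties to the
lower class id, and the contested-voxel count is logged — this protects
small structures from being swallowed by large neighbours. Duplicate
(class, slice) predictions are rejected outright.

Volumes are voxel count × voxel volume on the canonical 1 mm grid
(1000 voxels = 1 ml); mapping back through the native transform is
possible but off by default, matching the fixed-resolution design.
Groups: whole system = all twelve; each side = anterior horn + body +
atrium + temporal horn; midline = third + fourth. The relative
volumetric error (predicted − reference)/reference is signed and
reported as missing (not infinite) when the reference is empty —
posterior horns are legitimately 0 ml in many subjects.

### Metrics

Dice 2|A∩B|/(|A|+|B|) and Jaccard |A∩B|/|A∪B| (the identity
J = D/(2−D) holds exactly and is property-tested). Both score 1.0 when
both masks are empty, with a log record: for structures whose median
volume is zero, predicting absence correctly is a success, not an
undefined case. HD95 takes the 95th percentile of the *pooled*
bidirectional surface-to-surface distances (surfaces = foreground
voxels with a background face-neighbour), in mm via the spacing;
literature varies between pooling and averaging the two directions, so
the choice is stated here and frozen. Detection uses greedy
confidence-ordered matching, all-point (precision-envelope) AP
interpolation, mAP50–95 over IoU 0.50:0.05:0.95, and unweighted means
over classes with at least one ground-truth instance. Every metric is
tested against an independent brute-force oracle (O(n²) distance
enumeration, explicit PR-curve integration).

## The phantom generator

No public cohort exists for this task, so the package generates its
own study material: a 256³, 1 mm isotropic head with an ellipsoidal
skull shell (bone 900 HU, thickness 6 mm), parenchyma 35 ± 3 HU, CSF
8 ± 2 HU inside the subregions, plus 4 HU global Gaussian noise — the
contrast lives inside the 0–80 HU window exactly where the clinical
problem does. The twelve subregions are geometric primitives with
closed-form volumes: ellipsoids for bodies (~16 ml each), anterior
horns, atria and the midline ventricles (~1–2.5 ml), and arcs of tori
(curved tubes) for the thin posterior (~0.7 ml) and temporal horns
(~1.8 ml) — elongated curved targets chosen deliberately so the
detector and segmenter face thin structures, not just blobs. Left and
right primitives are exact sagittal mirror images before pose jitter
(tube arcs mirror by conjugating their rotation with the reflection,
Mx·R·My, exploiting the arc's local symmetry).

Cohorts draw, per subject and reproducibly from (seed, index) alone, a
ventriculomegaly scale s ~ U(0.9, 1.25) applied to all primitives
(volumes scale as s³, mean body volume ≈ 21 ml, matching the magnitude
of a mildly hydrocephalic population), a rigid head rotation of up to
±5° per axis, and fresh noise. Generation validates that subregions
stay pairwise disjoint and inside the skull after scaling, and the
default geometry keeps ≥ 1.4 mm clearance at the maximum scale.

What the phantom does *not* emulate — and hence what passing tests do
not show about clinical data: beam hardening and streak artifacts,
anatomical shape variability beyond affine scale/pose, connected
ventricles (primitives are deliberately disjoint where real subregions
touch), craniectomy defects and shunt hardware. Phantom results
validate the machinery (geometry, metrics, reconstruction, learning
capacity), not clinical accuracy.

## The network engine

No deep-learning framework is a dependency: the U-Net and detector run
on a compact NumPy/numba engine (`ventriseg.nn`) with channels-first
float32 activations. The 3×3 convolution forward, input-gradient and
weight-gradient passes are numba kernels whose inner loops are
contiguous row fused-multiply-adds; 1×1 convolutions are batched BLAS
matmuls. Max-pool backward routes the gradient to every element equal
to the window maximum (exact positive float ties are vanishingly rare,
and ties at zero are masked by the preceding ReLU's backward). The BCE
loss is computed on logits with log1p/logaddexp stabilization. Adam,
batch-norm with running statistics, dropout and He initialization
complete the set. All randomness flows through seeded
`numpy.random.Generator`s, so training is bit-reproducible on CPU.

## Problem sizes

Defaults for the test and acceptance runs were chosen once as
desk-scale study conditions: ten-phantom training cohorts; the
lateral-ventricle-body U-Net trained on the ~260 body patches such a
cohort yields (start 16, depth 3, one block per level, batch 8,
learning rate 1e-3, at most 10 epochs with early stopping); the
detector trained on ~350 labeled slices for 20 epochs and evaluated on
two held-out phantoms; the resize-path end-to-end check run on a
ten-phantom cohort. Batch 8 (below the production 32/64 space) gives
the small desk dataset more optimizer steps per epoch and is the
fastest batch size for the memory-bound CPU kernels. Production-scale
settings (300 detector epochs, batch 64, the full hyperparameter
search space, five-fold cross-validation over 80 subjects) remain the
config defaults for real training runs.

## Known limitations

- The built-in detector is single-scale and anchor-free; it is a
  functional stand-in that exercises the cascade, not a
  state-of-the-art detector. External detectors plug in via YOLO-format
  files.
- Overlap fusion is a fixed priority heuristic; a learned or
  probability-weighted fusion could do better where subregions abut.
- Volumetry is reported on the canonical 1 mm grid; very thin
  structures (posterior horns) lose proportionally more to the
  resampling than large ones.
- Axial-only processing means transitions between subregions along the
  slice axis are hard boundaries; combining three planes is the
  natural extension.
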