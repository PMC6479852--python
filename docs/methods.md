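# Methods

`stumprot` implements a two-stage pipeline for post-harvest imagery of cut
Norway-spruce stumps: detect the stump disc in an RGB frame, then grade the
severity of root-and-butt rot (RBR, *Heterobasidion* spp. decay) visible on
the cut surface.  This note documents the models, the synthetic data they
are exercised on, the numerical choices, and the limits of what the desk
benchmarks demonstrate.

## Severity grading

Rot extent is the pixelwise RBR ratio `|rot| / |stump|` over the manually
(here: synthetically) segmented stump surface.  The three grades follow
timber-bucking rules: `NO_ROT` (ratio exactly 0, saw-timber quality),
`ROT_LT_50` (0 < ratio < 0.5, prime pulpwood), `ROT_GE_50` (ratio ≥ 0.5,
downgraded).  The 0.5 boundary is closed on the severe side.

## Segmentation quality (sq)

Detections are judged by **sq**, the mean of segmentation-overlap `O/L` and
segmentation-efficiency `O/S` (O = overlap area, L = labeled area, S =
segmented area):

    sq = (O/L + O/S) / 2 ∈ [0, 1]

sq is deliberately not IoU: a box that fully contains the object scores at
least 1/2 regardless of how oversized it is, and a box fully inside the
object likewise.  Boxes are half-open integer rectangles so every area is an
exact pixel count; the mask overload counts mask pixels instead.  A detection
is a true positive when its sq against an unmatched labeled box clears the
threshold (default 0.5, comparison `>=`, both configurable); matching is
greedy in descending score with one-to-one assignment, ties broken toward
higher sq and then the smaller label index.

## Synthetic scenes

No public stump photo set with pixelwise rot annotation exists at the scale
needed, so `simdata` renders labeled scenes: a forest-floor background
(humus tones, moss patches, needle strokes, branch polygons, sawdust blobs),
one elliptical stump disc with concentric growth rings, radial cracks and a
darker bark annulus, and — when rot is requested — a darker, noisier region
obtained by thresholding a smooth centre-weighted, angularly lobed random
field at the exact pixel count implied by the target ratio (realized ratio
within one pixel of target; the contract allows ±0.02).  Occlusion draws
needle/branch strokes over the disc up to a requested coverage fraction.
Lighting gain, an illumination gradient and an optional shadow are applied
**after** the masks are captured, so ground truth is exact by construction,
mirroring the fact that a human annotator outlines the physical surface
regardless of illumination.

Defaults emulate the reference field campaign: 300×400-pixel frames, stump
radius 8–35 % of the shorter side (apparent distance), class mix proportional
to 502 / 197 / 301 (no rot / <50 % / ≥50 %), one stump per scene
(multi-stump scenes are supported for matcher testing).  Per-scene seeds
derive from a master seed; identical parameters render bit-identical scenes.

What the generator does **not** emulate: real wood texture statistics,
perspective distortion of the ground plane, weathering/oxidation gradients,
camera noise and compression, and the visual ambiguity between rot
discoloration and wet or shaded wood.  Green numbers on these scenes
therefore demonstrate that the pipeline's machinery is correct and
well-calibrated, not that field accuracy would match.

## Detector

Frames are standardized to 300 rows × 400 columns (anisotropic resize; the
per-axis scale factors map boxes back to the original resolution).  Two
CNNs with the same architecture — 3×3 conv (32 filters), ReLU, 3×3 conv
(32), ReLU, 2×2 max-pool, FC-64, ReLU, FC-2, softmax, on 32×32 patches —
split the work as in two-stage detection:

* the **proposal network** is trained on loosely overlapping windows
  (sq ≥ 0.55 positive, pure background negative) and scores a coarse
  multi-scale sliding-window sweep (sizes 40–232 px in ×1.4 steps, aspects
  1.0/0.8, stride 0.45 of the window);
* the **detection network** is trained on tight boxes only (≤ ~10 % scale
  and ~8 % position jitter), with interior sub-windows, off-centre part
  windows and over-large containing windows as explicit negatives, plus one
  round of hard-negative mining (false alarms of the full detector on
  training scenes are fed back and training continues briefly).

Seeds surviving NMS on the coarse sweep are refined over three rounds of
local offset/scale grids (one wide, two narrow; per-axis scales allow aspect
correction), scored by the detection network.  Final boxes are thresholded
at score 0.5, suppressed at sq 0.3, vote-averaged over agreeing grid boxes,
suppressed once more (refinement moves boxes), and filtered by a minimum
side length of 30 px — below the smallest apparent stump the scene model can
produce.  NMS breaks score ties toward the larger box, so a window covering
the whole disc suppresses equally confident part windows (a nested part
always has sq > 1/2 with its container).

The pooling layer is 2×2 max with stride 2 (the historical description names
only "a pooling layer"); the classification head order is FC-64 → ReLU →
FC-2 → softmax.  Training uses SGD with momentum 0.9.  The desk schedule is
(lr 0.02, 14 epochs) then (0.004, 7) at mini-batch 32; the historical
full-scale four-step recipe (mini-batch 1, lr 1e-5/1e-5/1e-6/1e-6, epochs
20/20/20/10) ships as `DetectorConfig.full_scale()` for completeness but is
not suited to this from-scratch numpy implementation.

## Feature extraction and classifiers

Three routes grade rot on stump crops (ground-truth crops for training; at
evaluation either ground-truth crops or detector true positives):

* **BS** — bag of visual words: SIFT descriptors (scikit-image; a
  patent-free member of the same scale-invariant family as SURF, recorded in
  `Vocabulary.descriptor_kind`), k-means vocabulary (k = 500), histogram of
  nearest-word assignments normalized to sum 1 (an all-zero vector for
  structureless crops), linear one-vs-rest SVM.
* **VS** — penultimate-layer CNN features (the "FC-7" recipe) into a
  standardized linear SVM.  The backbone contract is met by a desk-scale CNN
  (three conv blocks 16/32/64 + FC-128 penultimate, input 48×48) pretrained
  on an auxiliary synthetic task — stump-surface vs forest-floor crops —
  which plays the role large-scale natural-image pretraining plays for a
  full 19-layer backbone (4096-wide FC-7); such a backbone can be slotted in
  behind the same interface when weights are available locally.
* **VF** — the same backbone fine-tuned end-to-end after replacing its head
  with FC-64 / ReLU / FC-n / softmax, the new layers at 10× the base
  learning rate (the boost multiplier is a package choice; only the
  *boosted* relation is prescribed).  Desk profile: batch 16, lr 0.01,
  30 epochs; the documented full-scale profile (batch 16, lr 1e-4,
  300 epochs) is `FinetuneSpec.full_scale()`.

Training always balances classes by subsampling without replacement (the
reference protocol balances at 160 crops per class, its smallest class).
Both 2-class (rot absent/present) and 3-class modes are supported; they
differ only in label mapping and head width.

## Evaluation layer

Confusion matrices are row-true/column-predicted with a fixed class order.
Per-class accuracy strings are **truncated** to one decimal (61/73 = 83.56 →
"83.5%"): this is the single rendering convention consistent with the
shipped reference tables (28 of their 30 printed accuracies; the remaining
two are inconsistent with their own printed count rows and are flagged in
the fixture rather than reproduced).  Detection summary percentages render
precision to the nearest integer and recall truncated, matching the
reference report; exact fractions are always carried alongside.  The
`reproduce-tables` command and `reproduce_reference_tables()` recompute all
of this from the fixture counts at run time.

## Benchmarks and problem sizes

`stumprot.benchmarks` fixes the two acceptance settings:

* detector: 60 training / 40 test single-stump scenes, no occlusion, flat
  lighting — the "easy" setting; the quality bar is precision ≥ 0.9 and
  recall ≥ 0.8 at sq ≥ 0.5;
* classifiers: 160 balanced training crops per grade from 192×192 frames
  (smaller frames with proportionally larger stumps render faster without
  changing the crops), 35 held-out crops per grade; the bars are VF
  per-class accuracy ≥ 0.85 and overall-accuracy ordering BS ≤ VS ≤ VF.

These sizes keep a full run on one CPU in the tens of minutes while leaving
clear statistical margin on the bars.  All randomness flows from a single
seed through `numpy.random.SeedSequence`.

## Known limitations

* The detector's proposal stage is a sliding-window sweep, not a learned
  region-proposal network; the contract admits one, and the four-step
  alternating schedule is carried as configuration only.
* The scene model's rot region is always a single connected blob/sector;
  real rot can be annular or fragmented.
* Scores saturate near 0/1 on the synthetic task, so detector confidence is
  not calibrated as a probability.
* `render_scene` with multiple stumps rejects overlapping placements by
  retrying; extremely crowded requests can fail for large radii.
* BoF encoding of a crop with no detectable keypoints is the zero vector,
  which the SVM classifies arbitrarily (it occurs only on degenerate crops).
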