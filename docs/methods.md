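# Methods

## Problem and model

The screening task is weakly supervised: slides carry a binary diagnosis
(NILM vs neoplastic), and only neoplastic slides have coarse free-hand
polygon annotations around representative abnormal cells.  The pipeline
turns this into tile-level supervision — any tile showing at least one
annotated cell is a positive; any tissue tile on a NILM slide is a
negative — trains a tile classifier, and aggregates tile probabilities to
a slide score by taking the maximum.  Max aggregation encodes the clinical
asymmetry of screening: a single convincing neoplastic field is sufficient
to refer the slide, whereas a negative call asserts that *no* field is
abnormal.

The tile classifier is a CNN–GRU hybrid.  The backbone maps a square RGB
tile to a `g×g×c` feature map; a 7×7 max pool with stride 5 reduces it to
`g' = ⌊(g−7)/5⌋+1` per side; the pooled map is scanned row-major
(top-left → bottom-right) into a sequence of `g'²` c-dimensional vectors
consumed by a GRU of hidden size 128, whose final state feeds a single
logistic unit.  At production geometry (input 1024, backbone downsample
32) this gives grid 32 → pooled 6×6 → sequence length 36; at the reduced
test geometry (input 128, downsample 8) grid 16 → pooled 2×2 → sequence 4.
The GRU update is `h_t = z_t h_{t−1} + (1−z_t) n_t` with the reset gate
applied to the previous state inside the candidate (the original
formulation); the scan order into the GRU is a design choice the source
description leaves open, fixed here to row-major.

### Backbones

The production reference architecture for this design is an
ImageNet-pretrained EfficientNetB0.  Pretrained weights are deliberately
out of scope, and no deep-learning framework is a dependency: the package
ships its own numpy layer stack (`lbcscreen.nn` — strided 3×3
convolutions, batch norm, ReLU, max pool, GRU, linear, Adam, BCE-on-logits,
all with hand-derived backward passes, guarded by finite-difference tests).
Two backbones are registered: `tiny-cnn` (three stride-2 conv/BN/ReLU
blocks, downsample 8) and `cnn32` (five blocks, downsample 32, matching the
reference feature-grid geometry).  The identifier `efficientnet-b0` is
accepted for geometry computations and refuses to build, pointing at
`cnn32`.

### Training

Adam with β₁ = 0.9, β₂ = 0.999, lr = 0.001, decayed ×0.95 every 2 epochs;
binary cross-entropy; early stopping after 10 epochs without validation
improvement; the returned model is the best-validation snapshot.  Because
weak supervision has no natural epoch, an epoch is `steps_per_epoch`
balanced batches (default 32).  Validation loss is tile-level BCE on a
fixed balanced tile set drawn once from the validation slides; per-epoch
full-slide inference on validation would dominate runtime at any scale.

*Partial fine-tuning* trains only the batch-norm affine scale/shift inside
the backbone (plus the whole GRU and head).  This contract is implemented
and tested exactly — conv kernels are bit-identical after arbitrarily many
steps.  It pays off when the frozen kernels are pretrained; with the random
initial kernels used here it underfits, so the end-to-end synthetic
experiments train all parameters.  Both modes are exposed
(`TrainConfig.partial_finetune`).

*Hard-negative mining.*  At each epoch end, sliding-window inference over
the training NILM slides assigns each negative tile its predicted
probability `p`, and its sampling weight becomes `w = 1 + γ·p`.  The
affine form is a design choice (no formula is published): it is monotone in
`p`, keeps every tile reachable (`w ≥ 1`, no starvation), and has one
strength knob; γ = 9 makes a confident false positive ten times as likely
to be drawn as an easy tile, and γ = 0 recovers uniform sampling.
Re-weighting is per tile, not per slide.

*Augmentation* jitters brightness (±0.2 of full scale, additive),
saturation and contrast (×[0.8, 1.2]), applied in that order; ranges are
configurable and collapse to the identity.  At the reduced 512 px scale a
full-range brightness shift (±51 grey levels) overwhelms the nucleus-
darkness cue that separates neoplastic cells from benign mimics, so the
synthetic end-to-end experiments run with augmentation off; on real
stained material the cue separation is far larger than the jitter.

*Positive-tile jitter.*  Positives can be drawn off-lattice by a uniform
offset up to ±tile/4 while preserving the annotation-visibility property,
approximating "random extraction from annotated regions"; it is off by
default for reproducibility.

## Geometry conventions

Pixel coordinates are 0-based at level 0; tile squares are half-open
`[x, x+size) × [y, y+size)`; tiles that would cross the slide edge are
skipped, never padded.  The tile lattice for a W×H slide has
`(⌊(W−tile)/stride⌋+1) · (⌊(H−tile)/stride⌋+1)` cells.  A polygon
intersects a tile iff the intersection has positive area (boundary contact
does not count).  Tissue masks are computed on a mean-pooled thumbnail
(default downsample 32; cell spreads are coarse and full-resolution
masking is wasteful); foreground is the dark side of the Otsu split,
inclusive of the threshold bin, matching skimage's convention that the
bright class lies strictly above the returned threshold.  Tiles qualify as
tissue when their mask-window foreground fraction is ≥ 0.05 (default).
Slides whose heatmap is empty (no tissue found) score 0.0 — screen
negative — with a logged warning; ties in the heatmap argmax resolve to
the first cell in row-major order.

## Evaluation statistics

A slide call is positive when `score ≥ threshold` (ties positive;
threshold 0.5 by default).  Sensitivity = TP/(TP+FN),
specificity = TN/(TN+FP) = 1 − FPR, accuracy = (TP+TN)/N; undefined ratios
are reported as missing, never as 0.  The ROC curve sweeps all distinct
scores (scikit-learn), and the trapezoidal AUC is verified in tests to
equal the Mann–Whitney pair statistic exactly.  Log loss is the mean of
−[y ln p + (1−y) ln(1−p)] with p clipped to [1e−15, 1−1e−15], natural log.
Confidence intervals use the percentile bootstrap (1000 pair resamples,
2.5/97.5 percentiles); single-class resamples are redrawn (up to 100
tries), and the interval is refused if more than half the resamples fail.
BCa corrections are intentionally not applied.

Fleiss' kappa follows the standard estimator; when every rating falls in
one category the chance agreement P_e is 1 and the estimator is undefined,
and the package reports κ = 1.0 when observed agreement is also perfect —
the convention the published concordance table uses for its unanimous
binary-neoplastic subset.  Table comparisons round half-up to 3 decimals.
Interpretation bins: ≤0 poor, ≤0.20 slight, ≤0.40 fair, ≤0.60 moderate,
≤0.80 substantial, ≤1.00 almost perfect (boundary values fall in the lower
bin).

The bundled rating table reproduces the published 16-cytoscreener column
exactly (0.042, 0.098, 0.364, 0.073, 1.000, 0.568), interpreting the
published rows "NILM / Neoplastic / All cases" as case subsets by report
label — the interpretation that reproduces all values.  The published
8-senior-rater column (0.755, 0.500, 0.716, 0.815, 0.861) does **not**
reproduce from a direct Fleiss computation on raters CS1–CS8 under any
subset/scheme combination we tried (with or without the report as an
additional rater); this package makes no attempt to force agreement and
documents the discrepancy instead.

## Synthetic slides

The generator emulates the features the classifier must exploit, not
photorealism.  Background is near-white with mild Gaussian noise.  Cells
are ellipse pairs — pale cytoplasm in Pap-like tints, darker nucleus with
matching orientation — with the nucleus/cytoplasm **area ratio** (N/C) and
nucleus grey level as the class-bearing features: normal cells N/C
0.10–0.30 at grey 120–170, neoplastic cells N/C 0.55–0.90 at grey 40–90
(hyperchromatic).  Each neoplastic cell emits one 12-vertex polygon around
its cytoplasm, mimicking coarse free-hand annotation.  *Confuser clusters*
(default 2 per slide, also on NILM slides, never annotated) are tight
groups of small high-N/C cells at intermediate grey 100–140 — the
synthetic analogue of parabasal-cell clusters, the dominant false-positive
source in practice, and the workload for hard mining.

Default density is a dense monolayer: 7680 cells on a 4096² slide (120 on
the 512² desk-scale slide), 5% of cells neoplastic on neoplastic slides.
Density matters: hard mining is only meaningful when hard negatives are
rare among abundant easy tissue; at unrealistically sparse densities most
tissue tiles contain a confuser and uniform sampling already covers them.
Cohorts write PNG + GeoJSON + CSV manifests with per-slide seeds derived
from a master seed; class counts are exact (`round(n·fraction)`).

What passing synthetic tests does *not* show: robustness to stain
variation, scanner noise, debris/blood, 3D cell clusters, or the fine
morphology (chromatin texture, nucleoli) real cytology turns on.  The
synthetic results validate the pipeline mechanics and the mining
mechanism, not clinical performance.

## Reduced-scale study conditions

Desk-scale experiments divide the production geometry by 8: 512² slides,
128 px tiles, stride 64, `tiny-cnn`, mask downsample 8.  The end-to-end
experiment trains on 30 slides (50% neoplastic, master seed 7), validates
on 10, and scores 20 held-out slides; 16 epochs of 24 batches of 8.  The
hard-mining contrast repeats training with mining on/off for seeds 7, 8, 9
and counts held-out NILM tiles with p > 0.5.  These sizes are the
package's reference conditions for its own tests; they fit comfortably in
a few CPU-minutes.

## Numerical choices

float32 weights and activations; He initialisation for conv, Glorot for
the head, U(−1/√H, 1/√H) for the GRU; BCE computed on logits in the
stable form `max(z,0) − zy + log(1+e^{−|z|})`; batch norm uses biased
batch variance with ε = 1e−5, momentum 0.1 running stats (eval mode uses
running stats).  Training histories are bit-reproducible for a fixed seed
with augmentation off (single-threaded numpy).  NaN/inf loss aborts with
diagnostics rather than continuing.

## Known limitations

- No pretrained backbone: transfer learning, the main reason partial
  fine-tuning exists, cannot be exercised; it is tested as a contract.
- Single-level slide access; pyramidal TIFF levels are recorded as
  metadata only, and SVS needs an external reader plugged into
  `Slide.from_array`.
- The GRU consumes one sequence per tile; cross-tile recurrence is not
  modelled.
- Bootstrap CIs are percentile-only.
- Kappa standard errors and weighted variants are out of scope.
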