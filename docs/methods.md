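# Methods

This document records the model, the fixed parameters, the synthetic-data
generator and the numerical/design decisions behind `sirmil`.

## Problem setting

Liver-biopsy slides stained with Sirius Red render collagen red against
green/yellow counterstain. Fibrosis severity follows the NASH-CRN ordinal
stage 0–4; the tool binarizes it at the stage-2/3 boundary (**mild ≤ 2**
vs **severe ≥ 3**, severe being the positive class). The diagnostic signal
for severe disease — bridging fibrosis — is sparse: a few thin collagen
bands in a gigapixel slide. Portal tracts stain red in every liver, so red
content alone does not separate the classes. Supervision is weak: only the
slide-level stage is available.

## Pipeline

### Tiling (`slideio`)

1. Read the slide (pyramidal TIFF via `tifffile`, choosing the level whose
   magnification is nearest the requested one, or a plain raster via
   Pillow).
2. Tissue mask: HSV saturation > 0.25, 5×5 median filter, binary hole
   filling (`scipy.ndimage`). A precomputed mask can be supplied instead.
3. Tile grid: square tiles of side `s` (default **1651 px at 5×**) with
   fractional overlap `o` (default **0.5**). The stride is the exact
   `floor(s·(1−o))`, computed with `fractions.Fraction` because plain float
   multiplication can land an epsilon below an integer and floor one stride
   short. Tiles are row-major; tiles overhanging the border are dropped.
4. Per-tile scores: tissue fraction (mask mean) and red-pixel fraction
   (hue in [0°, 25°] ∪ [335°, 360°], saturation ≥ 0.30, value ≥ 0.20).
5. Adaptive selection: keep tiles with tissue fraction ≥ t, starting at
   **t = 0.5** and lowering by **0.05** per iteration (floor 0.05) until at
   least **10 tiles** survive; if even the floor fails (crumbling or faded
   tissue), fall back to the 10 tiles with the highest tissue fraction.
   Ties inside the threshold rule never arise (the rule is a pure filter);
   the fallback orders by descending fraction, then ascending (y, x).

### Bags (`bagbuild`)

- **RED-1**: one bag per slide containing the k tiles with the highest red
  fraction (ties broken by ascending (y, x) so the result is
  deterministic). Cheap, but red-content ranking is misled by portal
  tracts and red-vein artifacts.
- **RAND-n**: a seeded permutation of the slide's valid tiles split into
  consecutive blocks of k, giving ⌊N/k⌋ pairwise-disjoint bags; leftover
  tiles are discarded. A slide with fewer than k tiles cannot form a
  RAND-n bag — the builder raises and the caller falls back to one RED-1
  bag of all available tiles (that is what `build_bags` does).
- Bags inherit the slide's label as a **proxy label**; for RAND-n this is
  deliberately noisy (a random bag from a severe slide may contain no
  lesion), which MIL training tolerates.
- Tiles are resized to the encoder input (default **224 px**) with Pillow
  bicubic interpolation, then normalized to `[−0.5, 0.5]` float64 CHW.
- Augmentation (training only): independent 50 % horizontal and vertical
  flips and a uniform 90°-multiple rotation per tile, seeded per
  (seed, epoch, batch).

### Model (`milmodel`, `nn`)

The encoder maps each tile to a d-dimensional embedding:

- `tiny_cnn` (d = 64): three stride-2 conv+BN+ReLU stages, a
  squeeze-and-excitation block, global average pooling. Small enough to
  train from scratch on a CPU; used by the tests and scaled experiments.
- `resnet18` / `se_resnet18` (d = 512): standard BasicBlock residual
  stacks, the SE variant inserting squeeze-and-excitation into every
  block. Same layers, same code path, for full-scale use.

Squeeze-and-excitation (reduction 16, no biases):
`s = σ(W₂·relu(W₁·gap(x)))`, channels rescaled by `s`.

Gated attention over the k embeddings `h₁…h_k` (no biases):

```
score_j = wᵀ( tanh(V h_j) ⊙ σ(U h_j) )
a = softmax(score)            z = Σ_j a_j h_j
p(bag) = σ(w_cᵀ z + b_c)
```

The alternative `max_pool` aggregation scores each tile with the classifier
and takes the maximum probability; its gradient flows only through the
argmax tile. Both aggregations are permutation invariant by construction.

All of this is plain NumPy with handwritten backpropagation (im2col
convolutions, batch-norm backward, softmax Jacobian for attention). The
test suite verifies every parameter's analytic gradient against central
finite differences.

### Training (`training`)

- Folds: 5-fold cross-validation stratified on label × colour-appearance
  category, 70 % train / 10 % validation / 20 % test per fold. Strata
  smaller than the fold count are distributed as evenly as possible (with
  a warning); validation slides are drawn from the non-test remainder by
  largest-remainder apportionment so every fold's shares are exact.
- Loss: bag-level binary cross-entropy on the proxy labels, probabilities
  clamped to [1e−7, 1−1e−7].
- Optimizer: Adam with two parameter groups — encoder **lr 1e−5**, heads
  (attention + classifier) **lr 1e−4** — weight decay 1e−4 (L2), batch of
  **6 bags**, up to 50 epochs.
- Early stopping: patience 10 on validation loss (training loss when no
  validation split is given); the best-validation weights are restored.
- Determinism: weight init, epoch shuffling and augmentation draws are all
  seeded; two runs with the same seed produce identical weights.

### Inference and evaluation (`evaluation`)

A slide's bags are scored independently; the slide score is the **maximum**
bag probability ("one wins all" — the most severe region decides, mirroring
how staging works clinically) and the call is severe iff the score ≥ 0.5.
Consequence: adding bags can only raise a slide's score, never lower it.

Metric panel, severe = positive:

- Per fold: Accuracy and F1, reported as mean ± sample (n−1) sd across
  folds.
- On the entrywise sum of the fold confusion matrices: Recall,
  Specificity, Precision, F2, MCC. Zero-denominator metrics are reported
  as NaN, never silently 0.
- AUC on the pooled test scores (`sklearn.metrics.roc_auc_score`);
  per-fold AUC averaging is available as an option.

`export_attention` ranks every tile of a slide by its attention weight and
writes a CSV plus the top-N tile PNGs — the artefact a pathologist reviews
to check the model attends to actual fibrosis. It refuses max-pooling
models, which have no attention weights.

## Synthetic slides (`synthdata`)

Real Sirius-Red cohorts cannot ship with a code package, so tests and
scaled experiments run on a seeded generator:

- **Tissue**: 2–3 elongated elliptical strips mimicking needle-core biopsy
  fragments on a white background, in one of three colour-appearance
  categories (green/grey, green/blue, yellow/grey, default cohort weights
  75:56:21).
- **Both classes**: 3–8 red portal blobs per slide (the natural-collagen
  confounder) placed inside tissue.
- **Severe only**: ≥ 1 Bezier-curved red bridging band whose endpoints lie
  within one tissue core; count is Poisson with mean `lesion_density`,
  width and span configurable.
- **Optional artifacts**: red vein streaks (both classes — these mislead
  red-content ranking), crumbling holes, stain fading, plus Gaussian pixel
  noise.
- Ground truth (tissue mask, lesion inventory with disk decompositions,
  label) is stored next to each slide, so tests can check e.g. that
  bridge-overlapping tiles out-score clean tiles on red fraction, or that
  a trained model's top attention tiles hit the bridge.

Scope and limits: slides are 512 px (8× the 64 px test tile side), single
resolution, no pyramid; textures are flat colour + noise, not histology;
the generator's purpose is controlled signal/confounder geometry, not
visual realism. Class difficulty is tunable via `lesion_density`,
`min/max_bridge_span`, `bridge_width_px` and `artifact_rate`.

## Scaled experiment conditions

The full-scale configuration (1651 px tiles, 224 px inputs, ResNet-18
encoders, 150+ slide cohorts) does not fit a CPU test budget. The
acceptance experiments therefore run a faithful scale model: 64 px tiles on
512 px slides, 32 px encoder inputs, `tiny_cnn` + gated attention
(attention dim 64), RAND-n k = 5, Adam lr 1e−3 for both groups, batch 6,
≤ 15 epochs with patience 5, augmentation on. Under these conditions one
fold on 80 slides trains in ~2–4 minutes on one CPU and reaches
accuracy ≥ 0.85 / AUC ≥ 0.9 in the majority of seeds, and RAND-n bags
match or beat RED-1 recall when vein artifacts are enabled — the same
directional finding that motivates random bagging at full scale.

## Numerical and design decisions

- **Exact stride arithmetic**: `Fraction`-based floor in the tile grid
  (see above) so grids are bit-identical across platforms.
- **float64 everywhere**: CPU-bound workloads gain little from float32,
  and float64 keeps the finite-difference gradient checks tight.
- **NaN over 0 for undefined metrics**: a recall of 0/0 is "no positives
  present", not "model recalled nothing"; JSON export maps NaN to null.
- **No biases in SE and attention**: follows the standard formulations of
  both blocks; biases there add parameters without changing expressivity
  materially.
- **Proxy-label consistency check**: training refuses bags from one slide
  with conflicting labels — that is always an upstream bug.
- **Checkpoints** are NumPy `.npz` archives of the state dict plus a JSON
  sidecar with the model configuration; loading reconstructs the model
  exactly (verified by round-trip tests).

## Limitations

- The NumPy encoders train well at the scaled-down size; full-scale
  ResNet-18 on 224 px tiles is functional but slow without a GPU
  framework — the architecture is provided for completeness and for
  checkpoint interchange, not speed.
- Single-magnification tiling; no stain normalization beyond the HSV
  thresholds; colour thresholds were set for Sirius Red and will need
  retuning for other stains.
- The synthetic generator demonstrates the method's mechanics; performance
  numbers on it do not transfer to clinical cohorts.
- Binary severity only; the ordinal 0–4 staging problem is out of scope.
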