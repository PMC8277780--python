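# Methods

## Problem setting and model

`ordmil` classifies whole-slide images (WSIs) into K ordered diagnostic
grades using only slide-level labels. The default label space is the
three-grade colorectal scheme — non-neoplastic (0) < low-grade lesion (1)
< high-grade lesion (2), with high-grade encompassing high-grade dysplasia
(including intramucosal carcinoma) and invasive adenocarcinoma — but K ≥ 2
with arbitrary strictly-increasing class values is supported.

The weak-supervision model is the ordinal MIL premise: a slide of grade Y
contains no tile of a grade above Y and at least one tile of grade exactly
Y. Under this premise the most severe tile determines the slide, which
motivates both the selection rule and the single-tile decision rule:

* **Tile ranking.** The backbone maps each tile to a probability vector
  p on the K-simplex; the tile score is the expected severity
  Σᵢ xᵢ·pᵢ with xᵢ = 0…K−1. The score is monotone under mass transfer
  toward more severe classes, so it orders tiles by predicted severity
  even when no single class dominates.
* **Training.** Per epoch: score every tile of every training slide with
  the *epoch-start* parameters (a snapshot, so reruns are reproducible
  and the selection provenance is well defined), select the top tile per
  slide (ties → lowest manifest index), then optimise on the selected
  tiles in shuffled mini-batches of 32.
* **Decision.** The slide grade is the argmax of the top-ranked tile's
  probabilities; rounding the expected value to the nearest class value
  is available behind `TrainConfig.decode="expected"`. The evidence tile
  is always returned for review.

## Loss

Agreement for ordinal grading is measured by the quadratic weighted kappa
(QWK): with confusion counts Cᵢⱼ, weights wᵢⱼ = (i−j)²/(K−1)², and
chance-expected matrix Eᵢⱼ = rowᵢ·colⱼ/n,

κ = 1 − Σ wᵢⱼCᵢⱼ / Σ wᵢⱼEᵢⱼ.

The training loss replaces C by the *soft* confusion S, where sample s of
true class y adds its whole probability vector to row y. The loss is
1 − κ_soft; it is differentiable, reduces exactly to 1 − κ(hard) on
one-hot predictions, and its gradient w.r.t. the probabilities is
available in closed form (a ratio of two affine functions of p; the
gradient is taken in the simplex gauge, i.e. treating the batch mass as
constant, which is exact along the directions a softmax layer can
produce). A `log` variant −log((1+κ_soft)/2 + ε) is available; the
denominator is guarded by ε = 1e-9.

**Cross-entropy stabiliser.** Pure κ optimisation has a known pathology:
κ rewards inflated expected disagreement, i.e. extreme prediction
marginals, and on the synthetic fixture we observed convergence to a
local optimum that never predicts the interior grade (82 % tile accuracy
despite linearly separable features), as well as a flat constant-
prediction plateau (κ_soft = 0 for any prediction shared by all samples)
from which a saturated softmax cannot escape. Two measures address this:

1. the objective is `(1 − κ_soft) + ce_weight · CE` with
   `ce_weight = 0.5` by default (0 restores the pure kappa loss); the
   per-sample likelihood term breaks the plateau symmetry while the
   ordinal weighting still dominates near the optimum;
2. backbone logits are clamped to ±10, keeping the softmax away from
   exact saturation so Adam's per-parameter normalisation can recover
   from confident-constant states.

With both measures the MIL loop converged on every probe seed (8/8),
versus 5/8 for the pure loss.

## Backbone

The backbone contract is minimal: featurise a tile, map features to
simplex probabilities, take one optimiser step. The provided
`TextureBackbone` is deliberately compact so the full pipeline trains in
seconds on a CPU: a fixed bank of 10 texture statistics (per-channel
means, grey-level spread, Sobel edge density, dark-pixel fractions at two
cut-offs, saturation mean/spread, grey mean — all scaled to ≈[0, 1] and
normalised with fixed constants, never batch statistics) feeding a
one-hidden-layer tanh network (16 units) with a softmax head, trained by
Adam with analytic gradients. Evaluation-mode predictions are a pure
function of the parameter state, which the determinism tests rely on.
Heavier convolutional backbones plug in behind the same contract.

Reference hyper-parameters follow the standard recipe for this pipeline
(batch 32, Adam, learning rate 1e-4, 512-px tiles, two warm-start
epochs); the desk-scale synthetic studies use 128-px tiles, learning rate
5e-2 and 30 epochs (`ordmil.experiments.desk_config`), chosen once for
the small network and problem size.

## Tiling

Tissue is detected on a downsampled pyramid level by thresholding HSV
saturation: stained tissue is saturated, glass is not. The threshold is
Otsu's, computed on saturation clipped at 0.25 so strongly stained nuclei
cannot pull the split into the tissue itself, floored at 0.02, and
applied with hysteresis (low threshold = max(0.25·Otsu, 0.02)): pixels
above the Otsu split seed regions that absorb connected pixels whose
noise dips below it. Specks under 64 mask px are removed and equally
small holes filled. The mask level is the coarsest pyramid level whose
long side is ≥ 96 px — local-mean downsampling suppresses the rare pixel
whose noise would otherwise breach even the low threshold.

Tiles come from the non-overlapping level-0 grid (stride = size by
default, configurable), fully inside slide bounds, row-major; a tile is
kept when its tissue fraction reaches the threshold (default 1.0 — pure
tissue). A slide with no qualifying tile keeps its single best tile
flagged `fallback=true`, because the MIL engine needs ≥ 1 tile per bag.
Coordinates are 0-based, half-open, level-0 frame.

## Region annotations

Annotations are polygons tagged with a diagnostic grade or a
non-diagnostic class (lymphocytes, fulguration). For supervised
pre-training they are reduced to tile labels by area: a tile takes a
diagnostic class when regions of that class cover ≥ 50 % of its
footprint; among classes that reach the bar the most severe wins
(consistent with the MIL premise); non-diagnostic tags never label a
tile, and unlabelled tiles are excluded. Pre-training runs 2 epochs of
fully-supervised learning on the labelled tiles with the same loss as
the MIL stage (cross-entropy selectable via config).

## Synthetic data

The generator emulates exactly the statistical structure the method
assumes, at desk scale:

* tiles are 128-px RGB textures: dark elliptical blobs (a crude nuclear-
  crowding analogue) placed uniformly on a noisy pink background; blob
  counts per tile are drawn uniformly from disjoint, strictly increasing
  per-grade ranges ((2–8, 14–24, 32–46) per 128² px, scaled by area);
* slide labels are drawn from a uniform prior over the three grades;
  tiles per slide are uniform on 4–12, mimicking the large tissue-driven
  variability of real cohorts; in a lesion slide 35 % of tiles are
  lesional with grades ≤ Y and at least one exactly Y, so the MIL
  premise holds by construction on every slide;
* 25 % of slides are "annotated": they carry exact per-tile rectangle
  annotations derived from the generator's own placement;
* each slide has its own child RNG keyed by (seed, slide index), so any
  slide regenerates byte-identically without rebuilding the dataset;
* slides can be mosaicked onto a white canvas (unfilled grid cells stay
  glass-white) and written as pyramidal TIFFs; re-tiling that mosaic at
  threshold 1.0 recovers the generator's grid exactly.

What the generator does **not** emulate: stain variability and scanner
domain shift, tissue morphology (glands, stroma, artefacts), label noise,
intra-class texture heterogeneity, and the gigapixel scale of real WSIs.
Passing tests therefore demonstrate the correctness and internal
consistency of the pipeline — selection, loss, geometry, bookkeeping —
not clinical-grade performance; the texture classes are separable by
design, which is what makes minute-scale convergence checks possible.

## Experiment designs

Three canonical studies (`ordmil.experiments`), each reported as a median
over three consecutive seeds:

* **End-to-end**: 80 slides (60 train / 20 test; 15 % of the training
  slides held out, stratified, for validation), 30 epochs. Checkpoint =
  maximal validation QWK.
* **Subset scaling**: 260 slides (200 train / 60 test), nested subsets of
  20/60/200 drawn once per seed as prefixes of one shuffle, all evaluated
  on the same test set. The epoch budget is 15: every subset gets the
  same recipe, so larger subsets see proportionally more gradient steps —
  the data-limited regime in which a learning curve is informative; with
  twice the budget even 20 slides saturate this separable task and the
  curve degenerates into sampling-noise ties.
* **Pre-training gain**: 160 slides, epochs to reach validation QWK ≥ 0.8
  with versus without the two-epoch supervised warm-start on the
  annotated fraction. The larger cohort keeps the validation split big
  enough that the epoch-counting comparison is stable.

Problem sizes were chosen so the whole acceptance run finishes in a few
minutes on one CPU while each effect (convergence, scaling, warm-start
speed-up) is reproducible across seeds.

## Numerical choices and degenerate inputs

* QWK denominator guard ε = 1e-9; an all-in-one-diagonal-cell matrix is
  perfect agreement (κ = 1); a zero matrix is a contract violation.
* Simplex tolerance 1e-6 on probability vectors.
* Ranking ties break to the lowest manifest index; subset shuffles,
  validation splits and batch orders all derive from the run seed through
  named child streams, so identical configs reproduce identical metrics
  byte-for-byte.
* Slides smaller than one tile yield an empty grid (not an error); the
  degenerate no-tissue slide is handled by the fallback tile.
* Means in cohort tables are rounded half-up to 2 decimals (`Decimal`,
  not float bankers' rounding); mean-tile and tile-count ratios are
  reported to the nearest integer and slide-count ratios truncated to one
  decimal, matching how such tables are conventionally printed.

## Known limitations

* The texture backbone cannot represent morphology-level features; on
  real slides a convolutional backbone behind the same contract is
  required.
* Single-tile decisions are exactly as brittle as the premise: a single
  false-severe tile flips the slide. The evidence tile in every
  prediction exists to make that failure mode auditable.
* Recurrent or attention-based aggregation of multiple tiles is out of
  scope by design; the engine trains and predicts on one tile per slide.
* The tissue mask is a saturation heuristic; pen marks, coverslip edges
  and heavy pigment can masquerade as tissue.
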