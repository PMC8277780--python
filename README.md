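# ordmil — weakly-supervised ordinal MIL for whole-slide cancer grading

Digital-pathology slides are gigapixel images, but a diagnosis is a single
ordinal label per slide — for colorectal biopsies, *non-neoplastic* <
*low-grade lesion* < *high-grade lesion*. Annotating every tile of every
slide is infeasible, so `ordmil` implements the weakly-supervised
alternative: **multiple instance learning (MIL)** over the slide's tiles
using only the slide-level grade, with the label order built into both the
tile-selection rule and the training loss. It is aimed at computational
pathology researchers who want a tested, CPU-scale reference implementation
of this pipeline — tiling, ranking, training, evaluation and reporting —
plus a seeded synthetic-slide generator so every stage runs in minutes
without any slide archive.

## The method

A slide is a *bag* of 512×512 tiles kept only when they contain 100 %
tissue (saturation-threshold mask on a downsampled pyramid level). The MIL
premise for ordinal grades: a slide of grade *Y* contains no tile more
severe than *Y*, and at least one tile of grade exactly *Y*.

Given backbone class probabilities *p₁ … p_K* for a tile, its severity
score is the expected value

```
tile_score = Σᵢ xᵢ · pᵢ ,   xᵢ = 0, 1, …, K−1
```

Each training epoch (1) scores all tiles of every training slide with the
epoch-start model, (2) takes the top-scoring tile per slide, paired with
the slide label, and (3) optimises the backbone on those tiles in batches
of 32 with a differentiable **quadratic weighted kappa (QWK)** loss. With
soft confusion matrix *S* (accumulated probability mass), weights
*w₍ᵢⱼ₎ = (i−j)²/(K−1)²* and expected matrix *E* from the marginals,

```
κ_soft = 1 − Σ wᵢⱼ Sᵢⱼ / Σ wᵢⱼ Eᵢⱼ ,   loss = (1 − κ_soft) + λ·CE ,
```

where the small cross-entropy term (λ = 0.5 by default) anchors each
sample to its own label — pure κ optimisation admits degenerate optima
with extreme prediction marginals (see `docs/methods.md`). On one-hot
predictions the κ part reduces exactly to the hard QWK metric. Inference
is single-tile as well: the slide's predicted grade is the argmax of the
top-ranked tile's probabilities, and that tile is reported as evidence.
An optional two-epoch supervised warm-start consumes region annotations
(GeoJSON polygons) reduced to tile labels by majority-area coverage.

Slides can be read from pyramidal TIFFs, from directories of PNG tiles
with a JSON sidecar, or generated synthetically: seeded slides whose tile
textures (dark nuclear-like blobs on a pink background, density increasing
with grade) satisfy the MIL premise by construction.

## Worked example

```python
from ordmil import OrdinalMILModel

model = OrdinalMILModel.from_synthetic(seed=7, n_slides=80)
res = model.fit()
print(res.summary())
```

```
Ordinal MIL slide classifier
============================================================
classes:        non-neoplastic < low-grade < high-grade
bags:           train=60, val=0, test=20
loss:           qwk (ce_weight=0.5)
optimizer:      adam, lr=0.05, batch=32
epochs:         30 (best @ 7), pretrained=False
seed:           7
------------------------------------------------------------
train  QWK=+1.000  accuracy=1.000  lesion sensitivity=1.000  (n=60)
test   QWK=+1.000  accuracy=1.000  lesion sensitivity=1.000  (n=20)
```

The summary reports slide-level QWK (chance-corrected, order-aware
agreement; 1 = perfect), plain accuracy, and lesion sensitivity (the
fraction of truly lesional slides flagged as lesional — the clinically
critical number). `res.predict(...)` adds, per slide, the predicted grade,
its probabilities and the evidence tile the decision came from:

```
slide_id  label  prediction  evidence_x  evidence_y  p_non-neoplastic  p_low-grade  p_high-grade
 syn0000      1           1           0         128          0.138254     0.807794      0.053951
 syn0004      0           0         256         128          0.874948     0.124806      0.000246
 syn0009      2           2         256         128          0.000042     0.007308      0.992650
```

A 15 % stratified validation split is held out of the training slides and
the checkpoint with maximal validation QWK is kept. The same pipeline is
scriptable from the shell: `ordmil simulate | tile | pretrain | train |
predict | evaluate | stats | subset-experiment` (see `ordmil --help`).

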