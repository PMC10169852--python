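# Methods

## Problem setting

A whole-slide image carries a single label: healthy, or one of four tumor
grades (superficial and nodular — low-aggressive; medium; high). Severity is
ordered healthy < superficial < nodular < medium < high, and a slide or case
with mixed growth patterns inherits the worst grade present. Three tasks
share this schema: T1 collapses all grades into "tumor" (2 classes), T2
groups superficial+nodular as low-risk and medium+high as high-risk
(3 classes), T3 keeps all five. T2 is by construction a coarsening of T3,
which the tests assert for every subtype.

## Pipeline model and assumptions

**Tiling.** Slides are cut into non-overlapping 224×224 patches at 10X.
Native scans at higher magnification are downsampled by the integer
native/target factor with area averaging. Grid boxes are half-open
`[x, x+224) × [y, y+224)`, 0-based; incomplete right/bottom tiles are dropped
rather than padded so every model input has the same shape. Patches with
tissue fraction ≥ 0.15 are retained ("at least 15%" is a closed bound — a
fraction of exactly 0.15 survives).

**Tissue detection.** No ground truth exists for this step on real slides, so
the rule is declared, not inferred: a pixel is tissue when its HSV saturation
exceeds an Otsu threshold clipped into [0.08, 0.20] and its value is below
0.95, excluding ink (saturated hues in [0.25, 0.72] — green through blue — or
low-value, low-saturation black strokes). The Otsu ceiling matters: strongly
stained tumor can be far more saturated than pale stroma, and an unclipped
bimodal split would then cut between tissue kinds instead of between tissue
and glass. The hue band deliberately stops below the H&E pinks and violets
(hue ≳ 0.75). Pen marks are thereby never tissue, which the tests check with
ink-only images.

**Contrastive pretraining.** Two stochastic views per patch (random resized
crop at scale 0.6–1.0, horizontal/vertical flips, mild brightness/contrast ×
0.85–1.15 / 0.8–1.2, saturation jitter, occasional grayscale, Gaussian blur),
NT-Xent with temperature τ = 0.5 over cosine similarities, self-similarity
excluded from the denominator. A batch of one positive pair has loss exactly
0; the loss is invariant under a common orthogonal rotation of the
embeddings — both are test oracles. The jitter is kept mild on purpose: slide
grade correlates with stain intensity and chroma, and aggressive photometric
augmentation would instruct the encoder to discard exactly that signal.
Full-scale defaults follow the published recipe (batch 512, 32 epochs, Adam
lr 1e-4 cosine-annealed to zero, weight decay 1e-6, 18-layer residual
backbone with 512-wide features). Desk-scale runs use a 3-conv encoder
(32-wide features, 32 px inputs, batch 32, 8 epochs, lr 1e-3). Neither
encoder uses batch statistics, so extracted features are exactly independent
of batching. Test patches are excluded from pretraining by the caller.

**Patch graph.** Edge (i, j) iff the Chebyshev distance between grid
coordinates is 1 (4 sides + 4 corners, degree ≤ 8). Components are never
relinked: multiple tissue sections, and multiple sectioning levels on one
glass, are simply more disconnected components. The model consumes only the
adjacency and node features — grid coordinates never enter the forward pass —
so translating a component is a bit-exact no-op. The normalisation
`Â = D̃^{-1/2}(A+I)D̃^{-1/2}` (self-loops added only here) is a declared
convention; an edgeless graph yields the identity.

**Classifier.** `H' = relu(Â H W)` (one GCN layer by default), then min-cut
pooling: a row-stochastic soft assignment `S = softmax(H Wₚ)` gives pooled
tokens `SᵀH`, pooled adjacency `SᵀAS`, the relaxed normalised-cut loss
`−tr(SᵀAS)/tr(SᵀDS)` ∈ [−1, 0] and the orthogonality penalty
`‖SᵀS/‖SᵀS‖_F − I/√k‖_F` ∈ [0, 2]. Graphs with fewer nodes than clusters use
the identity assignment with zero auxiliary losses. The transformer is a
standard pre-LayerNorm encoder — 3 blocks, MLP width 128, multi-head
self-attention, learned class token, GELU in the MLP, ReLU in the GCN — with
**no sequence positional embeddings**: spatial context is the graph's job,
which makes the logits invariant to token permutation (asserted at 1e-5).
Widths that the recipe leaves open are declared defaults: 8 heads and
64-wide tokens at full scale (32 wide / 4 heads at desk scale), k = 100
pooled clusters at full scale (8 at desk scale), all configurable. Slides
whose graphs have zero retained patches are rejected with an error rather
than given a default class.

**Training.** Cross entropy plus the two pooling losses (weight 1.0),
Adam with batch 4 (gradient accumulation over graphs), 100 epochs, lr 1e-3
stepped ×0.1 at epochs 40 and 80, weight decay 1e-5; the same
hyperparameters serve all tasks. No class re-weighting by default (a flag
exists). Cross-validation is 5-fold over *cases*: folds are as even as the
case count allows (e.g. 7 cases over 5 folds give sizes {2,2,1,1,1}), and all
slides of a case share a fold. The fold models are ensembled by majority
vote; ties go to the highest mean probability among the tied classes (a
declared rule — ties are possible with 5 voters and ≥3 classes).

**Metrics.** Accuracy = trace/total of the confusion matrix; per-class
sensitivity TP/(TP+FN) and specificity TN/(TN+FP), one-vs-rest; one-vs-rest
ROC AUC from predicted probabilities. A class absent from the truths has
undefined sensitivity and is reported as missing, never as 0. Mean CV ROC
curves use vertical averaging of fold TPRs on a fixed FPR grid.

**GraphCAM.** After a backward pass from the target-class logit, each block
contributes `W_b = mean_heads(relu(∂logit/∂attn ⊙ attn))`; rollout
`R = Π_b rownorm(I + W_b)` respects the residual paths, and the class-token
row of R (excluding the class token) is the token relevance. Patch scores are
`S·r`, max-normalised to [0, 1], rendered as a colormapped
(default jet, α = 0.5) overlay on a slide thumbnail; background pixels are
untouched.

## Numerical core

All neural components run on a small reverse-mode autodiff engine over
float64 numpy arrays (matmul incl. batched, broadcasting arithmetic,
reductions, relu/GELU (tanh form)/exp/log/sqrt, row softmax, layer norm,
im2col for convolutions). Every primitive's gradient is checked against
central finite differences in the test suite, and a full transformer block is
gradient-checked end-to-end. Adam uses the standard bias-corrected moments
with L2 weight decay added to the gradient. All randomness flows through
explicit `numpy.random.Generator`s, so identical seeds give identical models,
losses and predictions.

## Synthetic slides: what they emulate, and what they do not

The generator plants: a near-white background; 1–8 connected tissue sections
(star-shaped perturbed ellipses placed on a cell grid so that any two
sections, and tissue and the canvas border, are separated by at least
`min_separation_px` of background — the default 480 px exceeds twice the tile
size, so separate sections can never become graph-adjacent); a tumor region
of an *exact* requested area fraction inside each section (pixels are chosen
by quantile, of boundary distance for the superficial band or of a smoothed
Gaussian field whose kernel sets the motif: large isotropic → nodular nests,
anisotropic medium → strands, fine → infiltrative threads); per-grade
darkening vectors whose magnitudes order mean tumor intensity by grade and
whose directions differ in hue, so both simple statistics and a small encoder
can discriminate the classes; and optional blue/black pen strokes on the
background margin. Cases own 1–2 slides so grouped splitting has work to do.

Desk-scale study conditions: 2048×2048 px canvases at native 10X (sections
capped at 300 px radius, giving roughly 5–25 retained patches per slide),
tumor fraction drawn from [0.28, 0.42], pen marks on a quarter of slides,
60 training + 30 held-out slides over three classes (healthy / nodular /
high under T2) for the end-to-end study. These sizes keep a full run at a
few minutes on one CPU while leaving the graphs genuinely disconnected and
multi-component.

The motifs are geometric stand-ins, not histology: no nuclei, no stain
deconvolution realism, no scanner artifacts beyond pen marks, and class
signal that is far cleaner than real BCC. Passing the end-to-end criteria
therefore demonstrates that the pipeline's machinery — tiling, held-out
contrastive features, disconnected graphs, grouped CV, ensembling,
explanation — is wired correctly and can learn; it says nothing about
accuracy on clinical slides.

## Known limitations

- The pure-numpy engine is single-threaded and desk-scale; gigapixel slides
  and the full 512-wide residual encoder are out of practical reach here,
  though the code paths exist and are tested at small widths.
- GraphCAM relevance on these synthetic slides is fairly diffuse (scores
  often span only the top half of [0, 1]) because most tissue patches carry
  some tumor signal; the localization metric (top-decile overlap with the
  planted mask) is the meaningful summary.
- Tissue detection thresholds are tuned to H&E-like palettes; other stains
  would need the HSV constants revisited.
- The severity order places superficial below nodular within the
  low-aggressive group. The grading system numbers them Ib and Ia
  respectively, so the within-group order is a convention; it cannot affect
  T1 or T2, which pool the two.
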