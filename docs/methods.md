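# Methods

## Model

A slide is a bag of n cell embeddings (n × D, D set by the upstream
encoder; 1000 for the hematology encoder this design targets, configurable).
The forward computation:

1. **Aggregator network** — affine D→d followed by GELU (softplus instead
   when the generalized mean is among the aggregations, keeping its inputs
   nonnegative). The reduced cells are summarised by the configured
   aggregation functions; the default set is {mean, variance}. Variance is
   the population form (divide by n) plus a floor `variance_eps = 1e-8`:
   bags are large (300-400 cells) so the n vs n−1 distinction is
   negligible, and the population form is defined at n = 1. The
   generalized mean uses a fixed exponent (default p = 3) and is not
   learned.
2. **Parallel network** — affine D→d + GELU per cell.
3. The k summary vectors are prepended as class tokens; the (k+n) × d
   sequence carries **no positional encoding** (a bag is a set; this also
   makes the permutation properties exact rather than approximate).
4. **Self-attention** — `attn_layers` (default 1) layers of multi-head
   attention (default 4 heads, d = token_dim divisible by heads), residual
   connection, no layer normalisation: at these widths training is stable
   without it and the forward pass stays easy to verify against a
   straight-line oracle. The implementation always materialises the
   post-softmax attention weights — a fused kernel that cannot expose them
   would break the explanation path.
5. **Classifier** — the k post-attention class-token outputs are
   concatenated (k·d) and passed through a 2-layer MLP (hidden width
   `mlp_hidden`, default 64) to the class logits. Dropout (default 0.1)
   applies to the attention output and the MLP hidden layer during
   training only.

**Masked attention.** Per-cell scores come from the final layer's
head-averaged attention matrix: rows 0..k−1 (class-token queries) restricted
to columns k..k+n−1 (cell keys). Mass that class tokens place on each other
is discarded and each row renormalised over cells; the cell score is the
mean of the k rows, renormalised. Head- and token-averaging is the
least-committal reduction; both are isolated in `extract_masked_attention`
and straightforward to change.

The aggregator and parallel networks do not share weights. Depth is one
affine layer each: the source architecture's depths are not published, and
a single layer suffices for the study conditions here while keeping the
independent-oracle tests short.

## Training

Adam (lr 1e-3 default), one bag per step, cross-entropy on slide labels.
Every epoch each training slide contributes one fresh uniform subsample of
300-400 cells — the same protocol a hematopathologist approximates by
reviewing ~300 cells — which doubles as data augmentation. Early stopping
tracks validation AUROC (one fixed subsample per validation slide for a
stable signal) with patience 10 by default; among epochs with equal
validation AUROC the **latest** wins, because once AUROC saturates,
continued loss minimisation still sharpens the attention distribution (the
interpretability outputs keep improving after the ranking metric stops
moving). The learning rate is deliberately larger than typical
transformer defaults: the networks are tiny (tens of thousands of
parameters) and the synthetic signals strong, so 1e-3 converges in a few
epochs; it is config-driven for other regimes.

All randomness derives from a single integer seed per fit via
`numpy.random.SeedSequence` spawning (init / subsampling / dropout /
validation streams), so identical config + seed reproduces parameters,
history and metrics exactly.

**Prediction** averages softmax outputs over `n_repeats` (default 8)
independent subsamples; attention is reported from the first subsample,
mapped back to the full bag with unsampled cells scored 0 and flagged
not-evaluated. `n_repeats = 1` reproduces single-pass behaviour and is the
default in the limit-of-detection experiment, mirroring a single 300-400
cell draw per synthetic patient.

**Splits** are at the patient level: patients (not slides) are shuffled and
partitioned per label stratum, so split sizes are within one patient of the
targets per stratum, and no patient's slides ever straddle splits (asserted
on every run). A mixed-label patient takes the label of their first slide,
with a warning.

## Baselines

*Gated-attention MIL*: a_i ∝ exp(wᵀ(tanh(V h_i) ⊙ σ(U h_i))), bag
representation Σ a_i h_i, linear head; trained identically.

*Cytometry*: each slide becomes its vector of cell-type fractions;
out-of-vocabulary types pool into a reserved "other" bucket. Six standard
families (logistic regression, random forest, gradient boosting, k-NN, SVM
with calibrated probabilities, Gaussian naive Bayes) are grid-searched with
patient-grouped stratified CV; the published grid of 227 hyperparameter
groups is not available, so the shipped grid is config-driven with small
(~20-candidate) and expanded variants. For unbiased discrimination
estimates on small cohorts the package also provides nested CV (selection
inside each outer fold, AUROC on pooled out-of-fold predictions): a single
held-out split of ~16 slides has null-AUROC noise of ~0.15, large enough to
obscure the counts-versus-morphology contrast the cohort is built to show.

## Synthetic cohort generator

The generator emulates the statistical structure of encoder embeddings of
blood cells, not their actual distribution. Cell types are isotropic
Gaussian clusters: prototypes are drawn with typical pairwise distance
~1.5× the separation floor (`type_separation × within_type_sd`, default
4 × 1) and redrawn (bounded) if any pair falls below the floor. Defaults:
dim 64 (kept well below encoder scale for test speed; configurable to
1000), 8 types with a roughly normal white-cell differential (55%
neutrophils, 30% lymphocytes, ..., 1% blasts), 40 patients per class, one
slide of 1500-2500 cells per patient.

Disease classes isolate one signal each:

- **AML** — composition: blast fraction drawn U(0.05, 0.60), exact count
  (`round(f·n)`), remainder renormalised normal composition. Visible to
  count-only classifiers by construction.
- **MDS** — morphology only: composition stays the normal multinomial, but
  designated myeloid types (neutrophils, immature granulocytes) have their
  means shifted by 1.5 within-type SDs along one fixed random direction per
  cohort. Invisible to counts by construction; the dysplasia analogue.
- **HCL** — out-of-vocabulary population: U(0.10, 0.40) of cells come from
  a novel prototype placed midway between the lymphocyte and blast
  prototypes, and each such cell is labeled with its *nearest standard
  prototype* — deliberately wrong labels, emulating an upstream cell
  classifier that has never seen hairy cells. The true novel mask lives
  only in ground-truth metadata.

What passing tests on this cohort do show: the architecture can recover
composition shifts, within-type mean shifts, and unlabeled novel clusters
from slide labels alone, and its attention concentrates on the causal
cells. What they do not show: performance on real encoder embeddings,
whose type clusters are anisotropic, heavy-tailed, patient-correlated and
much higher-dimensional; real-cohort AUROCs are not reproducible here.

## Limit of detection

Blast cells are pooled across all AML slides and normal cells across all
normal slides (pooled donors; sampling with replacement, so pools may be
smaller than patients × cells). For each fraction in {0, 1, 2, 5, 10, 15,
20}%, 50 synthetic patients of 300-400 cells are built with the exact
blast count `round(f·n)` (per-cell Bernoulli mixing available by flag),
scored with a single subsample draw, and thresholded at 0.5. Sensitivities
are reported in the conventional overlapping bins (high ≥ 20%, low < 20%,
very low ≤ 10%, extremely low ≤ 5%, invisible ≤ 1%); empty bins report
undefined, not zero.

## Enrichment statistics

Per cell type, a 2×2 table of top-attention membership × type membership.
The test is Pearson chi-squared with 1 df and **no continuity correction**
(the most common default; configurable), with Bonferroni control across
types (flag i true iff p_i < α/m). Degenerate tables (a zero marginal)
report statistic 0, p 1, flagged. Disease-level reports sum the per-slide
tables over correctly classified slides before testing (pooling weighs
slides by cell count; per-slide reports are also available). The log-odds
ratio always applies the Haldane–Anscombe +0.5 correction so rare cell
types — the reason to look at log-odds at all — are finite. A pooled
permutation test (`top_fraction_permutation_test`) checks
over-representation of an arbitrary cell mask in per-slide top-attention
sets against uniformly redrawn sets.

## Numerics

The trainable models run on a minimal reverse-mode autodiff engine over
float64 numpy arrays (`caremil/_autodiff.py`), gradient-checked against
central finite differences. Eval-mode forwards are deterministic;
permutation invariance of the aggregations is exact up to float summation
order (asserted at 1e-10), and logits/attention at 1e-5 across reorderings.
Ties in cell ranking break by ascending cell index (stable sort); the max
aggregation routes its gradient to the first argmax. Degenerate inputs
(empty bags, single-cell bags, zero marginals, empty LOD bins) are handled
explicitly rather than by convention: empty bags raise, a single cell gets
attention 1.0, empty bins report undefined.

## Problem sizes

The shipped study conditions (40 patients/class, dim 64, 15 training
epochs, 50 LOD patients per fraction) were chosen so a full
generate-train-analyse cycle for all three binary tasks completes in a few
minutes on one CPU; they are the generator/trainer defaults, and every size
is configurable upward.
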