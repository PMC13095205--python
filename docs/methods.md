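# Methods

## Overview

`mojknet` classifies cancer subtypes from four molecular layers measured on
one patient cohort — copy-number alteration (CNA), DNA methylation (MET),
mRNA expression and reverse-phase protein arrays (RPPA) — and evaluates
whether the learned patient representation also stratifies survival. The
pipeline has five stages:

1. **Preprocessing.** Sample identifiers are truncated to 12 characters
   (`TCGA-CS-4938-01` → `TCGA-CS-4938`), duplicates deduplicated keeping the
   last occurrence. Per modality, features with strictly more than 10%
   missing values are dropped, remaining missing cells imputed with zero, and
   features with strictly more than 10% zeros after imputation dropped
   (near-constant features carry little discriminative signal; a feature at
   exactly 10% is retained). Samples missing any modality or lacking a
   subtype label are excluded; the cohort is sorted by sample id.
2. **Affinity graphs.** Per modality, squared-euclidean patient distances
   feed a locally scaled Gaussian kernel
   `s_ij = exp(-d_ij / (2·mu·eps_ij))` with
   `eps_ij = (mean_kNN(i) + mean_kNN(j) + d_ij)/3`, then k-nearest-neighbor
   sparsification (top-k per row, symmetrized by elementwise max).
3. **Similarity network fusion (SNF).** Cross-diffusion
   `P(v) ← S(v) · mean_{u≠v} P(u) · S(v)ᵀ` over row-normalized full kernels
   P and kNN-restricted local kernels S, iterated a fixed number of times
   with a reported max-abs-change diagnostic; the consensus network is the
   view average.
4. **Representation learning.** Two pathways: *Input1* trains one
   jumping-knowledge (JK) graph branch per modality on its raw
   (standardized) features and per-modality graph; *Input2* trains a
   patient-level JK branch on the latent output of a multimodal autoencoder,
   using the fused network. The five branch embeddings are concatenated
   into the final patient representation.
5. **Classification and evaluation.** A graph attention network (GAT) on
   the fused network classifies subtypes; macro precision/recall/F1 are
   reported as mean ± sd over stratified 5-fold cross-validation (a 75/25
   stratified holdout is available behind a flag). Survival evaluation fits
   a Cox head on the final embedding, median-splits patients into risk
   groups, and reports Kaplan–Meier curves, the log-rank χ² (1 df) and the
   concordance index.

## Models

### Multimodal autoencoder

Each modality m has an encoder (one hidden ReLU layer of width
min(p_m, 500)); encoder outputs are concatenated and linearly projected to
a shared latent of width 100 (matching the JK hidden width); four decoders
reconstruct the inputs. The loss is the weighted sum of per-modality mean
squared errors with weights (α, β, γ, δ) = (0.2, 0.2, 0.3, 0.3) for
(CNA, MET, mRNA, RPPA), constrained to sum to 1 — the transcriptomic and
proteomic layers carry slightly more weight. Trained full-batch with Adam
(lr 1e-3, 150 epochs), unsupervised, on training-fold rows only; the whole
cohort is embedded afterwards.

### Jumping-knowledge branches

Node update is GCN-style message passing on the weighted graph with
self-loops: `H(l) = ReLU(Â H(l-1) W(l))`, `Â = D̃^{-1/2}(A+I)D̃^{-1/2}`.
Layer 0 is a *linear projection* of the input to the hidden width (100), so
a raw block of 10³–10⁴ features cannot dwarf the hidden layers in the
aggregate. The jumping-knowledge step aggregates layers 0..L by column
concatenation (default; elementwise max also available), which preserves
shallow, unsmoothed representations at any depth — the over-smoothing
remedy at the core of the architecture. A `last` mode keeps only layer L,
reducing the branch to a plain GCN for the ablation harness.

Each branch carries an auxiliary linear softmax head trained with
cross-entropy on training-fold patients only (transductive: full-graph
forward, masked loss); the branch output is the pre-head aggregate for all
patients. Depths default to 2 for both pathways; a `coadread` profile
selects 3 (Input1) and 4 (Input2) for cohorts with many weakly separated
subtypes. Dropout 0.5 on hidden layers, Adam lr 1e-3, 150 epochs, no early
stopping.

### Graph attention classifier

One multi-head attention layer (hidden 100, 2 heads concatenated, LeakyReLU
slope 0.2 on the attention logits, dropout 0.5 on inputs and attention)
followed by a linear softmax head. Attention uses the fused network's edge
structure with guaranteed self-loops; edge strengths are left to the
learned coefficients. Attention rows are softmax-normalized over each
neighborhood and sum to 1 by construction. Training is transductive with
cross-entropy on training-fold nodes.

### Numerical core

All three models run on a small in-repo reverse-mode autodiff engine over
float64 numpy arrays (`mojknet.nn`). Gradients are verified against central
finite differences in the test suite; full-batch training on cohorts of a
few hundred patients makes this engine exact, fast enough, and
bit-reproducible for a given seed.

## Design choices in open territory

- **Fused network density.** Cross-diffusion leaves the consensus matrix
  near-dense. Used directly as graph structure it makes neighborhood
  aggregation and attention global and destroys local similarity
  structure — empirically the classifier
  collapses to the majority class. The pipeline therefore k-NN
  re-sparsifies the fused network (same K) before using it as structure,
  consistent with how SNF consumers conventionally threshold the consensus
  network.
- **Kernel bandwidth.** A single global bandwidth per modality either
  saturates or collapses similarities across layers whose dimensionalities
  span two orders of magnitude; the locally scaled kernel above (the SNF
  lineage's form, parameterized by mu = 0.5 and K = 20) is used instead.
- **Risk scores.** The risk score is the linear predictor of a
  ridge-penalized Cox proportional-hazards head (in-repo, Breslow ties,
  gradient ascent) fitted on the leading 8 principal components of the
  final embedding. Scores are produced *out-of-fold* (head fitted on 4/5
  of patients, scoring the held-out 1/5), so a patient's own survival never
  informs their score: in-sample scoring is optimistically biased on pure
  noise, while out-of-fold scoring gives a null concordance of ~0.5. Eight
  components keep the head's variance in check: with many more axes the
  out-of-fold predictor is variance-dominated and concordance falls well
  below what the class structure supports. Ties at the median go to the
  low-risk group.
- **Transductive graphs.** Affinity and fused graphs are built once from
  all patients (globally standardized features); test-fold patients
  participate in graph structure but never in any loss. Per-fold feature
  standardization, autoencoder training and all supervised losses use
  training-fold statistics and labels only — verified by a leakage canary
  that corrupts test-fold labels and checks parameter checksums.
- **Seeds.** One global seed fans out to per-stage seeds via a stage-name
  hash (CRC32), so each stage is independently reproducible and two full
  runs with one seed emit byte-identical metrics JSON.

## Synthetic cohorts

The generator emulates the shape of a cBioPortal-style TCGA cohort: four
modalities of very different width, imbalanced subtype classes, per-modality
mean-shift signal on a small informative feature subset (class patterns are
±1 sign vectors drawn once per seed, so class pairs differ in about half
the informative positions), additive Gaussian noise, injected missingness,
and exponential survival with subtype-dependent hazards under independent
right censoring calibrated to a target censored fraction (baseline median
survival 60 months for the hazard-ratio-1 class).

The canonical recipe used by the acceptance script: n = 200 patients,
three classes (50/30/20%), widths (500, 500, 500, 60) — three
high-dimensional layers plus a protein-array-like narrow one — 10%
informative features with effect sizes (0.6, 0.8, 1.0, 0.5) sd, unit noise,
2% missingness, hazard ratios (5, 2, 1), 30% censoring, seed 17. These
sizes keep a full five-fold run on one CPU to a couple of minutes while
leaving the recovery non-trivial: no single modality separates the classes
on its own, and network fusion visibly sharpens the patient neighborhoods.

What the generator does **not** emulate: methylation beta-value marginals,
copy-number segment structure, feature–feature correlation, batch effects,
or label noise. Passing tests on these cohorts demonstrates that the
machinery recovers planted multi-modal structure under realistic shapes and
noise — not that the pipeline attains any particular accuracy on real
tumor cohorts.

A second generator builds the over-smoothing probe: a two-class stochastic
block model with nearly balanced within/between edge probabilities
(0.10 / 0.07) and a weak mean shift (0.6 sd on 4 of 20 features). Shallow
aggregation still sees class-enriched features; each further propagation
step mixes the classes, so a depth-4 final-layer-only GCN degrades while
the JK concatenation retains the shallow layers — the direction the
ablation harness checks across seeds.

## Numerical conventions

- Standardization is population z-scoring (ddof 0) fitted on training
  rows; sd-zero features map to 0.
- Top-k ties break by lower sample index (stable sort), for
  reproducibility.
- The kernel bandwidth has an epsilon floor (1e-12) so an all-identical
  input degenerates to similarity 1 rather than 0/0.
- SNF runs a fixed 20 iterations; no early stopping. Convergence is
  reported as the per-iteration max-abs change of the status matrices.
- Isolated nodes (zero affinity rows) are epsilon-regularized with a
  warning during kernel normalization; disconnected k-NN graphs warn with
  the component count but still run.
- Macro metrics average over all classes; a class never predicted
  contributes precision 0.
- Degenerate (constant) risk scores raise instead of silently splitting.

## Limitations

- All models are full-batch and dense; cohorts beyond ~10³–10⁴ patients
  would need sparse propagation and mini-batching.
- The attention classifier uses one attention layer plus a linear head;
  layer counts are configurable but deeper stacks are untested.
- Survival evaluation assumes proportional hazards and right censoring
  independent of covariates.
- Whether the two pathways should share parameters is an open design
  question; they are fully independent here.
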