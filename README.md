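# mojknet

Multi-omics cancer subtype classification with patient similarity networks,
jumping-knowledge graph branches and graph attention — plus survival
evaluation of the learned patient representation.

## Who this is for

Computational biologists integrating several molecular layers measured on
one tumor cohort — copy-number alteration (CNA), DNA methylation, mRNA
expression and reverse-phase protein arrays (RPPA), e.g. cBioPortal exports
of TCGA Pan-Cancer cohorts — who want subtype predictions with
cross-validated macro metrics and a prognostic read-out (Kaplan–Meier,
log-rank, C-index) from one reproducible pipeline.

## The model

For each modality *m*, patients are connected by a locally scaled Gaussian
kernel on squared euclidean distances,

    s_ij = exp( −d_ij / (2·μ·ε_ij) ),   ε_ij = (mean_kNN(i) + mean_kNN(j) + d_ij) / 3,

sparsified to a k-nearest-neighbor graph (K = 20, μ = 0.5). Similarity
network fusion merges the per-omics graphs into one consensus network by
cross-diffusion, `P(v) ← S(v) · mean_{u≠v} P(u) · S(v)ᵀ`.

Representation learning runs along two pathways. *Input1*: one
jumping-knowledge graph branch per modality on its raw features and graph —
GCN propagation `H(l) = ReLU(Â H(l−1) W(l))` with the representations of
**all** depths 0..L concatenated, so shallow unsmoothed signal survives
deep stacks (the over-smoothing remedy). *Input2*: a patient-level branch
on the shared latent of a multimodal autoencoder whose loss weights the
per-modality reconstruction errors α·MSE₁ + β·MSE₂ + γ·MSE₃ + δ·MSE₄ with
(α, β, γ, δ) = (0.2, 0.2, 0.3, 0.3). The five branch embeddings are
concatenated and a two-head graph attention network on the fused network
predicts subtypes; metrics are macro precision/recall/F1 over stratified
5-fold cross-validation. A ridge Cox head on the final embedding produces
out-of-fold risk scores; a median split defines high/low risk groups
compared by the log-rank test χ² = (O₁−E₁)²/V₁ and the concordance index.

The neural stages run on a compact in-repo reverse-mode autodiff engine
over float64 numpy (gradient-checked against finite differences), so the
whole pipeline is dependency-light and bit-reproducible for a given seed.

## Worked example

```python
from mojknet import TrainConfig, generate_cohort, reference_recipe, run_full
from mojknet.omics_io import filter_and_impute

cohort = generate_cohort(reference_recipe())      # synthetic 200-patient cohort
for m in list(cohort.omics):                      # >10% missing / zero filters
    cohort.omics[m] = filter_and_impute(cohort.omics[m])

result = run_full(cohort, TrainConfig(seed=1))
p, r, f1 = result.metrics.mean
print(f"macro precision/recall/F1 (%): {100*p:.2f} / {100*r:.2f} / {100*f1:.2f}")
print(result.survival_stats)
```

prints

```
macro precision/recall/F1 (%): 100.00 / 100.00 / 100.00
{'logrank_chi2': 35.84164893758284, 'logrank_p': 2.1402343308113043e-09, 'c_index': 0.6311654861558275}
```

The three planted subtypes of the synthetic cohort are recovered perfectly
under 5-fold cross-validation, and the median-split risk groups separate
the planted hazards (hazard ratios 5/2/1): log-rank p ≈ 2×10⁻⁹ with
C-index ≈ 0.63 (within-class risks are tied, which caps the attainable
concordance well below 1).

The same flow is scriptable from the shell:

```
mojknet synth --out cohort/ --seed 17
mojknet train --bundle cohort/ --out results/ --seed 1
mojknet ablate --bundle cohort/ --out ablation.csv --which exclude_one_omics
mojknet survival --bundle cohort/ --out surv/ --plot
```

For real cBioPortal exports, `mojknet preprocess` reads the four
`data_*.txt` matrices plus a clinical table (PATIENT_ID, SUBTYPE,
OS_MONTHS, OS_STATUS), applies the cleaning cascade (12-character id
truncation, keep-last dedup, >10% missing/zero feature filters, four-way
sample intersection, sort) and writes a model-ready bundle.

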