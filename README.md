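# dl-lasso

Dictionary-learning LASSO feature selection for radiomics tables, with a
tumor-grading evaluation harness and a synthetic cohort generator.

## The problem

Radiomics pipelines extract hundreds to a thousand quantitative features
(first-order statistics, GLCM/GLRLM/GLSZM textures, shape descriptors)
per lesion. For a grading task — e.g. calling a liver lesion low- or
high-grade from contrast-enhanced MRI — only a handful of those features
carry signal, the rest are noisy and heavily inter-correlated, and
cohorts are small (hundreds of lesions). Selecting a compact, stable
feature panel before classification is the step that makes or breaks
such models.

The standard tool is the LASSO: regress the binary grade `y ∈ {0,1}^n`
on the feature matrix `X ∈ R^{n×k}`,

    α̂ = argmin_α ‖Xα − y‖₂² + μ‖α‖₁ ,

and keep the τ features with the largest |α̂_j|. This package implements
a dictionary-learning refinement of that recipe:

1. **Sample dictionary.** The training cohort itself is the dictionary
   `D0 = [d₁ … d_n] ∈ R^{k×n}` (columns = normalized feature vectors,
   the *atoms*). Each sample is sparse-coded over the other atoms
   (self-excluded), giving a code matrix `A` with zero diagonal.
2. **Fisher-ratio grouping.** Each atom's signed coding contribution
   `s_j(t) = A[j,t]·‖d_j‖₂` is scored by a Fisher ratio — between-class
   scatter of the contributions over mean within-class variance. The
   top-ρ fraction of atoms forms the high-information part (HIP) of the
   dictionary, `Dh`; the rest plus the coding residual form the
   low-information part `Dl`, with `Dh + Dl = D0` exactly.
3. **Discriminative projection.** A projection `P` maximizes the trace
   ratio `tr(P S_B^h Pᵀ) / tr(P [β S_W^h + (1−β) S_W^l] Pᵀ)` — preserve
   the between-class energy of the HIP, suppress within-class energy of
   both parts. `P`'s rows are the top generalized eigenvectors of
   `S_a q = λ S_b q` (ridge-regularized `S_b`, since both scatters are
   rank-deficient when k ≫ n).
4. **Final LASSO and back-projection.** The grade labels are regressed
   with the LASSO on the learned design `X̃ = (P·D0)ᵀ`; coefficients are
   mapped back to per-feature weights `w = Pᵀ α̂` (the unique linear
   model on the original features reproducing the projected model's
   predictions), and the top-τ features by |w| are selected.

Downstream, the selected panel feeds a 7-nearest-neighbor vote and an
RBF-kernel SVM (cost and width by 10-fold stratified CV), evaluated by
recall, precision, F1, accuracy and ROC AUC.

The LASSO solver is written in-package: cyclic coordinate descent with
active-set acceleration on the unscaled objective above, warm-started
along descending penalty paths, with `μ` chosen by cross-validation.

## Worked example

```python
from dl_lasso import (
    SyntheticSpec, generate_cohort, PipelineConfig,
    dl_lasso_select, recovery_score,
)

# a radiomics-like cohort: 150 lesions x 300 features, 10 informative
table, truth = generate_cohort(SyntheticSpec(seed=3))
result = dl_lasso_select(table, PipelineConfig(seed=3))

print("penalty chosen by CV:", round(result.mu, 3))
print("selected features:", sorted(result.selected_idx.tolist())[:10], "...")
precision, recall, f1 = recovery_score(result.selected_idx, truth)
print(f"recovery precision={precision:.2f} recall={recall:.2f} f1={f1:.2f}")
```

prints

```
penalty chosen by CV: 2.928
selected features: [22, 24, 29, 42, 72, 76, 98, 105, 110, 134] ...
recovery precision=0.45 recall=0.90 f1=0.60
```

meaning: with the default panel size τ = 20, nine of the ten truly
informative features were recovered (recall 0.9); the remaining slots
went to correlated nuisance features, giving precision 0.45.

The same pipeline is available from the shell:

```bash
dl-lasso simulate --seed 3 --out cohort.csv --truth truth.json
dl-lasso select --input cohort.csv --out results/
```

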