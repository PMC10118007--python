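# Methods

This note documents the model, the numerical choices, the synthetic data
generator, and the known limitations of the dl-LASSO implementation. It
records design rationale; every empirical statement here is computed by
the test suite or by `scripts/acceptance.py`, not asserted from memory.

## Model and pipeline

Inputs are a feature table `X ∈ R^{n×k}` (rows = lesions, columns =
numeric radiomic features) with binary grade labels `y ∈ {0,1}^n`
(0 = low-grade, 1 = high-grade). All stages operate on Z-score
normalized features; normalization statistics (per-feature mean and
sample sd, ddof = 1) are fitted on training data only and applied
unchanged to held-out data. Constant features are kept and mapped to
zero rather than dropped, so selection output always references the
original column indices.

The selection pipeline:

1. **Per-sample sparse coding.** The sample dictionary is
   `D0 = Xᵀ ∈ R^{k×n}`. Sample t's code solves the LASSO of `d_t` on the
   dictionary with atom t removed, its own coefficient pinned at zero —
   without self-exclusion the identity code is optimal and carries no
   information. All n solves share one n×n Gram matrix; the per-sample
   subproblem drops one row/column.
2. **Fisher-ratio atom scores.** Atom j's contribution to sample t is
   the k-vector `z_{jt} = A[j,t]·d_j`; it is scalarized as
   `s_j(t) = A[j,t]·‖d_j‖₂`, keeping the coefficient's sign (an
   alternative `‖z‖₂` scalarization that discards sign is available via
   `scalarization="l2"`). Samples are grouped by their own class label
   and the score is between-class scatter of `s_j` over the mean
   within-class variance, with an additive guard `ε_f = 1e−12` in the
   denominator so perfectly separated atoms stay finite and all-zero
   atoms score 0.
3. **HIP/LIP split.** The top `⌈ρ·n⌉` atoms by Fisher score form the
   high-information part; ties break toward the lower atom index so the
   partition is deterministic. Per sample, the HIP column is its code
   restricted to HIP atoms, `d_t^h = Σ_{j∈HIP} A[j,t] d_j`; the LIP
   column is everything else *including the coding residual*
   `d_t − D0 A[:,t]`, which is unexplained by the dictionary and hence
   treated as uninformative. Computing `Dl = D0 − Dh` makes the
   conservation identity `Dh + Dl = D0` exact to rounding.
4. **Projection learning.** With `S_B^h` the between-class scatter of
   `Dh` and `S_W^h`, `S_W^l` the within-class scatters of the two parts,
   the projection maximizes
   `tr(P S_B^h Pᵀ) / tr(P [β S_W^h + (1−β) S_W^l] Pᵀ)`. The rows of `P`
   are the generalized eigenvectors of `(S_a, S_b)` with the largest
   eigenvalues, where `S_a = S_B^h` and
   `S_b = β S_W^h + (1−β) S_W^l + ε_reg·I`. This one-shot eigen solution
   maximizes the ratio-trace, and each direction individually maximizes
   its Rayleigh quotient over the orthogonal complement; it is *not* an
   iterative trace-ratio optimizer (Dinkelbach-style refinement is out
   of scope). Eigenvectors are `S_b`-normalized (`qᵀ S_b q = 1`),
   ordered by descending eigenvalue, and sign-fixed (largest-magnitude
   entry positive) for bitwise reproducibility.
5. **Final LASSO and attribution.** The labels are regressed on the
   learned design `X̃ = (P D0)ᵀ`. Because `X̃ a = X (Pᵀ a)`, the
   back-projected vector `w = Pᵀ α̂` is the unique linear model on the
   original features with the same predictions; features are ranked by
   `|w|` and the top τ selected. Zero-weight features are never
   selected, so fewer than τ indices may be returned.

### Tunable parameters

| name | meaning | default | rationale |
|---|---|---|---|
| `tau` | features selected | 20 | typical radiomics panel size |
| `rho` | HIP fraction of atoms | 0.5 | balanced split absent prior knowledge |
| `beta` | HIP vs LIP within-class energy weight | 0.5 | equal balance |
| `mu` | final LASSO penalty | CV on `X̃` | prediction-error minimizer, ties to sparser model |
| `mu_code` | coding penalty | CV on the label regression | single data-driven scale shared by all codings |
| `eps_reg` | ridge on `S_b` | `1e−6·tr(S_b)/k` | scatters are rank-deficient for k ≫ n; trace scaling keeps the ridge relative |
| `m` | projection directions kept | `min(k, n−1)` | the scatters' maximal effective rank |
| `folds` | CV folds for `mu` | 5 | standard at n ≈ 100–150 |

All parameters are echoed into the run record, and every source of
randomness flows from a single integer seed.

### Numerical choices

* The LASSO objective is the **unscaled** `‖Xα − y‖² + μ‖α‖₁` (no 1/2n
  factor), so `μ` is on the same scale as the squared residual. The
  all-zero solution is optimal exactly at `μ ≥ 2·max_j |X_jᵀy|`, which
  anchors the CV grid (8 points, 3 decades down from that threshold).
* Solver: cyclic coordinate descent on the Gram system with active-set
  acceleration; convergence means a *full* sweep moves no coefficient by
  more than `tol·(1 + max|α|)`, `tol = 1e−8`, sweep budget `1e5`.
  Exhausting the budget returns `converged=False` with a warning rather
  than raising: on rank-deficient Grams (possible when atoms outnumber
  feature dimensions, k < n) cyclic descent can crawl along a flat
  null-space direction and the sweep-change criterion never triggers,
  while the iterate is already optimal to well below any tolerance that
  matters downstream.
* Cross-validation fits run at a looser tolerance (1e−5): they feed only
  a fold-level prediction-error comparison, itself far noisier than the
  solver error. Final fits keep 1e−8.
* Ties everywhere (Fisher scores, weight ranking, KNN distances, CV
  error) break toward the lower index / larger penalty, making every
  stage deterministic given the seed.
* Degenerate inputs: constant features pass through normalization as
  zeros; single-class tables, non-finite values and even KNN votes are
  rejected with explicit errors; zero-denominator metrics report 0.0
  with an `undefined` flag instead of NaN.

## Grading harness

KNN uses Euclidean distance with K = 7; vote ties cannot occur for odd
K, distance ties resolve to the lower training index, and the score used
for ROC analysis is the positive-neighbor fraction. The SVM uses an RBF
kernel with cost and width chosen on the classic coarse power-of-four
grid (`C ∈ 2^{−5..15}`, `γ ∈ 2^{−15..3}`) by 10-fold stratified CV
(capped at the minority-class count) maximizing accuracy; signed
decision values are the ROC scores. ROC curves are built by a
descending-threshold sweep over unique scores; the trapezoidal area
equals the Mann-Whitney concordance with ties counted one half, and the
suite verifies this identity to 1e−12.

## Synthetic cohorts

The generator emulates the statistical shape of a radiomics cohort:

* `s` informative features: unit-variance Gaussians whose class-1 mean
  is shifted by `effect` (in units of the base sd);
* the remaining features in equicorrelated nuisance blocks of size
  `block` (default 10) with zero class difference, mimicking the strong
  redundancy of texture-feature families;
* independent Gaussian noise (sd `noise_sd`, default 0.5) on every
  feature, standing in for acquisition and preprocessing variability —
  at the default the marginal sd is `√1.25 ≈ 1.12`, so the realized
  standardized shift is `effect/1.12`;
* a seeded column shuffle so methods cannot exploit feature order; the
  informative indices are returned as ground truth.

`rho_corr` is a contract for the *realized* within-block correlation:
the pre-noise mixing weight is inflated by `(1 + noise_sd²)` to undo the
attenuation the additive noise would cause (verified at n = 2000 to
±0.05). Labels are assigned as exact counts `round(class_balance·n)`
positives via a seeded permutation, guaranteeing both classes are
present for stratified splitting.

Reference conditions — n = 150 lesions, k = 300 features, s = 10,
effect = 1.2, rho_corr = 0.6 — are the fixed study design used by the
recovery tests and the acceptance script; the acceptance script averages
recovery over 5 replicate cohorts and grades one 70/30 split, sizes
chosen to keep a full run within a few tens of seconds on one CPU.

What passing these tests does *not* show: real radiomic features are
non-Gaussian (heavy-tailed, bounded, discrete counts), their correlation
is not block-uniform, informative features correlate with nuisance ones,
and batch effects correlate with nothing in this generator. Recovery
rates on synthetic cohorts are an upper bound on what the same pipeline
would achieve on scanner data.

## Design choices where the design was open

* **One code per sample, one global atom partition.** The grouping
  stage could be read as re-using the label-regression coefficients,
  but those live in R^k and cannot weight n atoms; the per-sample
  self-excluded coding is the only reading under which the HIP/LIP
  parts have per-sample columns, as the scatter definitions require.
* **Residual assigned to the LIP.** The coding residual is unexplained
  by the dictionary; putting it in the low-information part makes the
  decomposition exact and testable rather than leaky.
* **Projecting `D0`, not `Dh`.** The projection was built to pass HIP
  energy and block LIP energy, so applying it to the full dictionary
  realizes "enhance the informative part, suppress the rest" in a
  single object, and keeps the identity-projection special case an
  exact reduction to plain LASSO.
* **Back-projection for attribution.** `w = Pᵀα̂` is the only linear
  attribution consistent with the projected model's predictions. Its
  cost: `w` is generically dense, so dl-LASSO fills all τ slots even
  when few directions are active, which depresses recovery *precision*
  relative to a plain LASSO whose support is naturally sparse. With two
  classes `S_a` has rank 1, the final LASSO typically loads on the
  single leading eigen-direction, and the selection effectively ranks
  features by that discriminant direction's entries.

## Known limitations

* Two-class grading only; the formulas generalize to C > 2 but are
  untested and unexposed.
* The trace-ratio objective is solved one-shot via the generalized
  eigendecomposition; for m > 1 kept directions this maximizes the
  ratio-trace, and projections with a strictly larger trace ratio can
  exist.
* Discriminant-direction entries are not marginal feature importances:
  under strong feature correlation the |w| ranking concentrates signal
  (true features rank far above the nuisance median) but does not
  guarantee the top-s slots are exactly the informative features.
* The sparse coder can fail to certify convergence on overcomplete
  dictionaries (k < n) due to flat null-space directions; results
  remain usable and flagged.
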