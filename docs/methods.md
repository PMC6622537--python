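# Methods

## The prediction problem

A screening panel reports, for drug *d* and cancer cell line *c*, the
half-maximal inhibitory concentration IC50(d, c). The package predicts either
the binary activity class (active ⇔ IC50 ≤ cutoff, 1 µM by default, the
comparison inclusive) or log10(IC50 / M) itself, from a feature vector that
joins the cell line's binary oncogene mutation profile with the drug's
chemical fingerprint. All concentrations are handled as log10 of molar
values; "log(IC50)" is taken as log base 10 throughout, so RMSEs are in
log10 units.

## Feature construction

**Gene panel.** Genes are ranked by the binary information entropy of their
mutation frequency across cell lines, H(p) = −p log₂p − (1−p) log₂(1−p);
selecting the top-k genes by entropy is equivalent to selecting the k genes
whose mutated/unmutated split is closest to half-and-half. Ties are broken
lexicographically by gene id (the ordering is otherwise undefined).

**Fingerprints.** 192 continuous two-dimensional physicochemical and
topological descriptors (a frozen manifest of RDKit descriptor names shipped
at `oncoforest/data/descriptors_192.txt`; descriptors that can be undefined
or overflow on valid molecules — Ipc, the BCUT2D family, partial-charge
extrema — are excluded) followed by a radius-3 circular fingerprint
(ECFP6-equivalent) folded to 1024 bits. Descriptor values are toolkit-
dependent; the contract is the count (192), 2-D-only inputs, and
determinism within a pinned RDKit version — forests depend on descriptor
informativeness, not identity, so no attempt is made to reproduce any other
toolkit's values bit-for-bit. Fingerprints can be cached to CSV and reloaded
so experiments replay exactly.

**Dataset filter.** Cell lines missing mutation status for ≥ 20 panel genes
are dropped (the limit is read against the oncogene panel, not a full
genome); remaining sporadic missing statuses are coded 0 — absence of
evidence of mutation — matching the 0/1 vector construction. Unobserved
activity records, and records of dropped cell lines, are removed. The filter
is idempotent and never alters a retained value.

## Forests

Classification forests use 500 trees and m_try = round(√p) features per
split — 37 for the full 1361-feature matrix, the Ranger-style default; the
value tracks p when the gene subset shrinks rather than staying frozen at
37. Regression forests use 500 trees and m_try = p/3, the classical
regression-forest setting: with a continuous response composed of sparse
additive contributions, √p split sampling underfits badly (on the desk
preset it leaves pooled RMSE ≈ 1.0 where p/3 reaches ≈ 0.73 against a
generative noise floor of 0.5), while classification is insensitive to the
difference. Gini importance is the forest's total (mean-decrease-in-)
impurity reduction per feature; absolute magnitudes are toolkit-dependent,
so analyses and tests assert ranks, never raw values.

## Validation battery

* **k-fold CV** (k = 5): rows are shuffled with a recorded seed, then split
  contiguously; `ordered_folds=True` reproduces an unshuffled
  first-80%/last-20% style split. Metrics are reported per fold and as
  mean ± sd.
* **SMOTE** is applied only when the minority class is < 20% of rows:
  synthetic minority rows x + u·(x′ − x), u ~ U(0,1), with x′ one of the 5
  minority-class Euclidean nearest neighbors of x (k falls back to
  minority−1 when the class is tiny); the majority class is randomly
  under-sampled; both classes end at half the original row count.
  Balancing runs *inside each training fold* by default so synthetic points
  never leak into test folds; `smote_before_split=True` balances the whole
  matrix first, the literal (leakage-prone) reading, kept as an explicit
  option.
* **Cutoff sweep / ROC.** The labeling cutoff is swept over the 44-value
  grid from 0.01 µM to 5000 µM plus the initial 1 µM; each cutoff's
  cross-validated mean (FPR, sensitivity) becomes one ROC point, cutoffs
  yielding a single class are skipped with a warning, and AUC is the
  trapezoid over FPR-sorted points augmented with (0,0) and (1,1). Note this
  ROC varies the *activity definition*, not a score threshold.
* **y-randomization** permutes labels (or regression targets) within each
  training split only; test folds stay untouched. A sound pipeline collapses
  to κ ≈ 0 / r ≈ 0. Pooled y-randomized Pearson r fluctuates at the ±0.03
  level on a 40-drug panel (drug-level units dominate), so null checks
  average a few permutation repeats.
* **Leave-drug-out** withholds whole drugs (10 per round for classification,
  single drugs for regression) so training and test sets never share a
  compound — the blind-prediction scenario for a new drug.
* **Dummy baselines**: zero rule (majority class / training mean),
  stratified and uniform random labels, training quantiles, and 9-NN,
  evaluated under 10-fold CV. The 9-NN "baseline" effectively looks up
  same-drug rows through the fingerprint block, so it is near-oracle for
  random-split CV and not a fair comparator for blind drug hold-out; blind
  runs are compared against the label-only dummies on chance-corrected κ.
* **Imputation study.** A fraction (10–40%) of activity values is masked
  uniformly at random, refilled by one of four imputers — iterative random
  forest (500 trees; with only the activity column incomplete the iteration
  converges after one pass), 9-NN majority vote, L1-regularized logistic
  regression (penalty by internal CV, ≤ 100 iterations), or a single
  classification tree — then classifiers are retrained on the imputed matrix
  and scored only on rows whose labels were never masked. The binary class
  is imputed by default; a continuous mode imputes log10 IC50 with
  regression variants and thresholds afterwards (the published descriptions
  of such pipelines are ambiguous between the two readings, so both are
  provided). Observed labels are asserted unchanged on every run.
* **Per-drug importance.** One forest per drug (gene features only — the
  fingerprint is constant within a drug); genes with importance > mean + 2
  population SDs of that drug's gene importances are its top-ranking genes.
  Population rather than sample SD: at 145 genes the difference is
  negligible and the population form needs no n−1 convention.

## Synthetic screens

The generator emulates a GDSC-like panel from the additive model

log10 IC50(d,c) = μ + α(d) + β(c) + Σₖ γₖ · mut(c, gₖ) · fp(d, fₖ) + ε,
ε ~ N(0, σ²),

clipped to the physical range [−10.3, −0.4] log10 M (5×10⁻¹¹–0.4 M);
clipping events are logged. Defaults (the desk preset; chosen once as the
study conditions and not revisited): 300 cell lines × 40 drugs × 145 genes,
10 causal genes paired with 10 causal fingerprint bits at |γ| = 1.0 with
random signs, σ = 0.5, μ = −6 (so classes are near-balanced at the 1 µM
cutoff), β ~ N(0, 0.25²), drug offsets with sd 1.0 of which 75% of the
variance is a linear function of five continuous descriptors — chemically
informative, so held-out drugs remain partially predictable — and 25%
idiosyncratic. Per-gene mutation frequencies are Uniform(0.05, 0.5) with
causal genes in the informative Uniform(0.20, 0.50) band (the frequently
mutated, TP53-like regime); fingerprint bit densities are
Uniform(0.02, 0.30) with causal bits at Uniform(0.30, 0.60) (common
pharmacophore-like scaffolds). Missingness is MCAR. Identical seeds give
identical tables, and a JSON sidecar records every planted parameter for
recovery tests.

What the generator does **not** model: tumor-type structure, gene–gene
epistasis, drug-class clustering beyond the planted interactions,
informative missingness, or real descriptor correlation structure. Passing
recovery tests therefore demonstrates that the pipeline's machinery is
sound — not that comparable accuracy would be achieved on any real panel.

`plant_class_balance` retargets the expected active fraction at a given
cutoff by solving E[Φ((log10 cutoff − μ − S)/σ)] = target for μ over
Monte-Carlo draws of the structural sum S, raising a configuration error
when no baseline inside the clipped range reaches the target.

## Test-scale choices

The validation suite runs the frozen study conditions at sizes the package
chooses for iteration speed: the desk preset itself (12,000 records) with
100-tree forests for the y-randomization, minimal-gene-set, regression
noise-floor and ROC checks; a 200-cell variant (8,000 records) for the
imputation and blind-hold-out studies; and a 150-cell × 24-drug variant
for replicated causal-gene-recovery screens. The acceptance script runs the
full desk preset with 500-tree forests. Thresholds asserted by tests are
never adjusted to the scale; where a scale matters it is stated with the
measured margin in the test.

## Numerical and edge-case conventions

Ratios with zero denominators (sensitivity/specificity/FPR/NPV, κ at
p_e = 1, correlations of constant vectors) are reported as NaN with a
warning, never coerced to 0. Importance ties are broken lexicographically by
feature id. ROC points from skipped cutoffs are simply omitted. All
stochastic operations take explicit seeds; one master seed fans out through
a stable label-based derivation (`oncoforest._seeds`), so adding an
experiment never perturbs another's randomness, and reports record every
derived seed. SMOTE interpolation runs in float64 so synthetic rows lie
exactly on minority segments; forest training uses float32 feature blocks
for memory locality.

## Known limitations

Fingerprint reproducibility is guaranteed only within a pinned RDKit
version. The minimal-gene-set search measures performance of *nested*
top-N subsets from a single global ranking, not the best subset of size N.
Imputation of the activity column ignores correlation between records of
the same drug or cell line beyond what the features encode. The leave-drug-
out gap depends strongly on how much drug-level variance the descriptors
explain; with mostly idiosyncratic drug effects, blind prediction of a new
compound is impossible for any method.
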