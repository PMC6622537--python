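# oncoforest

Random-forest prediction of anticancer compound activity and potency from
**minimal genomic information**: a cancer cell line is described only by the
binary mutation status of a panel of oncogenes, a compound only by its
chemical structure, and their combination by a single feature vector

```
x(d, c) = [ mut(c, g1) … mut(c, gG) | fp(d, 1) … fp(d, 1216) ]
```

— G mutation bits joined with a 1216-element fingerprint (192 continuous 2-D
physicochemical/topological descriptors + 1024 radius-3 circular-fingerprint
bits). From screening records of log10(IC50) values the package trains

* **classifiers** for the activity class, active ⇔ IC50 ≤ cutoff (1 µM by
  default), scored by accuracy, sensitivity, specificity, FPR, NPV and
  Cohen's κ = (p₀ − p_e)/(1 − p_e);
* **regressors** for log10(IC50) itself, scored by RMSE, Pearson r and
  Spearman ρ on pooled out-of-fold predictions.

Around the forests it implements the full validation battery a QSAR /
chemogenomics practitioner expects: entropy-based gene panel selection, Gini
(mean-decrease-in-impurity) importance ranking with a minimal-gene-set
search, SMOTE class balancing inside training folds, an IC50-cutoff sweep
producing an ROC curve, y-randomization, leave-drug-out blind validation,
dummy baselines, and a missing-activity imputation study (iterative forest,
9-NN, lasso-logistic, CART).

Because real screening panels are large and externally hosted, the package
ships a first-class **synthetic-data generator** with a fully known ground
truth (planted gene × chemistry interaction effects) so that every stage can
be validated by signal recovery — that is what the test suite does.

## Worked example

```python
from oncoforest.synthetic import desk_preset, generate_dataset
from oncoforest.features import assemble_matrix, LabelingConfig
from oncoforest.classification import RFConfig, kfold_cv

# 300 cell lines x 40 drugs x 145 genes, 10 causal genes, noise sd 0.5
panel, drugs, sens, truth = generate_dataset(desk_preset(seed=1))
matrix = assemble_matrix(panel, drugs, sens, labeling=LabelingConfig(1e-6))
cv = kfold_cv(matrix, RFConfig(n_trees=100, seed=0), k=5)
print(f"accuracy {cv.mean('accuracy'):.3f}  kappa {cv.mean('kappa'):.3f}")
```

prints

```
accuracy 0.794  kappa 0.589
```

i.e. on the desk-scale synthetic screen the forest classifies ~79% of
held-out drug–cell pairs correctly, with chance-corrected agreement κ ≈ 0.59
— recovering the planted mutation × substructure interactions. Shuffling the
training labels (`kfold_cv(..., permute_train_labels=True)`) collapses κ to
≈ 0.00, confirming the signal is real rather than a chance correlation
between descriptors.

The same pipeline is available from the shell:

```bash
oncoforest simulate --preset desk --seed 1 --out run/
oncoforest classify --panel run/panel.csv --drugs run/drugs.csv \
    --sensitivity run/sensitivity.csv --task cv --trees 100 --out run/cv/
```

Every run writes tidy CSV metric tables plus a `manifest.json` recording
inputs, seeds, package version and wall time.

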