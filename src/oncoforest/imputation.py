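"""Missing-activity simulation and imputation.

Masks a fraction of the activity values completely at random (MCAR), imputes
them from the remaining rows' features by one of four learners — iterative
random forest, 9-nearest-neighbors, L1-regularized logistic regression, or a
single classification tree — and quantifies the downstream effect by
training classifiers on the imputed matrix and evaluating them only on rows
whose labels were never masked.

By default the binary activity class is imputed; ``continuous=True`` imputes
log10 IC50 with regression variants of the same four learners and thresholds
afterwards.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.linear_model import LassoCV, LogisticRegressionCV
from sklearn.neighbors import KNeighborsClassifier, KNeighborsRegressor
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor

from ._seeds import child_rng, child_seed
from .classification import (
    CVResult,
    RFConfig,
    _fold_assignment,
    compute_metrics,
    smote_balance,
    train_classifier,
)
from .datatypes import DrugLibrary, FeatureMatrix, OncogenePanel, SensitivityTable
from .exceptions import ValidationError
from .features import LabelingConfig, assemble_matrix

IMPUTE_METHODS = ("rf_iterative", "knn9", "lasso_logistic", "cart")

#: Paper-style masking grid.
DEFAULT_FRACTIONS = (0.10, 0.20, 0.30, 0.40)


@dataclass
class MaskPlan:
    """Which (drug, cell line) records lose their activity value."""

    fraction: float
    seed: int
    masked_keys: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0 <= self.fraction < 1:
            raise ValidationError("masking fraction must be in [0, 1)")


def make_mask_plan(matrix: FeatureMatrix, fraction: float, seed: int) -> MaskPlan:
    """Draw round(fraction x rows) keys uniformly without replacement."""
    plan = MaskPlan(fraction=fraction, seed=seed)
    n_mask = int(round(fraction * matrix.n_rows))
    idx = child_rng(seed, "mask").choice(matrix.n_rows, size=n_mask, replace=False)
    ids = matrix.ids.iloc[np.sort(idx)]
    plan.masked_keys = list(zip(ids["drug_id"], ids["cell_line_id"]))
    return plan


@dataclass
class MaskedMatrix:
    """A classify-mode matrix with some labels hidden, plus the truth store."""

    matrix: FeatureMatrix  # labels on masked rows are placeholders, never read
    masked: np.ndarray  # boolean, True where the label was removed
    truth: pd.Series  # original labels of the masked rows (by position)


def mask_values(matrix: FeatureMatrix, plan: MaskPlan) -> MaskedMatrix:
    """Hide the labels of the planned rows; keep originals in a truth store."""
    if matrix.mode != "classify":
        raise ValidationError("mask_values requires a classify-mode matrix with labels")
    key = pd.MultiIndex.from_frame(matrix.ids[["drug_id", "cell_line_id"]])
    masked = key.isin(pd.MultiIndex.from_tuples(plan.masked_keys)) if plan.masked_keys else (
        np.zeros(matrix.n_rows, dtype=bool)
    )
    masked = np.asarray(masked, dtype=bool)
    truth = matrix.label[masked].copy()
    return MaskedMatrix(matrix=matrix, masked=masked, truth=truth)


def _fit_imputer(method: str, continuous: bool, seed: int, rf_trees: int = 500):
    if method == "rf_iterative":
        cls = RandomForestRegressor if continuous else RandomForestClassifier
        return cls(n_estimators=rf_trees, random_state=seed, n_jobs=1)
    if method == "knn9":
        return (KNeighborsRegressor if continuous else KNeighborsClassifier)(n_neighbors=9)
    if method == "lasso_logistic":
        if continuous:
            return LassoCV(cv=3, max_iter=100, random_state=seed)
        return LogisticRegressionCV(
            penalty="l1", solver="liblinear", Cs=5, cv=3, max_iter=100,
            random_state=seed,
        )
    if method == "cart":
        cls = DecisionTreeRegressor if continuous else DecisionTreeClassifier
        return cls(random_state=seed)
    raise ValidationError(f"unknown imputation method {method!r}")


def impute(
    masked: MaskedMatrix,
    method: str,
    seed: int = 0,
    continuous_targets: pd.Series | None = None,
    labeling: LabelingConfig | None = None,
    rf_trees: int = 500,
) -> FeatureMatrix:
    """Fill the hidden labels from the observed rows' features.

    With ``continuous_targets`` given, the learner imputes log10 IC50 on the
    masked rows and the imputed values are thresholded by ``labeling`` into
    classes; otherwise the class itself is imputed. Observed labels are
    never altered. The iterative-forest scheme (up to 10 refit iterations)
    converges after one pass when only the activity column is incomplete,
    which is the case here.
    """
    m, is_masked = masked.matrix, masked.masked
    if not is_masked.any():
        raise ValidationError("no masked rows to impute")
    if is_masked.all():
        raise ValidationError("all rows are masked; nothing to learn from")
    continuous = continuous_targets is not None
    X = m.X()
    X_obs, X_mis = X[~is_masked], X[is_masked]
    if continuous:
        y_obs = continuous_targets.to_numpy(dtype=float)[~is_masked]
        est = _fit_imputer(method, True, child_seed(seed, "impute", method), rf_trees)
        est.fit(X_obs, y_obs)
        cutoff = (labeling or LabelingConfig()).log10_cutoff
        filled = (est.predict(X_mis) <= cutoff).astype(int)
    else:
        y_obs = m.label.to_numpy()[~is_masked]
        if len(np.unique(y_obs)) < 2:
            warnings.warn("observed rows are single-class; constant imputation")
            filled = np.full(int(is_masked.sum()), y_obs[0], dtype=int)
        else:
            est = _fit_imputer(method, False, child_seed(seed, "impute", method), rf_trees)
            est.fit(X_obs, y_obs)
            filled = est.predict(X_mis).astype(int)
    label = m.label.copy()
    label.iloc[np.flatnonzero(is_masked)] = filled
    return FeatureMatrix(
        ids=m.ids, features=m.features, gene_cols=list(m.gene_cols),
        chem_cols=list(m.chem_cols), label=label, mode="classify",
    )


def _cv_on_imputed(
    completed: FeatureMatrix,
    true_labels: pd.Series,
    never_masked: np.ndarray,
    cfg: RFConfig,
    k: int,
    seed: int,
) -> CVResult:
    """k-fold CV training on imputed labels, testing on never-masked truth.

    Fold assignment and per-fold seeds mirror ``kfold_cv`` exactly, so at
    masking fraction 0 the result coincides with the ordinary pipeline.
    """
    rng = child_rng(seed, "folds")
    folds = _fold_assignment(completed.n_rows, k, False, rng)
    all_rows = np.arange(completed.n_rows)
    result = CVResult()
    for i, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(all_rows, test_idx)
        train = completed.take(train_idx)
        train = smote_balance(train, seed=child_seed(seed, "smote", i))
        fold_seed = child_seed(seed, "fold", i)
        model = train_classifier(train, RFConfig(cfg.n_trees, cfg.m_try, fold_seed))
        eval_idx = test_idx[never_masked[test_idx]]
        if len(eval_idx) == 0:
            warnings.warn(f"fold {i}: no never-masked rows to evaluate on; skipped")
            continue
        test = completed.take(eval_idx)
        result.folds.append(
            compute_metrics(model.predict(test), true_labels.iloc[eval_idx].to_numpy())
        )
        result.seeds.append(fold_seed)
    return result


def imputation_experiment(
    panel: OncogenePanel,
    drugs: DrugLibrary,
    sens: SensitivityTable,
    gene_subset: list[str] | None,
    cfg: RFConfig,
    labeling: LabelingConfig | None = None,
    fractions=DEFAULT_FRACTIONS,
    methods=IMPUTE_METHODS,
    continuous: bool = False,
    k: int = 5,
    seed: int | None = None,
    rf_trees: int = 500,
) -> pd.DataFrame:
    """Mask -> impute -> retrain -> evaluate, fully crossed over fractions
    and methods. Returns one tidy row per (fraction, method) with the
    imputation accuracy against the truth store and the downstream
    classification metrics on never-masked test rows."""
    labeling = labeling or LabelingConfig()
    seed = cfg.seed if seed is None else seed
    matrix = assemble_matrix(panel, drugs, sens, gene_subset, labeling, mode="classify")
    targets = None
    if continuous:
        targets = assemble_matrix(
            panel, drugs, sens, gene_subset, labeling, mode="regress"
        ).target
    true_labels = matrix.label.copy()
    rows = []
    for frac in fractions:
        for method in methods:
            if frac == 0:
                completed, never_masked, imp_acc = matrix, np.ones(matrix.n_rows, bool), float("nan")
            else:
                plan = make_mask_plan(matrix, frac, child_seed(seed, "plan", f"{frac:g}"))
                masked = mask_values(matrix, plan)
                completed = impute(
                    masked, method, seed=child_seed(seed, "imp", method, f"{frac:g}"),
                    continuous_targets=targets, labeling=labeling, rf_trees=rf_trees,
                )
                never_masked = ~masked.masked
                filled = completed.label[masked.masked].to_numpy()
                imp_acc = float((filled == masked.truth.to_numpy()).mean())
                assert (completed.label[never_masked] == true_labels[never_masked]).all()
            cv = _cv_on_imputed(completed, true_labels, never_masked, cfg, k, seed)
            row = {"fraction": frac, "method": method, "imputation_accuracy": imp_acc}
            for metric in ("accuracy", "sensitivity", "specificity", "kappa"):
                row[metric] = cv.mean(metric)
                row[f"{metric}_sd"] = cv.sd(metric)
            rows.append(row)
    return pd.DataFrame(rows)
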