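"""Random-forest regression of log10(IC50) with validation battery.

Headline metrics are pooled out-of-fold RMSE, Pearson r and Spearman rho
(every pair predicted exactly once by a model not trained on it); per-fold
metrics supply dispersion. Blind generalization is measured by
leave-one-drug-out validation, and chance structure by y-randomization and
dummy regressors (training mean, training quantiles, 9-NN mean).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, spearmanr
from sklearn.ensemble import RandomForestRegressor
from sklearn.neighbors import KNeighborsRegressor

from ._seeds import child_rng, child_seed
from .classification import RFConfig, _fold_assignment
from .datatypes import DrugLibrary, FeatureMatrix, OncogenePanel, SensitivityTable
from .exceptions import ValidationError
from .features import assemble_matrix


@dataclass(frozen=True)
class RegMetrics:
    """RMSE (log10 IC50 units), Pearson r and Spearman rho over n pairs.

    Correlations of constant vectors are undefined and reported as NaN,
    never coerced to 0.
    """

    rmse: float
    pearson_r: float
    spearman_rho: float
    n: int

    def as_dict(self) -> dict:
        return {"rmse": self.rmse, "pearson_r": self.pearson_r,
                "spearman_rho": self.spearman_rho, "n": self.n}


def reg_metrics(predicted, observed) -> RegMetrics:
    pred = np.asarray(predicted, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if pred.shape != obs.shape or pred.size == 0:
        raise ValidationError("predicted and observed must be equal-length, non-empty")
    rmse = float(np.sqrt(np.mean((pred - obs) ** 2)))
    if np.ptp(pred) == 0 or np.ptp(obs) == 0:
        warnings.warn("constant vector: correlations undefined, reported missing")
        r = rho = float("nan")
    else:
        r = float(pearsonr(pred, obs).statistic)
        rho = float(spearmanr(pred, obs).statistic)
    return RegMetrics(rmse=rmse, pearson_r=r, spearman_rho=rho, n=pred.size)


class FittedRegressor:
    """Opaque handle around a fitted regression forest."""

    def __init__(self, forest: RandomForestRegressor, feature_names: list[str]):
        self._forest = forest
        self.feature_names = list(feature_names)

    def predict(self, features) -> np.ndarray:
        if isinstance(features, FeatureMatrix):
            features = features.X()
        return self._forest.predict(np.asarray(features, dtype=np.float32))

    def gini_importance(self) -> pd.Series:
        return pd.Series(
            self._forest.feature_importances_, index=self.feature_names, name="gini_importance"
        )


def _regression_mtry(cfg: RFConfig, n_features: int) -> int:
    """Features tried per split for regression forests.

    Defaults to the classical regression-forest setting of one third of the
    features (Breiman's p/3), which fits the continuous target far better
    than the sqrt rule used for classification; an explicit ``m_try`` in the
    config overrides it.
    """
    if cfg.m_try is not None:
        return cfg.resolve_mtry(n_features)
    return max(1, n_features // 3)


def train_regressor(matrix: FeatureMatrix, cfg: RFConfig) -> FittedRegressor:
    """Fit a random forest on a regress-mode matrix; deterministic per seed."""
    if matrix.mode != "regress":
        raise ValidationError("train_regressor requires a regress-mode matrix")
    y = matrix.y()
    if np.ptp(y) == 0:
        warnings.warn("constant regression target; predictions will be constant")
    forest = RandomForestRegressor(
        n_estimators=cfg.n_trees,
        max_features=_regression_mtry(cfg, matrix.n_features),
        random_state=child_seed(cfg.seed, "rf"),
        n_jobs=1,
    )
    forest.fit(matrix.X(), y)
    return FittedRegressor(forest, list(matrix.features.columns))


@dataclass
class RegressionCVResult:
    pooled: RegMetrics
    per_fold: pd.DataFrame
    predictions: pd.DataFrame  # drug_id, cell_line_id, observed, predicted, fold


def regression_cv(
    matrix: FeatureMatrix,
    cfg: RFConfig,
    k: int = 5,
    permute_train_targets: bool = False,
    seed: int | None = None,
) -> RegressionCVResult:
    """k-fold CV: every row predicted exactly once from a model not trained
    on it. ``permute_train_targets`` shuffles each training split's targets
    (y-randomization) while test targets stay untouched."""
    if k < 2 or k > matrix.n_rows:
        raise ValidationError(f"k={k} invalid for {matrix.n_rows} rows")
    seed = cfg.seed if seed is None else seed
    rng = child_rng(seed, "folds")
    folds = _fold_assignment(matrix.n_rows, k, False, rng)
    all_rows = np.arange(matrix.n_rows)
    pred = np.full(matrix.n_rows, np.nan)
    fold_of = np.full(matrix.n_rows, -1)
    fold_rows = []
    for i, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(all_rows, test_idx)
        train = matrix.take(train_idx)
        if permute_train_targets:
            perm = child_rng(seed, "yrand", i).permutation(train.n_rows)
            train = FeatureMatrix(
                ids=train.ids, features=train.features, gene_cols=train.gene_cols,
                chem_cols=train.chem_cols,
                target=train.target.iloc[perm].reset_index(drop=True), mode="regress",
            )
        model = train_regressor(train, RFConfig(cfg.n_trees, cfg.m_try, child_seed(seed, "fold", i)))
        test = matrix.take(test_idx)
        pred[test_idx] = model.predict(test)
        fold_of[test_idx] = i
        fold_rows.append({"fold": i, **reg_metrics(pred[test_idx], test.y()).as_dict()})
    pooled = reg_metrics(pred, matrix.y())
    predictions = pd.DataFrame(
        {
            "drug_id": matrix.ids["drug_id"],
            "cell_line_id": matrix.ids["cell_line_id"],
            "observed": matrix.y(),
            "predicted": pred,
            "fold": fold_of,
        }
    )
    return RegressionCVResult(pooled=pooled, per_fold=pd.DataFrame(fold_rows), predictions=predictions)


def leave_one_drug_out(
    panel: OncogenePanel,
    drugs: DrugLibrary,
    sens: SensitivityTable,
    gene_subset: list[str] | None,
    cfg: RFConfig,
    drug_ids: list[str] | None = None,
    n_drugs: int = 9,
    seed: int | None = None,
) -> pd.DataFrame:
    """Blind per-drug validation: for each held-out drug, a model trained on
    every other drug predicts its log10 IC50 values. Defaults to 9 randomly
    selected drugs. Returns per-drug metrics plus a ``mean`` summary row."""
    seed = cfg.seed if seed is None else seed
    matrix = assemble_matrix(panel, drugs, sens, gene_subset, mode="regress")
    row_drug = matrix.ids["drug_id"].to_numpy()
    if drug_ids is None:
        counts = pd.Series(row_drug).value_counts()
        eligible = [d for d in drugs.drug_ids if counts.get(d, 0) >= 10]
        if len(eligible) < n_drugs:
            raise ValidationError("not enough drugs with >= 10 records to hold out")
        rng = child_rng(seed, "lodo-pick")
        drug_ids = sorted(rng.choice(eligible, size=n_drugs, replace=False))
    rows = []
    for d in drug_ids:
        test_mask = row_drug == d
        if test_mask.sum() < 10:
            raise ValidationError(f"held-out drug {d} has fewer than 10 records")
        train = matrix.take(np.flatnonzero(~test_mask))
        test = matrix.take(np.flatnonzero(test_mask))
        model = train_regressor(
            train, RFConfig(cfg.n_trees, cfg.m_try, child_seed(seed, "lodo", str(d)))
        )
        m = reg_metrics(model.predict(test), test.y())
        rows.append({"drug_id": str(d), **m.as_dict()})
    df = pd.DataFrame(rows)
    summary = {"drug_id": "mean", **df[["rmse", "pearson_r", "spearman_rho"]].mean().to_dict(),
               "n": int(df["n"].sum())}
    return pd.concat([df, pd.DataFrame([summary])], ignore_index=True)


DUMMY_REG_STRATEGIES = ("zero_rule_mean", "quantile", "knn9")
QUANTILE_GRID = tuple(round(q, 2) for q in np.arange(0.05, 0.96, 0.05))


def dummy_regressor(
    strategy: str,
    matrix: FeatureMatrix,
    k_folds: int = 10,
    q: float | None = None,
    seed: int = 0,
) -> RegMetrics:
    """Dataset-based regression baseline under k-fold CV (pooled).

    zero_rule_mean predicts the training mean; quantile(q) the training
    q-quantile (q on the 5%..95% grid); knn9 the mean target of the 9
    nearest training rows.
    """
    if strategy not in DUMMY_REG_STRATEGIES:
        raise ValidationError(f"unknown dummy regressor {strategy!r}")
    if strategy == "quantile":
        if q is None or round(float(q), 2) not in QUANTILE_GRID:
            raise ValidationError(f"quantile q must be one of {QUANTILE_GRID}")
    X, y = matrix.X(), matrix.y()
    rng = child_rng(seed, "dummy-folds")
    folds = _fold_assignment(len(y), k_folds, False, rng)
    all_rows = np.arange(len(y))
    pred = np.full(len(y), np.nan)
    for test_idx in folds:
        train_idx = np.setdiff1d(all_rows, test_idx)
        if strategy == "zero_rule_mean":
            pred[test_idx] = y[train_idx].mean()
        elif strategy == "quantile":
            pred[test_idx] = np.quantile(y[train_idx], q)
        else:
            est = KNeighborsRegressor(n_neighbors=9).fit(X[train_idx], y[train_idx])
            pred[test_idx] = est.predict(X[test_idx])
    return reg_metrics(pred, y)
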