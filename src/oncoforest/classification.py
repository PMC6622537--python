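"""Random-forest activity classification with full validation battery.

Implements the classification half of the pipeline: 500-tree random forests
over the joined mutation + fingerprint features, confusion-matrix metrics
(accuracy, sensitivity, specificity, FPR, NPV, Cohen's kappa), shuffled
5-fold cross-validation, hand-rolled SMOTE balancing applied inside training
folds, an activity-cutoff sweep producing an ROC curve whose points are the
(FPR, sensitivity) pairs of models trained at each IC50 cutoff, label
shuffling (y-randomization), leave-drugs-out blind validation, and dummy
baselines (zero rule, stratified, uniform, 9-nearest-neighbors).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.dummy import DummyClassifier
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier, NearestNeighbors

from ._seeds import child_rng, child_seed
from .datatypes import DrugLibrary, FeatureMatrix, OncogenePanel, SensitivityTable
from .exceptions import DegenerateLabelsError, ValidationError
from .features import LabelingConfig, assemble_matrix

#: IC50 cutoff grid (micromolar) swept when building the ROC curve: the
#: 44-value grid from 0.01 to 5000 uM plus the initial 1 uM cutoff.
SWEEP_CUTOFFS_UM: tuple[float, ...] = (
    0.01, 0.05, 0.08, 0.1, 0.5, 0.6, 0.7, 0.8, 1.0, 2, 3, 4, 5, 6, 7, 8, 9,
    10, 12, 14, 16, 18, 20, 30, 40, 50, 75, 100, 150, 200, 250, 300, 350,
    400, 450, 500, 600, 700, 800, 900, 1000, 2500, 3000, 4000, 5000,
)


@dataclass(frozen=True)
class RFConfig:
    """Random-forest hyperparameters.

    ``m_try`` (features tried per split) defaults to round(sqrt(n_features)),
    which gives 37 for the 1361-feature full matrix.
    """

    n_trees: int = 500
    m_try: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValidationError("n_trees must be >= 1")

    def resolve_mtry(self, n_features: int) -> int:
        if self.m_try is not None:
            if not 1 <= self.m_try <= n_features:
                raise ValidationError(f"m_try={self.m_try} out of range 1..{n_features}")
            return self.m_try
        return max(1, round(math.sqrt(n_features)))


@dataclass(frozen=True)
class ClassMetrics:
    """Confusion-matrix statistics for a binary activity classifier.

    accuracy = (TP+TN)/N, sensitivity = TP/(TP+FN), specificity = TN/(TN+FP),
    FPR = FP/(TN+FP), NPV = TN/(TN+FN), kappa = (p0-pe)/(1-pe) with
    pe = [(TP+FN)(TP+FP) + (FP+TN)(FN+TN)] / N^2. Ratios with a zero
    denominator are reported as NaN (missing) with a warning.
    """

    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float
    fpr: float
    npv: float
    p0: float
    pe: float
    kappa: float
    n: int

    @classmethod
    def from_counts(cls, tp: int, tn: int, fp: int, fn: int) -> "ClassMetrics":
        n = tp + tn + fp + fn
        if n == 0:
            raise ValidationError("empty confusion matrix")

        def ratio(num, den, name):
            if den == 0:
                warnings.warn(f"{name} undefined (zero denominator); reported missing")
                return float("nan")
            return num / den

        p0 = (tp + tn) / n
        pe = ((tp + fn) * (tp + fp) + (fp + tn) * (fn + tn)) / n**2
        kappa = float("nan") if pe == 1.0 else (p0 - pe) / (1.0 - pe)
        if pe == 1.0:
            warnings.warn("kappa undefined (pe == 1); reported missing")
        return cls(
            tp=tp, tn=tn, fp=fp, fn=fn,
            accuracy=p0,
            sensitivity=ratio(tp, tp + fn, "sensitivity"),
            specificity=ratio(tn, tn + fp, "specificity"),
            fpr=ratio(fp, tn + fp, "FPR"),
            npv=ratio(tn, tn + fn, "NPV"),
            p0=p0, pe=pe, kappa=kappa, n=n,
        )

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "tp", "tn", "fp", "fn", "n", "accuracy", "sensitivity",
            "specificity", "fpr", "npv", "p0", "pe", "kappa")}


def compute_metrics(predictions, truth) -> ClassMetrics:
    """Confusion-derived metrics of 0/1 predictions against 0/1 truth."""
    pred = np.asarray(predictions, dtype=int)
    true = np.asarray(truth, dtype=int)
    if pred.shape != true.shape:
        raise ValidationError("predictions and truth differ in length")
    if pred.size == 0:
        raise ValidationError("empty prediction vector")
    tp = int(((pred == 1) & (true == 1)).sum())
    tn = int(((pred == 0) & (true == 0)).sum())
    fp = int(((pred == 1) & (true == 0)).sum())
    fn = int(((pred == 0) & (true == 1)).sum())
    return ClassMetrics.from_counts(tp, tn, fp, fn)


class FittedClassifier:
    """Opaque handle around a fitted forest: predictions + Gini importance."""

    def __init__(self, forest: RandomForestClassifier, feature_names: list[str]):
        self._forest = forest
        self.feature_names = list(feature_names)

    def predict(self, features) -> np.ndarray:
        if isinstance(features, FeatureMatrix):
            features = features.X()
        return self._forest.predict(np.asarray(features, dtype=np.float32))

    def gini_importance(self) -> pd.Series:
        """Mean-decrease-in-impurity importance per feature (all >= 0)."""
        return pd.Series(
            self._forest.feature_importances_, index=self.feature_names, name="gini_importance"
        )


def train_classifier(matrix: FeatureMatrix, cfg: RFConfig) -> FittedClassifier:
    """Fit a random forest on a classify-mode matrix; deterministic per seed."""
    if matrix.mode != "classify":
        raise ValidationError("train_classifier requires a classify-mode matrix")
    y = matrix.y()
    if len(np.unique(y)) < 2:
        raise DegenerateLabelsError("training labels contain a single class")
    forest = RandomForestClassifier(
        n_estimators=cfg.n_trees,
        max_features=cfg.resolve_mtry(matrix.n_features),
        random_state=child_seed(cfg.seed, "rf"),
        n_jobs=1,
    )
    forest.fit(matrix.X(), y)
    return FittedClassifier(forest, list(matrix.features.columns))


# ---------------------------------------------------------------------------
# SMOTE
# ---------------------------------------------------------------------------

def smote_balance(
    matrix: FeatureMatrix,
    minority_threshold: float = 0.20,
    k_neighbors: int = 5,
    seed: int = 0,
) -> FeatureMatrix:
    """Balance classes by synthetic minority over-sampling + under-sampling.

    Applied only when the minority class is below ``minority_threshold`` of
    the rows; otherwise the matrix is returned unchanged. Each synthetic row
    is ``x + u * (x' - x)`` with ``u ~ Uniform(0,1)``, ``x`` a minority row
    and ``x'`` one of its ``k_neighbors`` minority-class Euclidean nearest
    neighbors; the majority class is randomly under-sampled. Both classes end
    at half the original row count (ratio 1.0).
    """
    if matrix.mode != "classify":
        raise ValidationError("smote_balance requires a classify-mode matrix")
    y = matrix.y()
    counts = np.bincount(y, minlength=2)
    if counts.min() == 0:
        raise DegenerateLabelsError("both classes must be present for balancing")
    minority = int(np.argmin(counts))
    n_min, total = int(counts[minority]), len(y)
    if n_min / total >= minority_threshold:
        return matrix
    if n_min < 2:
        raise DegenerateLabelsError("fewer than 2 minority rows; cannot interpolate")
    k = k_neighbors
    if n_min <= k_neighbors:
        k = n_min - 1
        warnings.warn(f"minority count {n_min} <= k_neighbors; falling back to k={k}")
    rng = child_rng(seed, "smote")
    min_idx = np.flatnonzero(y == minority)
    maj_idx = np.flatnonzero(y != minority)
    # interpolate in full precision so synthetic rows lie exactly on segments
    X_min = matrix.features.to_numpy(dtype=float)[min_idx]
    target = total // 2
    n_syn = max(0, target - n_min)

    nn = NearestNeighbors(n_neighbors=k + 1).fit(X_min)
    neigh = nn.kneighbors(X_min, return_distance=False)[:, 1:]  # drop self
    base = rng.integers(0, n_min, size=n_syn)
    pick = neigh[base, rng.integers(0, k, size=n_syn)]
    u = rng.random(n_syn)[:, None]
    X_syn = X_min[base] + u * (X_min[pick] - X_min[base])

    keep_maj = rng.choice(maj_idx, size=min(target, len(maj_idx)), replace=False)
    kept = np.concatenate([min_idx, keep_maj])
    kept_mat = matrix.take(kept)
    syn_feat = pd.DataFrame(X_syn, columns=matrix.features.columns)
    syn_ids = matrix.ids.iloc[min_idx[base]].reset_index(drop=True)
    features = pd.concat([kept_mat.features, syn_feat], ignore_index=True)
    ids = pd.concat([kept_mat.ids, syn_ids], ignore_index=True)
    label = pd.concat(
        [kept_mat.label, pd.Series(np.full(n_syn, minority, dtype=int))], ignore_index=True
    )
    return FeatureMatrix(
        ids=ids, features=features, gene_cols=list(matrix.gene_cols),
        chem_cols=list(matrix.chem_cols), label=label, mode="classify",
    )


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    """Per-fold metrics with mean/sd aggregation."""

    folds: list[ClassMetrics] = field(default_factory=list)
    seeds: list[int] = field(default_factory=list)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame([m.as_dict() for m in self.folds])

    def mean(self, metric: str) -> float:
        return float(np.nanmean([getattr(m, metric) for m in self.folds]))

    def sd(self, metric: str) -> float:
        return float(np.nanstd([getattr(m, metric) for m in self.folds], ddof=1))

    def summary(self) -> pd.DataFrame:
        df = self.as_frame()
        num = df.drop(columns=["tp", "tn", "fp", "fn", "n"])
        return pd.DataFrame({"mean": num.mean(), "sd": num.std(ddof=1)})


def _fold_assignment(n: int, k: int, ordered: bool, rng) -> list[np.ndarray]:
    """Contiguous k-way split of (optionally shuffled) row order."""
    order = np.arange(n)
    if not ordered:
        rng.shuffle(order)
    return [np.sort(chunk) for chunk in np.array_split(order, k)]


def kfold_cv(
    matrix: FeatureMatrix,
    cfg: RFConfig,
    k: int = 5,
    ordered_folds: bool = False,
    smote: bool = True,
    minority_threshold: float = 0.20,
    smote_before_split: bool = False,
    permute_train_labels: bool = False,
    seed: int | None = None,
) -> CVResult:
    """k-fold cross-validated classification metrics.

    Rows are shuffled with a recorded seed before contiguous splitting
    (``ordered_folds=True`` reproduces an unshuffled first-80%/last-20%
    style split). SMOTE runs inside each training fold by default;
    ``smote_before_split`` balances the whole matrix first (the
    leakage-prone variant, kept as an explicit option).
    ``permute_train_labels`` shuffles each training split's labels
    (y-randomization) while test labels stay untouched.
    """
    if k < 2:
        raise ValidationError("k must be >= 2")
    if k > matrix.n_rows:
        raise ValidationError(f"k={k} exceeds row count {matrix.n_rows}")
    seed = cfg.seed if seed is None else seed
    if smote_before_split and smote:
        matrix = smote_balance(matrix, minority_threshold, seed=child_seed(seed, "presplit"))
    rng = child_rng(seed, "folds")
    folds = _fold_assignment(matrix.n_rows, k, ordered_folds, rng)
    result = CVResult()
    all_rows = np.arange(matrix.n_rows)
    for i, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(all_rows, test_idx)
        train = matrix.take(train_idx)
        if len(np.unique(train.y())) < 2:
            raise DegenerateLabelsError(f"fold {i}: training split contains one class")
        if permute_train_labels:
            perm = child_rng(seed, "yrand", i).permutation(train.n_rows)
            train = FeatureMatrix(
                ids=train.ids, features=train.features,
                gene_cols=train.gene_cols, chem_cols=train.chem_cols,
                label=train.label.iloc[perm].reset_index(drop=True), mode="classify",
            )
        if smote and not smote_before_split:
            train = smote_balance(
                train, minority_threshold, seed=child_seed(seed, "smote", i)
            )
        fold_seed = child_seed(seed, "fold", i)
        model = train_classifier(train, RFConfig(cfg.n_trees, cfg.m_try, fold_seed))
        test = matrix.take(test_idx)
        result.folds.append(compute_metrics(model.predict(test), test.y()))
        result.seeds.append(fold_seed)
    return result


def y_randomize(
    matrix: FeatureMatrix,
    cfg: RFConfig,
    k: int = 5,
    repeats: int = 5,
    seed: int | None = None,
) -> list[CVResult]:
    """Repeated y-randomization: labels shuffled within training splits only,
    metrics computed on the untouched test folds. With chance-level
    correlations removed, mean kappa collapses to ~0."""
    seed = cfg.seed if seed is None else seed
    return [
        kfold_cv(
            matrix, cfg, k=k, permute_train_labels=True,
            seed=child_seed(seed, "yrand-repeat", r),
        )
        for r in range(repeats)
    ]


def leave_drugs_out_cv(
    panel: OncogenePanel,
    drugs: DrugLibrary,
    sens: SensitivityTable,
    gene_subset: list[str] | None,
    cfg: RFConfig,
    labeling: LabelingConfig | None = None,
    n_out: int = 10,
    rounds: int = 20,
    seed: int | None = None,
) -> CVResult:
    """Blind validation: per round, withhold ``n_out`` random drugs entirely.

    The training and test sets never share a drug, simulating prediction for
    a compound unseen during training.
    """
    if n_out < 1:
        raise ValidationError("n_out must be >= 1 (no test set otherwise)")
    drug_ids = np.asarray(drugs.drug_ids)
    if n_out >= len(drug_ids):
        raise ValidationError("n_out must be smaller than the drug count")
    seed = cfg.seed if seed is None else seed
    matrix = assemble_matrix(panel, drugs, sens, gene_subset, labeling, mode="classify")
    row_drug = matrix.ids["drug_id"].to_numpy()
    result = CVResult()
    for r in range(rounds):
        rng = child_rng(seed, "lodo", r)
        held = set(rng.choice(drug_ids, size=n_out, replace=False))
        test_mask = np.isin(row_drug, list(held))
        train = matrix.take(np.flatnonzero(~test_mask))
        test = matrix.take(np.flatnonzero(test_mask))
        if test.n_rows == 0:
            warnings.warn(f"round {r}: withheld drugs have no records; skipped")
            continue
        train = smote_balance(train, seed=child_seed(seed, "lodo-smote", r))
        round_seed = child_seed(seed, "lodo-fit", r)
        model = train_classifier(train, RFConfig(cfg.n_trees, cfg.m_try, round_seed))
        if len(np.unique(test.y())) < 2:
            warnings.warn(
                f"round {r}: withheld set contains one class; sensitivity or "
                "specificity reported missing"
            )
        result.folds.append(compute_metrics(model.predict(test), test.y()))
        result.seeds.append(round_seed)
    return result


# ---------------------------------------------------------------------------
# ROC over activity cutoffs
# ---------------------------------------------------------------------------

@dataclass
class ROCCurve:
    """ROC built from (FPR, sensitivity) of models at each IC50 cutoff."""

    points: pd.DataFrame  # columns: cutoff_molar, fpr, tpr
    auc: float

    def as_frame(self) -> pd.DataFrame:
        return self.points.copy()


def trapezoid_auc(points) -> float:
    """Trapezoid area under (FPR, TPR) points augmented with (0,0), (1,1)."""
    pts = [(0.0, 0.0), (1.0, 1.0)] + [(float(f), float(t)) for f, t in points]
    pts = sorted(set(pts))
    fpr = np.array([p[0] for p in pts])
    tpr = np.array([p[1] for p in pts])
    if ((fpr < 0) | (fpr > 1) | (tpr < 0) | (tpr > 1)).any():
        raise ValidationError("ROC coordinates must lie in [0, 1]")
    return float(np.trapezoid(tpr, fpr))


def cutoff_sweep(
    panel: OncogenePanel,
    drugs: DrugLibrary,
    sens: SensitivityTable,
    gene_subset: list[str] | None,
    cfg: RFConfig,
    cutoffs_molar: list[float] | None = None,
    k: int = 5,
    permute_train_labels: bool = False,
    seed: int | None = None,
) -> ROCCurve:
    """Relabel at each cutoff, balance if needed, cross-validate, and collect
    mean (FPR, sensitivity) per cutoff into an ROC curve."""
    if cutoffs_molar is None:
        cutoffs_molar = [c * 1e-6 for c in SWEEP_CUTOFFS_UM]
    if any(c <= 0 for c in cutoffs_molar):
        raise ValidationError("cutoffs must be strictly positive")
    seed = cfg.seed if seed is None else seed
    base = assemble_matrix(panel, drugs, sens, gene_subset, mode="regress")
    rows = []
    for c in cutoffs_molar:
        label = (base.target <= math.log10(c)).astype(int)
        if label.nunique() < 2:
            warnings.warn(f"cutoff {c:g} M yields a single class; point skipped")
            continue
        mat = FeatureMatrix(
            ids=base.ids, features=base.features, gene_cols=base.gene_cols,
            chem_cols=base.chem_cols, label=label.rename("label"), mode="classify",
        )
        try:
            cv = kfold_cv(
                mat, cfg, k=k, smote=True,
                permute_train_labels=permute_train_labels,
                seed=child_seed(seed, "sweep", f"{c:.6g}"),
            )
        except DegenerateLabelsError as exc:
            warnings.warn(f"cutoff {c:g} M skipped: {exc}")
            continue
        rows.append({"cutoff_molar": c, "fpr": cv.mean("fpr"), "tpr": cv.mean("sensitivity")})
    pts = pd.DataFrame(rows, columns=["cutoff_molar", "fpr", "tpr"])
    auc = trapezoid_auc(pts[["fpr", "tpr"]].dropna().to_numpy())
    return ROCCurve(points=pts, auc=auc)


# ---------------------------------------------------------------------------
# Dummy baselines
# ---------------------------------------------------------------------------

DUMMY_STRATEGIES = ("zero_rule", "stratified", "uniform", "knn9")


def dummy_classifier(
    strategy: str, matrix: FeatureMatrix, k_folds: int = 10, seed: int = 0
) -> ClassMetrics:
    """Dataset-based baseline evaluated with stratified k-fold CV (pooled).

    zero_rule assigns the majority class to every instance (its pooled
    accuracy equals the majority fraction exactly); stratified draws labels
    from the training distribution; uniform is a fair coin; knn9 is the
    majority vote of the 9 nearest training rows.
    """
    if strategy not in DUMMY_STRATEGIES:
        raise ValidationError(f"unknown dummy strategy {strategy!r}")
    X, y = matrix.X(), matrix.y()
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=child_seed(seed, "dummy-folds"))
    pred = np.empty_like(y)
    for i, (tr, te) in enumerate(skf.split(X, y)):
        fold_seed = child_seed(seed, "dummy", strategy, i)
        if strategy == "knn9":
            est = KNeighborsClassifier(n_neighbors=9)
        else:
            sk_name = {"zero_rule": "most_frequent", "stratified": "stratified",
                       "uniform": "uniform"}[strategy]
            est = DummyClassifier(strategy=sk_name, random_state=fold_seed)
        est.fit(X[tr], y[tr])
        pred[te] = est.predict(X[te])
    return compute_metrics(pred, y)
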