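"""Classifier training, confusion metrics, SMOTE, CV schemes, baselines."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import cohen_kappa_score

from oncoforest.classification import (
    ClassMetrics,
    RFConfig,
    compute_metrics,
    dummy_classifier,
    kfold_cv,
    smote_balance,
    train_classifier,
    trapezoid_auc,
)
from oncoforest.datatypes import FeatureMatrix
from oncoforest.exceptions import DegenerateLabelsError, ValidationError


def toy_matrix(n=60, p=6, seed=0, label_from_feature=0, flip=0.0):
    """Labels equal (optionally noisy) copies of one binary feature."""
    rng = np.random.default_rng(seed)
    X = rng.integers(0, 2, size=(n, p)).astype(float)
    y = X[:, label_from_feature].astype(int)
    if flip:
        sel = rng.random(n) < flip
        y[sel] = 1 - y[sel]
    return FeatureMatrix(
        ids=pd.DataFrame({"drug_id": ["d"] * n, "cell_line_id": [f"c{i}" for i in range(n)]}),
        features=pd.DataFrame(X, columns=[f"g{j}" for j in range(p)]),
        gene_cols=[f"g{j}" for j in range(p)],
        chem_cols=[],
        label=pd.Series(y),
        mode="classify",
    )


class TestComputeMetrics:
    def test_perfect(self):
        m = ClassMetrics.from_counts(50, 50, 0, 0)
        assert m.accuracy == 1.0 and m.kappa == 1.0

    def test_chance(self):
        m = ClassMetrics.from_counts(25, 25, 25, 25)
        assert m.accuracy == 0.5 and m.kappa == 0.0

    def test_hand_worked_confusion(self):
        m = ClassMetrics.from_counts(tp=40, tn=30, fp=10, fn=20)
        assert m.accuracy == pytest.approx(0.70)
        assert m.sensitivity == pytest.approx(2 / 3, abs=1e-4)
        assert m.specificity == pytest.approx(0.75)
        assert m.fpr == pytest.approx(0.25)
        assert m.npv == pytest.approx(0.60)
        assert m.pe == pytest.approx(0.50)
        assert m.kappa == pytest.approx(0.40)

    def test_empty_raises(self):
        with pytest.raises(ValidationError):
            compute_metrics([], [])

    def test_zero_denominator_reported_missing(self):
        with pytest.warns(UserWarning, match="sensitivity undefined"):
            m = compute_metrics([0, 0], [0, 0])
        assert np.isnan(m.sensitivity)

    @given(st.lists(st.integers(0, 500), min_size=4, max_size=4))
    @settings(max_examples=200, deadline=None)
    def test_identities_against_independent_arithmetic(self, counts):
        tp, tn, fp, fn = counts
        n = tp + tn + fp + fn
        if n == 0:
            return
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = ClassMetrics.from_counts(tp, tn, fp, fn)
        assert m.tp + m.tn + m.fp + m.fn == m.n == n
        assert m.accuracy == pytest.approx((tp + tn) / n)
        if tn + fp:
            assert m.fpr == pytest.approx(1 - m.specificity)
        # kappa against scikit-learn on a reconstructed label vector
        truth = [1] * (tp + fn) + [0] * (fp + tn)
        pred = [1] * tp + [0] * fn + [1] * fp + [0] * tn
        if len(set(truth)) == 2 and not np.isnan(m.kappa):
            assert m.kappa == pytest.approx(cohen_kappa_score(truth, pred), abs=1e-12)


class TestTrainClassifier:
    def test_separable_training_accuracy(self):
        mat = toy_matrix(n=50)
        model = train_classifier(mat, RFConfig(n_trees=20, seed=0))
        assert (model.predict(mat) == mat.y()).mean() == 1.0

    def test_deterministic_same_seed(self, smoke_matrix):
        cfg = RFConfig(n_trees=15, seed=7)
        p1 = train_classifier(smoke_matrix, cfg).predict(smoke_matrix)
        p2 = train_classifier(smoke_matrix, cfg).predict(smoke_matrix)
        np.testing.assert_array_equal(p1, p2)

    def test_single_class_raises(self):
        mat = toy_matrix(n=20)
        mat.label[:] = 1
        with pytest.raises(DegenerateLabelsError):
            train_classifier(mat, RFConfig(n_trees=5))

    def test_importance_nonnegative_and_full_length(self, smoke_matrix):
        model = train_classifier(smoke_matrix, RFConfig(n_trees=15, seed=0))
        imp = model.gini_importance()
        assert len(imp) == smoke_matrix.n_features
        assert (imp >= 0).all() and imp.sum() > 0

    def test_mtry_default_is_root_p(self):
        assert RFConfig().resolve_mtry(1361) == 37
        assert RFConfig(m_try=10).resolve_mtry(100) == 10


class TestKFold:
    def test_partition(self):
        mat = toy_matrix(n=100, flip=0.2)
        from oncoforest.classification import _fold_assignment

        rng = np.random.default_rng(0)
        folds = _fold_assignment(100, 5, False, rng)
        assert [len(f) for f in folds] == [20] * 5
        assert sorted(np.concatenate(folds)) == list(range(100))

    def test_leakage_sanity_label_is_feature(self):
        mat = toy_matrix(n=200, seed=1)
        cv = kfold_cv(mat, RFConfig(n_trees=25, seed=0), k=5)
        assert cv.mean("accuracy") >= 0.99

    def test_ordered_folds_reproduce_block_split(self):
        mat = toy_matrix(n=100, flip=0.3, seed=2)
        cv1 = kfold_cv(mat, RFConfig(n_trees=10, seed=0), k=5, ordered_folds=True)
        cv2 = kfold_cv(mat, RFConfig(n_trees=10, seed=99), k=5, ordered_folds=True, seed=0)
        # fold membership is deterministic (row order), per-fold seeds from seed
        assert [m.n for m in cv1.folds] == [m.n for m in cv2.folds] == [20] * 5
        np.testing.assert_array_equal(
            cv1.as_frame()[["tp", "tn", "fp", "fn"]], cv2.as_frame()[["tp", "tn", "fp", "fn"]]
        )

    def test_k_larger_than_rows_raises(self):
        with pytest.raises(ValidationError):
            kfold_cv(toy_matrix(n=5), RFConfig(n_trees=5), k=10)

    def test_null_permutation_equals_plain_cv(self, monkeypatch):
        """y-randomization with an identity shuffle reduces to ordinary CV."""
        mat = toy_matrix(n=120, flip=0.2, seed=3)
        cfg = RFConfig(n_trees=15, seed=4)
        plain = kfold_cv(mat, cfg, k=4)
        import oncoforest.classification as clf

        real_rng = clf.child_rng

        def identity_rng(master, *labels):
            rng = real_rng(master, *labels)
            if labels and labels[0] == "yrand":
                class _Id:
                    def permutation(self, n):
                        return np.arange(n)
                return _Id()
            return rng

        monkeypatch.setattr(clf, "child_rng", identity_rng)
        nulled = kfold_cv(mat, cfg, k=4, permute_train_labels=True)
        np.testing.assert_array_equal(
            plain.as_frame()[["tp", "tn", "fp", "fn"]],
            nulled.as_frame()[["tp", "tn", "fp", "fn"]],
        )


class TestYRandomize:
    def test_repeats_use_distinct_seeds_and_collapse_kappa(self):
        from oncoforest.classification import y_randomize

        mat = toy_matrix(n=150, flip=0.1, seed=6)
        results = y_randomize(mat, RFConfig(n_trees=15, seed=0), k=3, repeats=3)
        assert len(results) == 3
        seed_sets = [tuple(r.seeds) for r in results]
        assert len(set(seed_sets)) == 3  # distinct shuffles recorded
        # shuffled-label models sit near chance on a strongly-labeled toy
        assert abs(np.mean([r.mean("kappa") for r in results])) < 0.25


class TestLeaveDrugsOut:
    def test_zero_holdout_rejected(self, smoke_data):
        from oncoforest.classification import leave_drugs_out_cv

        panel, drugs, sens, _ = smoke_data
        with pytest.raises(ValidationError, match="no test set"):
            leave_drugs_out_cv(panel, drugs, sens, None, RFConfig(n_trees=5), n_out=0)

    def test_rounds_reported(self, smoke_data):
        from oncoforest.classification import leave_drugs_out_cv

        panel, drugs, sens, _ = smoke_data
        res = leave_drugs_out_cv(
            panel, drugs, sens, None, RFConfig(n_trees=10, seed=0), n_out=2, rounds=3
        )
        assert len(res.folds) == 3
        # each round tests exactly the records of the withheld drugs
        assert all(m.n == 2 * panel.n_cells for m in res.folds)


class TestSmote:
    def test_balanced_matrix_unchanged(self):
        mat = toy_matrix(n=100, flip=0.1, seed=5)
        assert abs(mat.label.mean() - 0.5) < 0.2
        out = smote_balance(mat, minority_threshold=0.20, seed=0)
        assert out is mat

    def test_one_dimensional_convexity(self):
        n = 40
        X = np.zeros((n, 1))
        X[:2, 0] = [0.0, 1.0]
        y = np.array([1, 1] + [0] * (n - 2))
        mat = FeatureMatrix(
            ids=pd.DataFrame({"drug_id": ["d"] * n, "cell_line_id": [str(i) for i in range(n)]}),
            features=pd.DataFrame(X, columns=["f"]),
            gene_cols=["f"], chem_cols=[], label=pd.Series(y), mode="classify",
        )
        with pytest.warns(UserWarning, match="falling back"):
            out = smote_balance(mat, k_neighbors=5, seed=1)
        syn = out.features["f"][out.label == 1]
        assert ((syn >= 0) & (syn <= 1)).all()

    def test_geometry_and_ratio_at_5pct_minority(self):
        rng = np.random.default_rng(8)
        n, p = 1000, 4
        X = rng.normal(size=(n, p))
        y = np.zeros(n, dtype=int)
        y[:50] = 1
        X[:50] += 3.0  # separate minority cloud
        mat = FeatureMatrix(
            ids=pd.DataFrame({"drug_id": ["d"] * n, "cell_line_id": [str(i) for i in range(n)]}),
            features=pd.DataFrame(X, columns=list("abcd")),
            gene_cols=list("abcd"), chem_cols=[], label=pd.Series(y), mode="classify",
        )
        out = smote_balance(mat, k_neighbors=5, seed=3)
        frac = out.label.mean()
        assert 0.44 <= frac <= 0.56
        ratio = out.label.sum() / (len(out.label) - out.label.sum())
        assert 0.8 <= ratio <= 1.25
        # coordinate-wise containment in the minority bounding box
        mins, maxs = X[:50].min(0), X[:50].max(0)
        syn = out.features[out.label == 1].to_numpy()[50:]
        assert (syn >= mins - 1e-9).all() and (syn <= maxs + 1e-9).all()

    def test_minority_too_small_raises(self):
        mat = toy_matrix(n=30)
        mat.label[:] = 0
        mat.label[0] = 1
        with pytest.raises(DegenerateLabelsError):
            smote_balance(mat, minority_threshold=0.5, seed=0)


class TestTrapezoidAUC:
    @pytest.mark.parametrize(
        "points,expected",
        [
            ([(0, 1)], 1.0),                       # perfect: (0,0),(0,1),(1,1)
            ([(0.25, 0.25), (0.75, 0.75)], 0.5),   # diagonal
            ([(0.2, 0.6)], 0.70),                  # hand trapezoid sum
        ],
    )
    def test_hand_computed_areas(self, points, expected):
        assert trapezoid_auc(points) == pytest.approx(expected, abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            trapezoid_auc([(1.2, 0.5)])


class TestDummies:
    def _mat(self, n, frac_active, seed=0):
        rng = np.random.default_rng(seed)
        y = (rng.random(n) < frac_active).astype(int)
        X = rng.normal(size=(n, 3))
        return FeatureMatrix(
            ids=pd.DataFrame({"drug_id": ["d"] * n, "cell_line_id": [str(i) for i in range(n)]}),
            features=pd.DataFrame(X, columns=list("xyz")),
            gene_cols=list("xyz"), chem_cols=[], label=pd.Series(y), mode="classify",
        )

    def test_zero_rule_exact_majority_fraction(self):
        mat = self._mat(1000, 0.3, seed=1)
        m = dummy_classifier("zero_rule", mat, seed=0)
        assert m.accuracy == pytest.approx((mat.label == 0).mean())
        assert m.sensitivity == 0.0

    def test_uniform_near_half(self):
        mat = self._mat(20000, 0.5, seed=2)
        m = dummy_classifier("uniform", mat, seed=0)
        assert m.accuracy == pytest.approx(0.5, abs=0.02)

    def test_stratified_closed_form(self):
        mat = self._mat(50000, 0.2, seed=3)
        m = dummy_classifier("stratified", mat, seed=0)
        assert m.accuracy == pytest.approx(0.8**2 + 0.2**2, abs=0.015)
        assert abs(m.kappa) < 0.03

    def test_unknown_strategy(self):
        with pytest.raises(ValidationError):
            dummy_classifier("oracle", self._mat(50, 0.5))
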