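"""Regression forests, pooled CV metrics, blind drug hold-out, baselines."""

import numpy as np
import pandas as pd
import pytest

from oncoforest.classification import RFConfig
from oncoforest.datatypes import FeatureMatrix
from oncoforest.exceptions import ValidationError
from oncoforest.regression import (
    dummy_regressor,
    leave_one_drug_out,
    reg_metrics,
    regression_cv,
    train_regressor,
)


def linear_matrix(n=200, seed=0, noise=0.0, p=5):
    """Target is a linear function of one continuous descriptor."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    y = 2.0 * X[:, min(2, p - 1)] + rng.normal(0, noise, n)
    cols = [f"desc_{j}" for j in range(p)]
    return FeatureMatrix(
        ids=pd.DataFrame({"drug_id": [f"d{i % 8}" for i in range(n)],
                          "cell_line_id": [f"c{i}" for i in range(n)]}),
        features=pd.DataFrame(X, columns=cols),
        gene_cols=[], chem_cols=cols,
        target=pd.Series(y), mode="regress",
    )


class TestRegMetrics:
    def test_perfect_predictions(self):
        y = np.linspace(-9, -3, 50)
        m = reg_metrics(y, y)
        assert m.rmse == 0.0
        assert m.pearson_r == pytest.approx(1.0, abs=1e-12)
        assert m.spearman_rho == pytest.approx(1.0, abs=1e-12)

    def test_constant_vector_reported_missing(self):
        with pytest.warns(UserWarning, match="constant"):
            m = reg_metrics(np.ones(10), np.arange(10.0))
        assert np.isnan(m.pearson_r) and np.isnan(m.spearman_rho)

    def test_spearman_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        obs = rng.normal(size=100)
        pred = obs + rng.normal(0, 0.5, 100)
        a = reg_metrics(pred, obs).spearman_rho
        b = reg_metrics(np.exp(pred), obs).spearman_rho
        assert a == pytest.approx(b, abs=1e-12)


class TestTrainRegressor:
    def test_linear_target_high_holdout_correlation(self):
        mat = linear_matrix(n=600, seed=2, p=3)
        res = regression_cv(mat, RFConfig(n_trees=60, m_try=3, seed=0))
        assert res.pooled.pearson_r >= 0.99

    def test_deterministic_same_seed(self):
        mat = linear_matrix(n=100, seed=3, noise=0.3)
        cfg = RFConfig(n_trees=20, seed=5)
        p1 = train_regressor(mat, cfg).predict(mat)
        p2 = train_regressor(mat, cfg).predict(mat)
        np.testing.assert_array_equal(p1, p2)

    def test_constant_target_warns(self):
        mat = linear_matrix(n=50, seed=4)
        mat.target[:] = -6.0
        with pytest.warns(UserWarning, match="constant"):
            train_regressor(mat, RFConfig(n_trees=5, seed=0))


class TestRegressionCV:
    def test_every_row_predicted_once(self):
        mat = linear_matrix(n=101, seed=5, noise=0.5)
        res = regression_cv(mat, RFConfig(n_trees=15, seed=0), k=5)
        assert res.pooled.n == 101
        assert (res.predictions["fold"] >= 0).all()
        assert res.predictions["predicted"].notna().all()

    def test_invalid_k(self):
        with pytest.raises(ValidationError):
            regression_cv(linear_matrix(n=10), RFConfig(n_trees=5), k=1)


class TestLeaveOneDrugOut:
    def test_twin_drug_near_zero_rmse(self):
        """A held-out drug identical in fingerprint to a training drug, with
        negligible noise and no idiosyncratic drug effect, is predicted
        almost exactly."""
        from oncoforest.synthetic import generate_dataset, smoke_preset

        m = smoke_preset(seed=11, noise_sd=1e-6, drug_offset_chem_fraction=1.0)
        panel, drugs, sens, _ = generate_dataset(m)
        # duplicate drug_001's fingerprint into drug_002 and re-derive its
        # records from drug_001's (twin drugs, same chemistry)
        fp = drugs.fingerprints.copy()
        fp.loc["drug_002"] = fp.loc["drug_001"]
        from oncoforest.datatypes import DrugLibrary, SensitivityTable

        rec = sens.records.copy()
        vals = rec.set_index(["drug_id", "cell_line_id"])["log10_ic50"]
        twin = rec[rec["drug_id"] == "drug_002"].copy()
        twin["log10_ic50"] = vals.loc["drug_001"].reindex(twin["cell_line_id"]).to_numpy()
        rec.loc[twin.index, "log10_ic50"] = twin["log10_ic50"]
        res = leave_one_drug_out(
            panel, DrugLibrary(fingerprints=fp), SensitivityTable(rec), None,
            RFConfig(n_trees=40, seed=0), drug_ids=["drug_002"],
        )
        # bootstrap resampling leaves a small residual even for an exact twin;
        # the error is far below the between-drug spread (~1.2 log units)
        assert res.loc[0, "rmse"] < 0.35
        assert res.loc[0, "pearson_r"] > 0.95

    def test_nine_drugs_plus_summary(self, smoke_data):
        panel, drugs, sens, _ = smoke_data
        res = leave_one_drug_out(
            panel, drugs, sens, None, RFConfig(n_trees=10, seed=0), n_drugs=9
        )
        assert len(res) == 10
        assert res["drug_id"].iloc[-1] == "mean"


class TestDummyRegressors:
    def _mat(self, y):
        n = len(y)
        rng = np.random.default_rng(0)
        return FeatureMatrix(
            ids=pd.DataFrame({"drug_id": ["d"] * n, "cell_line_id": [str(i) for i in range(n)]}),
            features=pd.DataFrame(rng.normal(size=(n, 2)), columns=["a", "b"]),
            gene_cols=[], chem_cols=["a", "b"],
            target=pd.Series(y), mode="regress",
        )

    def test_zero_rule_mean_rmse_is_target_sd(self):
        rng = np.random.default_rng(7)
        y = rng.normal(0, 1, 20000)
        m = dummy_regressor("zero_rule_mean", self._mat(y))
        assert m.rmse == pytest.approx(1.0, abs=0.03)

    def test_median_matches_mean_for_symmetric_targets(self):
        rng = np.random.default_rng(8)
        y = rng.normal(-6, 1, 5000)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = dummy_regressor("zero_rule_mean", self._mat(y)).rmse
            b = dummy_regressor("quantile", self._mat(y), q=0.5).rmse
        assert a == pytest.approx(b, rel=0.01)

    def test_quantile_off_grid_rejected(self):
        with pytest.raises(ValidationError):
            dummy_regressor("quantile", self._mat(np.arange(100.0)), q=0.33)

    def test_unknown_strategy(self):
        with pytest.raises(ValidationError):
            dummy_regressor("magic", self._mat(np.arange(100.0)))
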