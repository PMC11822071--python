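"""Discriminant model: closed-form, simulation, and sklearn cross-checks."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from cogload.features import FEATURE_COLUMNS
from cogload.lda import (
    FeatureMatrix,
    build_matrix,
    fit_preliminary_models,
    lda_fit,
    lda_predict,
    split_train_test,
    standardize,
)


def matrix_from(X, y, columns=None):
    X = np.asarray(X, dtype=float)
    columns = columns or [f"v{i}" for i in range(X.shape[1])]
    ids = pd.DataFrame({"participant_id": ["p"] * len(X), "trial_id": [f"t{i}" for i in range(len(X))]})
    return FeatureMatrix(X=X, y=np.asarray(y), ids=ids, columns=columns)


class TestSplit:
    def test_rounding_and_partition(self, rng):
        m = matrix_from(rng.normal(size=(1452, 3)), np.repeat(["a", "b", "c", "d"], 363))
        train, test = split_train_test(m, 0.8, seed=4)
        assert len(train.y) == 1162 and len(test.y) == 290
        all_ids = set(train.ids["trial_id"]) | set(test.ids["trial_id"])
        assert len(all_ids) == 1452
        assert not (set(train.ids["trial_id"]) & set(test.ids["trial_id"]))

    def test_seeded_and_fraction_validated(self, rng):
        m = matrix_from(rng.normal(size=(50, 2)), ["a"] * 25 + ["b"] * 25)
        a1, _ = split_train_test(m, seed=7)
        a2, _ = split_train_test(m, seed=7)
        assert np.array_equal(a1.X, a2.X)
        with pytest.raises(ValueError):
            split_train_test(m, fraction=1.2)


class TestStandardize:
    def test_train_moments_and_hand_example(self):
        m = matrix_from([[1.0], [2.0], [3.0]], ["a", "a", "b"])
        train_z, _, stats = standardize(m)
        assert train_z.X[:, 0].tolist() == pytest.approx([-1.0, 0.0, 1.0])
        assert abs(train_z.X.mean()) < 1e-12

    def test_test_transformed_with_train_stats(self, rng):
        m = matrix_from(rng.normal(2.0, 3.0, size=(40, 2)), ["a", "b"] * 20)
        train_z, test_z, _ = standardize(m, m)
        assert np.allclose(train_z.X, test_z.X)

    def test_zero_variance_column_named(self):
        m = matrix_from([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]], ["a", "a", "b"], columns=["ok", "flat"])
        with pytest.raises(ValueError, match="flat"):
            standardize(m)


class TestLdaFit:
    def test_symmetric_two_class_boundary_at_zero(self, rng):
        X = np.concatenate([rng.normal(-1, 1, 4000), rng.normal(1, 1, 4000)])[:, None]
        y = np.array(["neg"] * 4000 + ["pos"] * 4000)
        model = lda_fit(matrix_from(X, y))
        pred = lda_predict(model, np.array([[0.0]]))
        assert pred.posteriors[0] == pytest.approx([0.5, 0.5], abs=0.02)
        assert model.axes.shape == (1, 1)
        assert model.trace_proportions.tolist() == [1.0]

    def test_two_class_posterior_matches_closed_form_logistic(self, rng):
        """1-D equal-covariance LDA posterior equals the logistic of the
        linear discriminant computed from the estimated moments."""
        X = np.concatenate([rng.normal(-1, 0.8, 300), rng.normal(1.5, 0.8, 500)])[:, None]
        y = np.array(["a"] * 300 + ["b"] * 500)
        m = matrix_from(X, y)
        model = lda_fit(m)
        grid = np.linspace(-3, 3, 31)[:, None]
        pred = lda_predict(model, grid)
        mu_a, mu_b = model.means[0, 0], model.means[1, 0]
        s2 = model.pooled_cov[0, 0]
        pa, pb = model.priors
        # log odds of class b
        z = (mu_b - mu_a) / s2 * grid[:, 0] - (mu_b**2 - mu_a**2) / (2 * s2) + np.log(pb / pa)
        assert pred.posteriors[:, 1] == pytest.approx(1 / (1 + np.exp(-z)), abs=1e-9)

    def test_row_at_class_mean_assigned_to_it(self, rng):
        X = rng.normal(size=(200, 3)) + np.repeat(np.eye(3)[[0, 1]] * 4, 100, axis=0)
        y = np.array(["a"] * 100 + ["b"] * 100)
        model = lda_fit(matrix_from(X, y))
        pred = lda_predict(model, model.means)
        assert pred.labels.tolist() == ["a", "b"]
        assert np.allclose(pred.posteriors.sum(axis=1), 1.0)

    def test_trace_proportions_and_w_orthogonality(self, rng):
        X = rng.normal(size=(600, 5))
        X[:150, 0] += 3; X[150:300, 1] += 3; X[300:450, 2] += 3
        y = np.repeat(["a", "b", "c", "d"], 150)
        model = lda_fit(matrix_from(X, y))
        assert model.axes.shape == (5, 3)
        tp = model.trace_proportions
        assert tp.sum() == pytest.approx(1.0)
        assert np.all(np.diff(tp) <= 1e-12)
        gram = model.axes.T @ model.pooled_cov @ model.axes
        assert np.allclose(gram, np.eye(3), atol=1e-8)

    def test_predictions_invariant_to_predictor_rescaling(self, rng):
        X = rng.normal(size=(300, 4)) + np.repeat([[0, 0, 0, 0], [2, 0, 1, 0], [0, 2, 0, 1]], 100, axis=0)
        y = np.repeat(["a", "b", "c"], 100)
        scale = np.array([1.0, 100.0, 0.01, 7.0])

        def pipeline(Xs):
            m = matrix_from(Xs, y)
            tr, te = split_train_test(m, 0.8, seed=0)
            tr_z, te_z, _ = standardize(tr, te)
            model = lda_fit(tr_z)
            return lda_predict(model, te_z).labels

        assert np.array_equal(pipeline(X), pipeline(X * scale))

    def test_agreement_with_sklearn_reference(self, rng):
        """Independent cross-check: posteriors and labels match sklearn's
        shared-covariance LDA up to its covariance-denominator convention."""
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        X = rng.normal(size=(800, 4)) + np.repeat(
            [[0, 0, 0, 0], [2.5, 0, 0, 0], [0, 2.5, 0, 0], [0, 0, 2.5, 0]], 200, axis=0
        )
        y = np.repeat(["a", "b", "c", "d"], 200)
        model = lda_fit(matrix_from(X, y))
        pred = lda_predict(model, X)
        ref = LinearDiscriminantAnalysis(solver="svd").fit(X, y)
        agree = (pred.labels == ref.predict(X)).mean()
        assert agree > 0.99
        # posteriors close despite the N vs N-C covariance denominator
        assert np.abs(pred.posteriors - ref.predict_proba(X)).max() < 0.03

    def test_errors_small_class_and_single_class(self):
        with pytest.raises(ValueError):
            lda_fit(matrix_from([[0.0], [1.0]], ["a", "a"]))
        with pytest.raises(ValueError):
            lda_fit(matrix_from([[0.0], [1.0], [2.0]], ["a", "a", "b"]))

    def test_column_mismatch_rejected(self, rng):
        model = lda_fit(matrix_from(rng.normal(size=(40, 2)) + np.repeat([[0, 0], [3, 3]], 20, axis=0), ["a"] * 20 + ["b"] * 20))
        with pytest.raises(ValueError, match="column mismatch"):
            lda_predict(model, np.zeros((1, 5)))


class TestPreliminaryModels:
    def test_perfectly_encoded_task_reaches_accuracy_one(self, rng):
        n = 400
        table = pd.DataFrame(
            {
                "participant_id": ["p"] * n,
                "trial_id": [f"t{i}" for i in range(n)],
                "task": ["mental_calculation"] * (n // 2) + ["visual_search"] * (n // 2),
                "load": ["low", "high"] * (n // 2),
                "group": ["mc_low"] * (n // 2) + ["vs_low"] * (n // 2),
            }
        )
        for c in FEATURE_COLUMNS:
            table[c] = rng.normal(size=n)
        table.loc[table.task == "visual_search", "hrv_s"] += 30.0  # separable marker
        out = fit_preliminary_models(table, seed=0)
        assert out["type"]["accuracy"] == pytest.approx(1.0)
        assert out["type"]["model"].axes.shape[1] == 1
        assert out["type"]["model"].trace_proportions.tolist() == [1.0]
        assert 0.0 <= out["level"]["accuracy"] <= 1.0

    def test_null_table_accuracies_near_larger_prior(self, rng):
        n = 1200
        table = pd.DataFrame(
            {
                "participant_id": ["p"] * n,
                "trial_id": [f"t{i}" for i in range(n)],
                "task": rng.choice(["mental_calculation", "visual_search"], n, p=[0.55, 0.45]),
                "load": rng.choice(["low", "high"], n),
            }
        )
        table["group"] = "mc_low"
        for c in FEATURE_COLUMNS:
            table[c] = rng.normal(size=n)
        out = fit_preliminary_models(table, seed=1)
        for name in ("type", "level"):
            acc = out[name]["accuracy"]
            n_test = out[name]["n_test"]
            prior = 0.55 if name == "type" else 0.5
            assert abs(acc - prior) < 3 * np.sqrt(prior * (1 - prior) / n_test) + 0.03


def test_build_matrix_drops_missing_rows(small_dataset):
    table = small_dataset["table"].copy()
    table.loc[table.index[:5], "hrv_s"] = np.nan
    m = build_matrix(table)
    assert m.n_dropped >= 5
    assert np.isfinite(m.X).all()
    assert list(m.columns) == FEATURE_COLUMNS
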