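"""Learner benchmarking: splitting, CV selection, leakage audit."""

import hashlib

import numpy as np
import pandas as pd
import pytest
from sklearn.preprocessing import StandardScaler

from abpbench import ArtifactClassifier, HyperGrid, SplitSpec, split_data
from abpbench.bench import (
    cv_select,
    derive_seed,
    fit_predict,
    make_estimator,
    split_mask,
)


def separable_data(rng, n=400, n_noise=3, margin=1.0):
    """Linearly separable two-feature problem plus noise columns."""
    x0 = rng.normal(0, 1, n)
    x1 = rng.normal(0, 1, n)
    y = (x0 + x1) > 1.0
    x0 = x0 + np.where(y, margin, -margin)  # widen the margin
    cols = {"x0": x0, "x1": x1}
    for j in range(n_noise):
        cols[f"noise{j}"] = rng.normal(0, 1, n)
    return pd.DataFrame(cols), y


class TestSplit:
    def test_fixed_seed_reproduces_split(self):
        X = pd.DataFrame({"a": np.arange(100.0)})
        y = np.arange(100) % 2 == 0
        a = split_data(X, y, SplitSpec(seed=3))
        b = split_data(X, y, SplitSpec(seed=3))
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[2], b[2])

    def test_test_fraction_is_binomial(self):
        n = 2000
        fracs = [1 - split_mask(n, 0.8, seed).mean() for seed in range(30)]
        sd = np.sqrt(0.2 * 0.8 / n)
        assert abs(np.mean(fracs) - 0.2) < 3 * sd / np.sqrt(30) + 1e-9

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            split_data(pd.DataFrame({"a": []}), np.array([], bool), SplitSpec(seed=0))

    def test_single_class_training_set_rejected(self):
        X = pd.DataFrame({"a": np.arange(50.0)})
        y = np.zeros(50, dtype=bool)
        with pytest.raises(ValueError, match="single class"):
            split_data(X, y, SplitSpec(seed=0))


class TestCvSelect:
    def test_grid_of_one_returns_that_point(self, rng):
        X, y = separable_data(rng)
        grid = HyperGrid("lasso_logistic", [{"lam": 1e-3}])
        sel = cv_select(X, y, grid, seed=0)
        assert sel["params"] == {"lam": 1e-3}

    def test_lasso_solves_separable_data(self, rng):
        X, y = separable_data(rng)
        sel = cv_select(X, y, HyperGrid.small("lasso_logistic"), seed=0)
        assert sel["cv_kappa"] > 0.8

    def test_extreme_regularization_never_beats_the_optimum(self, rng):
        """Pushing lambda far beyond its useful range cannot raise CV kappa."""
        X, y = separable_data(rng)
        best = cv_select(X, y, HyperGrid.small("lasso_logistic"), seed=0)
        huge = cv_select(X, y, HyperGrid("lasso_logistic", [{"lam": 1e3}]), seed=0)
        assert huge["cv_kappa"] <= best["cv_kappa"]
        assert huge["cv_kappa"] == 0.0  # full shrinkage predicts the majority class

    def test_cv_kappa_recomputable_from_fold_predictions(self, rng):
        from abpbench import cohen_kappa, contingency

        X, y = separable_data(rng)
        sel = cv_select(X, y, HyperGrid.small("lasso_logistic"), seed=1)
        recomputed = [
            cohen_kappa(contingency(y[sel["fold_of"] == f], sel["oof_pred"][sel["fold_of"] == f]))
            for f in range(4)
        ]
        assert sel["fold_kappas"] == pytest.approx(recomputed)
        assert sel["cv_kappa"] == pytest.approx(np.mean(recomputed))

    def test_too_few_positives_rejected(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=40)})
        y = np.zeros(40, bool)
        y[:2] = True
        with pytest.raises(ValueError, match="each class"):
            cv_select(X, y, HyperGrid("lasso_logistic", [{"lam": 1e-3}]), seed=0)


class TestFitPredict:
    def test_constant_features_predict_majority(self, rng):
        X = pd.DataFrame({"a": np.ones(100)})
        y = np.zeros(100, bool)
        y[:20] = True
        for family, params in [("lasso_logistic", {"lam": 1e-3}),
                               ("svm_rbf", {"C": 1.0, "sigma": 0.1})]:
            labels, _, _ = fit_predict(family, params, X, y, X, seed=0)
            assert not labels.any()

    def test_nonfinite_features_name_the_column(self, rng):
        X, y = separable_data(rng, n=60)
        X.loc[5, "noise1"] = np.inf
        with pytest.raises(ValueError, match="noise1"):
            fit_predict("lasso_logistic", {"lam": 1e-3}, X, y, X, seed=0)

    def test_svm_separates_offset_artifacts(self, rng):
        """40 mmHg systematic offsets are cleanly separable."""
        n = 300
        y = rng.random(n) < 0.2
        X = pd.DataFrame({"sbp": rng.normal(120, 5, n) + np.where(y, 40.0, 0.0),
                          "dbp": rng.normal(60, 3, n)})
        from abpbench import cohen_kappa, contingency

        labels, _, _ = fit_predict("svm_rbf", {"C": 10.0, "sigma": 0.1}, X, y, X, seed=0)
        assert cohen_kappa(contingency(y, labels)) >= 0.9


class TestArtifactClassifier:
    def test_fit_results_carry_diagnostics_and_summary(self, rng):
        X, y = separable_data(rng, n=500)
        model = ArtifactClassifier(X, y, family="lasso_logistic",
                                   grid=HyperGrid.small("lasso_logistic"))
        res = model.fit(seed=2)
        assert -1.0 <= res.cv_kappa <= 1.0
        assert res.test_stats.kappa > 0.5
        text = res.summary()
        assert "lasso_logistic" in text and "cv kappa" in text
        # predictions on training rows reproduce the fitted pipeline
        assert res.predict(X.iloc[:5]).shape == (5,)

    def test_lasso_recovers_informative_features(self, rng):
        """With many rows, the selected lasso keeps the true signal columns."""
        X, y = separable_data(rng, n=10_000, n_noise=6)
        model = ArtifactClassifier(X, y, family="lasso_logistic",
                                   grid=HyperGrid.small("lasso_logistic"))
        res = model.fit(seed=0)
        coefs = res.estimator.named_steps["clf"].coef_.ravel()
        names = np.array(X.columns)
        nonzero = set(names[np.abs(coefs) > 1e-8])
        assert {"x0", "x1"} <= nonzero

    def test_no_leakage_in_scaler_and_folds(self, rng):
        """Deleting the test rows changes neither the standardization
        statistics nor the CV fold contents (hash check)."""
        X, y = separable_data(rng, n=600)
        model = ArtifactClassifier(X, y, family="lasso_logistic",
                                   grid=HyperGrid.small("lasso_logistic"))
        seed = 5
        res = model.fit(seed=seed)
        mask = res.train_mask
        # recompute from the training rows alone, as if the test set never existed
        Xtr = X.loc[mask].reset_index(drop=True)
        ytr = y[mask]
        scaler = StandardScaler().fit(Xtr.to_numpy(float))
        sel = cv_select(Xtr, ytr, model.grid, seed=seed + 1)

        def digest(*arrays):
            h = hashlib.sha256()
            for a in arrays:
                h.update(np.ascontiguousarray(a).tobytes())
            return h.hexdigest()

        assert digest(res.scaler_mean_, res.scaler_scale_) == \
            digest(scaler.mean_, scaler.scale_)
        assert digest(res.fold_assignments) == digest(sel["fold_of"])
        assert res.params == sel["params"]


def test_derive_seed_is_deterministic_and_bounded():
    assert derive_seed(42, 1, 2) == derive_seed(42, 1, 2)
    assert derive_seed(42, 1, 2) != derive_seed(42, 2, 1)
    assert 0 <= derive_seed(2**30, 999) < 2**31


def test_default_grids_span_stated_ranges():
    lams = [p["lam"] for p in HyperGrid.default("lasso_logistic").points]
    assert min(lams) >= 1e-7 - 1e-12 and max(lams) <= 1.0 + 1e-12
    # the grid brackets the selected penalties a glmnet user would report
    assert min(lams) < 2.78e-6 and max(lams) > 4.64e-4
    mlp = HyperGrid.default("mlp1").points
    assert {p["size"] for p in mlp} == set(range(2, 21))
    assert all(1e-7 - 1e-12 <= p["decay"] <= 10 + 1e-9 for p in mlp)
    svm = HyperGrid.default("svm_rbf").points
    assert all(5e-4 - 1e-12 <= p["C"] <= 1e3 + 1e-6 for p in svm)
    assert all(5e-4 - 1e-12 <= p["sigma"] <= 0.2 + 1e-9 for p in svm)


def test_estimator_families_construct(rng):
    for family, params in [("lasso_logistic", {"lam": 1e-2}),
                           ("mlp1", {"size": 3, "decay": 0.1}),
                           ("svm_rbf", {"C": 1.0, "sigma": 0.01})]:
        est = make_estimator(family, params, n_train=100, seed=0)
        X = rng.normal(size=(50, 3))
        y = rng.random(50) < 0.5
        est.fit(X, y)
        assert est.predict(X).shape == (50,)
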