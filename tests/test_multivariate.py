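import numpy as np
import pytest

from grainfill.multivariate import (
    PLSDA,
    double_cross_validate,
    fit_pca,
    select_markers,
    vip_scores,
)


class TestPCA:
    def test_rank_one_matrix_single_component(self):
        rng = np.random.default_rng(0)
        X = np.outer(rng.normal(size=10), rng.normal(size=6))
        res = fit_pca(X, n_components=3)
        assert res.explained_pct[0] == pytest.approx(100.0, abs=1e-8)

    def test_scores_covariance_diagonal(self):
        rng = np.random.default_rng(1)
        res = fit_pca(rng.normal(size=(30, 8)), n_components=4)
        cov = res.scores.T @ res.scores
        off = cov - np.diag(np.diag(cov))
        assert np.max(np.abs(off)) < 1e-10 * np.max(np.diag(cov))

    def test_explained_matches_eigendecomposition_oracle(self):
        """Brute-force oracle: eigenvalues of the dense covariance matrix."""
        rng = np.random.default_rng(2)
        X = rng.normal(size=(10, 6))
        Xc = X - X.mean(axis=0)
        evals = np.sort(np.linalg.eigvalsh(Xc.T @ Xc))[::-1]
        res = fit_pca(X, n_components=6)
        assert np.allclose(res.explained_pct, 100 * evals / evals.sum(), atol=1e-8)

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(20, 5))
        a, b = fit_pca(X, 3), fit_pca(X, 3)
        assert np.array_equal(a.loadings, b.loadings)
        for j in range(3):
            assert a.loadings[np.abs(a.loadings[:, j]).argmax(), j] > 0


class TestVIP:
    def _fit(self, X, y, ncomp=2):
        return PLSDA(X, y, n_components=ncomp).fit()

    def test_vip_normalization_identity(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(24, 4))
        y = np.repeat(["a", "b", "c"], 8)
        v = self._fit(X, y).vip()
        assert np.sum(v**2) == pytest.approx(4.0, abs=1e-8)

    def test_duplicated_columns_get_equal_vip(self):
        rng = np.random.default_rng(5)
        col = rng.normal(size=24)
        X = np.column_stack([col, col, rng.normal(size=24)])
        y = np.repeat(["a", "b"], 12)
        v = self._fit(X, y).vip()
        assert v[0] == pytest.approx(v[1], rel=1e-10)

    def test_informative_variable_attains_max_vip(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(40, 10))
            y = np.repeat(["a", "b"], 20)
            X[y == "a", 3] += 2.0
            v = self._fit(X, y).vip()
            hits += int(np.argmax(v) == 3)
        assert hits >= 95


class TestPLSDA:
    def test_separable_clouds_zero_training_error(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(30, 5))
        y = np.repeat(["a", "b"], 15)
        X[y == "b"] += 6.0
        fit = PLSDA(X, y, n_components=2).fit()
        assert fit.misclassification(X, y) == 0.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="two classes"):
            PLSDA(np.zeros((6, 3)), np.repeat("a", 6))

    def test_tiny_class_rejected(self):
        with pytest.raises(ValueError, match="at least two samples"):
            PLSDA(np.zeros((5, 3)), np.array(["a", "a", "a", "a", "b"]))

    def test_sample_duplication_leaves_coefficients_unchanged(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(20, 6))
        y = np.repeat(["a", "b"], 10)
        X[y == "a", 0] += 1.5
        c1 = PLSDA(X, y, n_components=2).fit().coef_
        c2 = PLSDA(np.vstack([X, X]), np.concatenate([y, y]), n_components=2).fit().coef_
        assert np.allclose(c1, c2, atol=1e-10)


class TestDoubleCV:
    def test_strong_separation_low_outer_error(self, preprocessed):
        scaled = preprocessed["scaled"]
        cv = double_cross_validate(
            scaled.values, scaled.design["genotype"].to_numpy(),
            task="classification", seed=0,
        )
        assert cv.misclassification <= 0.05
        assert min(cv.auc.values()) >= 0.95

    def test_daf_regression_on_accumulation_dominated_data(self, preprocessed):
        scaled = preprocessed["scaled"]
        cv = double_cross_validate(
            scaled.values, scaled.design["daf"].to_numpy(),
            task="regression", seed=1,
        )
        assert cv.r2 > 0.7
        assert cv.rmsep < 10.0

    def test_null_data_auc_near_chance(self):
        aucs = []
        for seed in range(12):
            rng = np.random.default_rng(100 + seed)
            X = rng.normal(size=(40, 12))
            y = np.repeat(["a", "b"], 20)
            cv = double_cross_validate(
                X, y, task="classification", n_comp_grid=range(1, 4),
                outer_k=4, inner_k=3, seed=seed,
            )
            aucs.append(np.mean(list(cv.auc.values())))
        se = np.std(aucs, ddof=1) / np.sqrt(len(aucs))
        assert abs(np.mean(aucs) - 0.5) < 3 * se + 1e-12

    def test_no_test_sample_in_training_by_construction(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(24, 5))
        y = np.repeat(["a", "b", "c"], 8)
        cv = double_cross_validate(X, y, task="classification",
                                   n_comp_grid=range(1, 3), outer_k=4,
                                   inner_k=3, seed=2)
        # every sample received exactly one outer prediction
        assert len(cv.y_pred) == 24
        assert not any(p is None for p in cv.y_pred)

    def test_excessive_fold_count_rejected(self):
        X = np.zeros((12, 3))
        y = np.repeat(["a", "b", "c"], 4)
        with pytest.raises(ValueError, match="exceeds"):
            double_cross_validate(X, y, outer_k=5, seed=0)


class TestMarkerSelection:
    def _planted(self, seed):
        rng = np.random.default_rng(seed)
        n_per, K = 16, 30
        y = np.repeat(["a", "b", "c"], n_per)
        X = rng.normal(size=(48, K))
        markers = {"a": [0, 1, 2], "b": [10, 11, 12], "c": [20, 21, 22]}
        for cls, idx in markers.items():
            X[np.ix_(y == cls, idx)] += 2.0
        return X, y, markers

    def test_planted_markers_recovered(self):
        X, y, markers = self._planted(0)
        cv = double_cross_validate(X, y, task="classification",
                                   n_comp_grid=range(1, 6), outer_k=4,
                                   inner_k=3, seed=0)
        rep = select_markers(X, y, cv)
        truth = {f"v{j}" for idx in markers.values() for j in idx}
        sel = set(rep.table["variable"])
        tp = len(sel & truth)
        assert tp / max(len(sel), 1) >= 0.8  # precision
        assert tp / len(truth) >= 0.8  # recall

    def test_vip_threshold_monotonicity(self):
        X, y, _ = self._planted(1)
        cv = double_cross_validate(X, y, task="classification",
                                   n_comp_grid=range(1, 6), outer_k=4,
                                   inner_k=3, seed=1)
        sizes = [
            select_markers(X, y, cv, vip_threshold=th).n_markers
            for th in (0.5, 1.0, 1.5, 2.0)
        ]
        assert sizes == sorted(sizes, reverse=True)

    def test_null_data_selects_almost_nothing(self):
        fracs = []
        for seed in range(20):
            rng = np.random.default_rng(200 + seed)
            X = rng.normal(size=(48, 40))
            y = np.repeat(["a", "b", "c"], 16)
            cv = double_cross_validate(X, y, task="classification",
                                       n_comp_grid=range(1, 5), outer_k=4,
                                       inner_k=3, seed=seed)
            fracs.append(select_markers(X, y, cv).n_markers / 40)
        assert np.mean(fracs) <= 0.05

    def test_unvalidated_model_yields_empty_report(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(30, 10))
        y = np.repeat(["a", "b", "c"], 10)
        cv = double_cross_validate(X, y, task="classification",
                                   n_comp_grid=range(1, 3), outer_k=3,
                                   inner_k=2, seed=3)
        rep = select_markers(X, y, cv)
        if not rep.params.get("model_validated", True):
            assert rep.n_markers == 0
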