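"""PCA, Box's M, QDA, LOOCV, confusion rates and canonical plane vs oracles."""

import numpy as np
import pytest
from scipy import linalg, stats

import steatofluor as sf
from steatofluor.discriminant import BoxMResult, ConfusionMatrix
from steatofluor.reference_data import reference_confusion


class TestPCA:
    def test_single_direction_explains_everything(self):
        t = np.linspace(-1, 1, 30)
        X = np.outer(t, [1.0, 2.0, -1.0]) + 5.0
        model = sf.pca_fit(X, n_components=1)
        assert model.explained_variance_fraction[0] == pytest.approx(1.0)

    def test_default_keeps_six_components(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 20))
        model = sf.pca_fit(X)
        assert model.n_components == 6
        assert model.loadings.shape == (6, 20)

    def test_toy_matrix_matches_covariance_eigendecomposition(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(5, 3))
        model = sf.pca_fit(X, n_components=2)
        C = np.cov(X, rowvar=False, ddof=1)
        evals, evecs = np.linalg.eigh(C)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        np.testing.assert_allclose(
            model.explained_variance_fraction, (evals / evals.sum())[:2], rtol=1e-10
        )
        for k in range(2):
            cos = abs(model.loadings[k] @ evecs[:, k])
            assert cos == pytest.approx(1.0, abs=1e-10)

    def test_matches_sklearn(self):
        sk = pytest.importorskip("sklearn.decomposition")
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 8))
        model = sf.pca_fit(X, n_components=4)
        ref = sk.PCA(n_components=4).fit(X)
        np.testing.assert_allclose(
            model.explained_variance_fraction, ref.explained_variance_ratio_, rtol=1e-8
        )
        np.testing.assert_allclose(
            np.abs(model.loadings), np.abs(ref.components_), rtol=1e-6, atol=1e-8
        )

    def test_orthonormal_loadings(self):
        rng = np.random.default_rng(3)
        model = sf.pca_fit(rng.normal(size=(25, 10)), n_components=5)
        np.testing.assert_allclose(model.loadings @ model.loadings.T, np.eye(5), atol=1e-10)

    def test_excess_components_rejected(self):
        with pytest.raises(ValueError):
            sf.pca_fit(np.random.default_rng(0).normal(size=(4, 10)), n_components=6)

    def test_low_variance_warns(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(50, 30))  # isotropic: 2 PCs explain little
        with pytest.warns(UserWarning, match="floor"):
            sf.pca_fit(X, n_components=2, variance_floor=0.90)


class TestBoxM:
    def test_identical_samples_m_zero_recommend_lda(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(30, 3))
        res = sf.covariance_equality_test({"a": x, "b": x.copy(), "c": x.copy()})
        assert res.m_statistic == pytest.approx(0.0, abs=1e-9)
        assert res.recommendation == "LDA"

    def test_type_one_error_near_alpha(self):
        """Under equal covariances the test rejects at about the nominal 5%
        (500 replicates, n_k=100, dim=3)."""
        rng = np.random.default_rng(42)
        reps, rejections = 500, 0
        for _ in range(reps):
            groups = {c: rng.standard_normal((100, 3)) for c in "abc"}
            rejections += sf.covariance_equality_test(groups, alpha=0.05).p_value < 0.05
        rate = rejections / reps
        se = np.sqrt(0.05 * 0.95 / reps)
        assert abs(rate - 0.05) < 3 * se

    def test_unequal_covariances_detected(self):
        rng = np.random.default_rng(1)
        groups = {
            "a": rng.standard_normal((80, 3)),
            "b": rng.standard_normal((80, 3)) * 3.0,
        }
        res = sf.covariance_equality_test(groups)
        assert res.p_value < 1e-6
        assert res.recommendation == "QDA"

    def test_synthetic_pipeline_selects_qda(self, normalized_study):
        normalized, _ = normalized_study
        sub = normalized.subset(excitation_nm=405.0)
        X = np.vstack([s.intensities for s in sub])
        y = np.array([s.group for s in sub])
        scores = sf.pca_fit(X).transform(X)
        res = sf.covariance_equality_test({g: scores[y == g] for g in set(y)})
        assert res.recommendation == "QDA"

    def test_too_small_groups_rejected(self):
        rng = np.random.default_rng(2)
        with pytest.raises(ValueError):
            sf.covariance_equality_test({"a": rng.normal(size=(3, 3)), "b": rng.normal(size=(10, 3))})


class TestQDA:
    def test_single_group_posterior_one(self):
        rng = np.random.default_rng(0)
        model = sf.qda_fit({"only": rng.normal(size=(20, 2))})
        labels, post = sf.qda_predict(model, rng.normal(size=(5, 2)))
        assert all(lab == "only" for lab in labels)
        np.testing.assert_allclose(post, 1.0)

    def test_equal_variance_midpoint_boundary(self):
        # symmetric 1-D classes, equal variance and priors: boundary at the midpoint
        a = np.array([[-2.0], [-1.0], [0.0]]) - 1.0
        b = np.array([[0.0], [1.0], [2.0]]) + 1.0
        model = sf.qda_fit({"a": a, "b": b}, priors="uniform")
        mid = (a.mean() + b.mean()) / 2
        lab_lo, _ = sf.qda_predict(model, [[mid - 1e-6]])
        lab_hi, _ = sf.qda_predict(model, [[mid + 1e-6]])
        assert lab_lo[0] == "a" and lab_hi[0] == "b"

    def test_unequal_variance_boundary_matches_quadratic_roots(self):
        """1-D QDA decision points equal the closed-form roots of the
        equal-discriminant quadratic."""
        rng = np.random.default_rng(5)
        xa = rng.normal(0.0, 1.0, 200)[:, None]
        xb = rng.normal(4.0, 2.5, 150)[:, None]
        model = sf.qda_fit({"a": xa, "b": xb})
        mu1, mu2 = model.means.ravel()
        s1, s2 = model.covariances[:, 0, 0]
        p1, p2 = model.priors
        # d_a(x) = d_b(x): quadratic A x^2 + B x + C = 0
        A = 0.5 * (1 / s2 - 1 / s1)
        B = mu1 / s1 - mu2 / s2
        C = (
            0.5 * (mu2**2 / s2 - mu1**2 / s1)
            + 0.5 * np.log(s2 / s1)
            + np.log(p1 / p2)
        )
        roots = np.roots([A, B, C])
        for r in np.sort(roots.real):
            lo, _ = sf.qda_predict(model, [[r - 1e-8]])
            hi, _ = sf.qda_predict(model, [[r + 1e-8]])
            assert lo[0] != hi[0]  # label flips across each root

    def test_posteriors_match_explicit_bayes_rule(self):
        """Posteriors equal Bayes' rule with explicit Gaussian densities."""
        rng = np.random.default_rng(6)
        groups = {
            "a": rng.multivariate_normal([0, 0, 0], np.eye(3), 40),
            "b": rng.multivariate_normal([2, 1, -1], np.diag([2.0, 0.5, 1.0]), 55),
            "c": rng.multivariate_normal([-1, 3, 1], np.eye(3) * 1.5, 35),
        }
        model = sf.qda_fit(groups)
        X = rng.normal(size=(20, 3))
        _, post = sf.qda_predict(model, X)
        dens = np.column_stack(
            [
                prior * stats.multivariate_normal.pdf(X, mean=mu, cov=cov)
                for prior, mu, cov in zip(model.priors, model.means, model.covariances)
            ]
        )
        expected = dens / dens.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(post, expected, rtol=1e-8)

    def test_posteriors_sum_to_one(self):
        rng = np.random.default_rng(7)
        groups = {c: rng.normal(size=(30, 4)) + i for i, c in enumerate("abc")}
        model = sf.qda_fit(groups)
        _, post = sf.qda_predict(model, rng.normal(size=(50, 4)))
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(post > 0) and np.all(post < 1)

    def test_mean_predicts_own_class(self):
        rng = np.random.default_rng(8)
        groups = {c: rng.normal(size=(30, 2)) + 5 * i for i, c in enumerate("abc")}
        model = sf.qda_fit(groups, priors="uniform")
        labels, _ = sf.qda_predict(model, model.means)
        assert list(labels) == list(model.labels)

    def test_matches_sklearn_qda(self):
        skl = pytest.importorskip("sklearn.discriminant_analysis")
        rng = np.random.default_rng(9)
        X = np.vstack([rng.normal(size=(30, 3)), rng.normal(size=(25, 3)) + 2])
        y = np.array(["a"] * 30 + ["b"] * 25)
        model = sf.qda_fit({"a": X[:30], "b": X[30:]})
        labels, post = sf.qda_predict(model, X)
        ref = skl.QuadraticDiscriminantAnalysis(store_covariance=True).fit(X, y)
        assert list(labels) == list(ref.predict(X))
        np.testing.assert_allclose(post, ref.predict_proba(X), atol=1e-8)

    def test_dimension_mismatch_rejected(self):
        rng = np.random.default_rng(10)
        model = sf.qda_fit({"a": rng.normal(size=(10, 3)), "b": rng.normal(size=(10, 3))})
        with pytest.raises(ValueError):
            sf.qda_predict(model, np.zeros((2, 4)))


class TestLOOCV:
    def test_separable_clusters_perfect(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(size=(15, 2)), rng.normal(size=(15, 2)) + 100.0])
        y = np.array(["a"] * 15 + ["b"] * 15)
        cm = sf.loocv(X, y)
        assert np.trace(cm.counts) == 30
        # and equals the in-sample classification matrix at infinite separation
        model = sf.qda_fit({"a": X[:15], "b": X[15:]})
        np.testing.assert_array_equal(cm.counts, sf.classify(model, X, y).counts)

    def test_matches_manual_refit_loop(self):
        """n=9: identical to an explicit per-observation refit loop."""
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(size=(4, 1)), rng.normal(size=(5, 1)) + 1.5])
        y = np.array(["a"] * 4 + ["b"] * 5)
        cm = sf.loocv(X, y)
        manual = []
        for i in range(9):
            keep = np.ones(9, bool)
            keep[i] = False
            m = sf.qda_fit({lab: X[keep & (y == lab)] for lab in ("a", "b")})
            manual.append(sf.qda_predict(m, X[i : i + 1])[0][0])
        expected = np.zeros((2, 2), int)
        idx = {"a": 0, "b": 1}
        for truth, pred in zip(y, manual):
            expected[idx[truth], idx[pred]] += 1
        np.testing.assert_array_equal(cm.counts, expected)

    def test_scheme_tags(self):
        rng = np.random.default_rng(2)
        X = np.vstack([rng.normal(size=(10, 1)), rng.normal(size=(10, 1)) + 3])
        y = np.array(["a"] * 10 + ["b"] * 10)
        assert sf.loocv(X, y).scheme == "cross-validation"
        model = sf.qda_fit({"a": X[:10], "b": X[10:]})
        assert sf.classify(model, X, y).scheme == "classification"

    def test_too_small_group_rejected(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(8, 3))
        y = np.array(["a"] * 4 + ["b"] * 4)
        with pytest.raises(ValueError):
            sf.loocv(X, y)


class TestConfusionRates:
    def test_published_330_classification_mcc_success(self):
        rates = sf.confusion_rates(reference_confusion(330, "classification"))
        assert round(rates["per_group"]["MCC"]["success_pct"], 1) == 88.6

    def test_published_385_crossval_mcd2w_success(self):
        rates = sf.confusion_rates(reference_confusion(385, "cross-validation"))
        assert round(rates["per_group"]["MCD2w"]["success_pct"], 1) == 96.1

    def test_perfect_diagonal_no_error(self):
        cm = ConfusionMatrix(["a", "b"], np.diag([7, 9]), "classification")
        rates = sf.confusion_rates(cm)
        assert rates["total_error_pct_pooled"] == 0.0
        assert rates["total_error_pct_unweighted"] == 0.0

    def test_both_total_definitions(self):
        # 330 nm classification: pooled 22/373, unweighted mean of group errors
        rates = sf.confusion_rates(reference_confusion(330, "classification"))
        assert rates["total_error_pct_pooled"] == pytest.approx(100 * 22 / 373)
        per = rates["per_group"]
        expected_unweighted = np.mean([per[g]["error_pct"] for g in ("MCC", "MCD2w", "MCD8w")])
        assert rates["total_error_pct_unweighted"] == pytest.approx(expected_unweighted)

    def test_zero_row_rejected(self):
        cm = ConfusionMatrix(["a", "b"], np.array([[3, 1], [0, 0]]), "classification")
        with pytest.raises(ValueError):
            sf.confusion_rates(cm)


class TestCanonicalPlane:
    @staticmethod
    def _three_groups(seed=0, d=3, n=40):
        rng = np.random.default_rng(seed)
        centers = np.array([[0, 0, 0], [4, 0, 1], [0, 4, -1]], dtype=float)[:, :d]
        X = np.vstack([rng.normal(size=(n, d)) + c for c in centers])
        y = np.array(sum([[lab] * n for lab in ("a", "b", "c")], []))
        return X, y

    def test_three_groups_two_axes(self):
        X, y = self._three_groups()
        plane = sf.canonical_plane(X, y, grid_resolution=20)
        assert plane.axes.shape[1] == 2
        assert plane.scores.shape == (len(y), 2)
        assert plane.centroids.shape == (3, 2)

    def test_eigenvalues_match_direct_generalized_eigenproblem(self):
        X, y = self._three_groups(seed=1)
        plane = sf.canonical_plane(X, y, grid_resolution=10)
        # independent oracle: eig of W^-1 B by direct inversion
        grand = X.mean(axis=0)
        W = np.zeros((3, 3))
        B = np.zeros((3, 3))
        for lab in ("a", "b", "c"):
            Xi = X[y == lab]
            mu = Xi.mean(axis=0)
            W += (Xi - mu).T @ (Xi - mu)
            B += len(Xi) * np.outer(mu - grand, mu - grand)
        evals = np.sort(np.real(linalg.eig(np.linalg.inv(W) @ B)[0]))[::-1]
        np.testing.assert_allclose(plane.eigenvalues, evals[:2], rtol=1e-8, atol=1e-10)

    def test_unit_pooled_within_class_variance(self):
        X, y = self._three_groups(seed=2)
        plane = sf.canonical_plane(X, y, grid_resolution=10)
        n, k = len(y), 3
        for j in range(2):
            pooled = sum(
                ((plane.scores[y == lab, j] - plane.scores[y == lab, j].mean()) ** 2).sum()
                for lab in ("a", "b", "c")
            ) / (n - k)
            assert pooled == pytest.approx(1.0, rel=1e-8)

    def test_merged_groups_second_axis_degenerate(self):
        X, y = self._three_groups(seed=3)
        y2 = np.where(y == "c", "b", y)  # two labels: between-scatter rank 1
        plane = sf.canonical_plane(X, y2, grid_resolution=10)
        assert plane.eigenvalues[1] == pytest.approx(0.0, abs=1e-10)

    def test_raster_covers_grid_and_labels(self):
        X, y = self._three_groups(seed=4)
        plane = sf.canonical_plane(X, y, grid_resolution=25)
        assert plane.raster.shape == (25, 25)
        assert set(np.unique(plane.raster)).issubset({0, 1, 2})
        # well-separated groups: all three regions appear
        assert len(np.unique(plane.raster)) == 3


class TestParameterRecovery:
    """Cross-validated performance on the synthetic study: high success with
    stage-separated profiles, chance with exchangeable groups."""

    def test_stage_separated_profiles_high_cv_success(self, normalized_study):
        normalized, _ = normalized_study
        sub = normalized.subset(excitation_nm=405.0)
        X = np.vstack([s.intensities for s in sub])
        y = np.array([s.group for s in sub])
        scores = sf.pca_fit(X).transform(X)
        rates = sf.confusion_rates(sf.loocv(scores, y))
        assert rates["total_success_pct_pooled"] > 90.0

    def test_identical_profiles_fall_to_chance(self, instrument):
        import dataclasses

        from steatofluor import preprocess as pp
        from steatofluor.spectra import SpectrumCollection

        base = sf.default_profiles()["MCC"]
        profiles = {
            g: dataclasses.replace(base, group=g, subject_cv=0.0)
            for g in ("MCC", "MCD2w", "MCD8w")
        }
        design = sf.StudyDesign(
            subjects={g: 5 for g in profiles},
            spectra_counts={"MCC": {405.0: 145}, "MCD2w": {405.0: 131}, "MCD8w": {405.0: 125}},
            excitations=(405.0,),
        )
        spectra, _ = sf.simulate_study(design, profiles=profiles, seed=2)
        normalized = SpectrumCollection(
            [pp.normalize_at(s, 600.0) for s in pp.preprocess_collection(spectra, instrument, normalize_nm=None)]
        )
        X = np.vstack([s.intensities for s in normalized])
        y = np.array([s.group for s in normalized])
        scores = sf.pca_fit(X).transform(X)
        rates = sf.confusion_rates(sf.loocv(scores, y))
        ns = np.array([145, 131, 125])
        chance = 100.0 * np.sum((ns / ns.sum()) ** 2)  # ~33.5% with empirical priors
        assert abs(rates["total_success_pct_pooled"] - chance) < 10.0
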