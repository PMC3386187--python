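"""Correlation PCA, contribution rates, sign orientation, F1 discriminant."""

import numpy as np
import pytest

from ilpci.glcm import TEXTURE_FEATURE_NAMES
from ilpci.pca import (
    FeatureMatrix,
    orient_signs,
    pca_fit,
    scores,
    select_components,
    sign_discriminate,
    stage_monotonicity,
    standardize,
)

from ._reference import eig_sym3_brute_force


def random_features(rng, n=50, p=9):
    names = TEXTURE_FEATURE_NAMES[:p]
    base = rng.standard_normal((n, 3))
    mix = rng.standard_normal((3, p))
    values = base @ mix + 0.3 * rng.standard_normal((n, p))
    return FeatureMatrix(values=values, feature_names=names)


class TestStandardize:
    def test_zero_mean_unit_sd(self, rng):
        X, _ = standardize(random_features(rng))
        np.testing.assert_allclose(X.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(X.std(axis=0, ddof=1), 1.0, atol=1e-12)

    def test_constant_column_dropped_with_name(self, rng, caplog):
        fm = random_features(rng)
        fm.values[:, 2] = 7.0  # 'idm'
        with caplog.at_level("WARNING"):
            X, params = standardize(fm)
        assert X.shape[1] == 8
        assert "idm" in caplog.text
        assert params.dropped_names == ("idm",)

    def test_params_round_trip(self, rng):
        fm = random_features(rng)
        X, params = standardize(fm)
        np.testing.assert_allclose(params.apply(fm.values), X, atol=1e-14)

    def test_all_constant_rejected(self):
        fm = FeatureMatrix(values=np.ones((5, 9)))
        with pytest.raises(ValueError, match="constant"):
            standardize(fm)


class TestPcaFit:
    def test_duplicated_feature_gives_full_first_cr(self, rng):
        x = rng.standard_normal(40)
        fm = FeatureMatrix(values=np.stack([x, x], axis=1), feature_names=("a", "b"))
        X, params = standardize(fm)
        model = pca_fit(X, params, ("a", "b"))
        np.testing.assert_allclose(model.eigenvalues, [2.0, 0.0], atol=1e-10)
        assert model.contribution_rates[0] == pytest.approx(1.0, abs=1e-12)

    def test_independent_columns_near_uniform_cr(self):
        rng = np.random.default_rng(99)
        names = tuple("f%d" % i for i in range(9))
        fm = FeatureMatrix(values=rng.standard_normal((10_000, 9)), feature_names=names)
        X, params = standardize(fm)
        model = pca_fit(X, params, names)
        assert np.abs(model.contribution_rates - 1 / 9).max() < 0.02

    def test_contribution_rates_sum_to_one(self, rng):
        X, params = standardize(random_features(rng))
        model = pca_fit(X, params)
        assert model.contribution_rates.sum() == pytest.approx(1.0, abs=1e-12)

    def test_eigenvectors_orthonormal(self, rng):
        X, params = standardize(random_features(rng))
        model = pca_fit(X, params)
        V = model.eigenvectors
        np.testing.assert_allclose(V.T @ V, np.eye(V.shape[1]), atol=1e-10)

    def test_matches_characteristic_polynomial_oracle(self, rng):
        """3x3 correlation-matrix eigendecomposition vs. a root-finding
        reference that never calls numpy.linalg.eigh."""
        for _ in range(20):
            X = rng.standard_normal((60, 3))
            X = (X - X.mean(0)) / X.std(0, ddof=1)
            corr = X.T @ X / (len(X) - 1)
            fm = FeatureMatrix(values=X, feature_names=("a", "b", "c"))
            Xs, params = standardize(fm)
            model = pca_fit(Xs, params, ("a", "b", "c"))
            vals_ref, vecs_ref = eig_sym3_brute_force(corr)
            np.testing.assert_allclose(model.eigenvalues, vals_ref, atol=1e-8)
            for i in range(3):
                dot = abs(np.dot(model.eigenvectors[:, i], vecs_ref[:, i]))
                assert dot == pytest.approx(1.0, abs=1e-6)

    def test_matches_sklearn_explained_variance(self, rng):
        from sklearn.decomposition import PCA

        fm = random_features(rng)
        X, params = standardize(fm)
        model = pca_fit(X, params)
        sk = PCA().fit(X)
        np.testing.assert_allclose(model.eigenvalues, sk.explained_variance_, atol=1e-8)


class TestScores:
    def test_variance_equals_eigenvalue(self, rng):
        X, params = standardize(random_features(rng, n=200))
        model = pca_fit(X, params)
        F = scores(model, X).scores
        np.testing.assert_allclose(F.var(axis=0, ddof=1), model.eigenvalues, atol=1e-8)

    def test_scores_uncorrelated(self, rng):
        X, params = standardize(random_features(rng, n=100))
        model = pca_fit(X, params)
        F = scores(model, X).scores
        cov = np.cov(F, rowvar=False)
        off = cov - np.diag(np.diag(cov))
        assert np.abs(off).max() < 1e-8

    def test_duplicated_rows_share_scores(self, rng):
        fm = random_features(rng, n=30)
        fm.values[1] = fm.values[0]
        X, params = standardize(fm)
        model = pca_fit(X, params)
        F = scores(model, X).scores
        np.testing.assert_allclose(F[0], F[1], atol=1e-12)

    def test_column_mismatch_rejected(self, rng):
        X, params = standardize(random_features(rng))
        model = pca_fit(X, params)
        with pytest.raises(ValueError):
            scores(model, X[:, :5])


class TestOrientSigns:
    def _two_group_table(self, rng, shift=3.0):
        n = 40
        labels = np.array(["normal"] * (n // 2) + ["tumor"] * (n // 2))
        values = rng.standard_normal((n, 4))
        values[labels == "normal", 0] -= shift  # make raw F1 mean negative for normal
        fm = FeatureMatrix(values=values, feature_names=("a", "b", "c", "d"),
                           region_labels=labels)
        X, params = standardize(fm)
        model = pca_fit(X, params, fm.feature_names)
        return model, scores(model, X, region_labels=labels)

    def test_flip_makes_reference_mean_positive(self, rng):
        model, table = self._two_group_table(rng)
        model2, table2 = orient_signs(model, table)
        ref = table2.scores[table2.region_labels == "normal", 0]
        assert ref.mean() >= 0
        np.testing.assert_allclose(np.abs(table2.scores), np.abs(table.scores), atol=1e-12)
        np.testing.assert_allclose(model2.eigenvalues, model.eigenvalues)

    def test_identity_when_already_positive(self, rng):
        model, table = self._two_group_table(rng)
        _, oriented = orient_signs(model, table)
        model3, again = orient_signs(model, oriented)
        np.testing.assert_array_equal(again.scores, oriented.scores)

    def test_absent_reference_group_rejected(self, rng):
        model, table = self._two_group_table(rng)
        with pytest.raises(ValueError, match="reference"):
            orient_signs(model, table, reference_label="vessel")


class TestSelectComponents:
    def test_dominant_first_component(self):
        model = _stub_model([0.9157, 0.04, 0.02, 0.0243])
        assert select_components(model, 0.80) == [0]

    def test_cumulative_rule(self):
        model = _stub_model([0.5, 0.4, 0.1])
        assert select_components(model, 0.80) == [0, 1]

    def test_threshold_one_keeps_all(self):
        model = _stub_model([0.5, 0.3, 0.2])
        assert select_components(model, 1.0) == [0, 1, 2]


def _stub_model(crs):
    from ilpci.pca import PCAModel, Standardization

    crs = np.asarray(crs, dtype=float)
    p = len(crs)
    return PCAModel(
        eigenvalues=crs * p,
        eigenvectors=np.eye(p),
        contribution_rates=crs,
        standardization=Standardization(np.zeros(p), np.ones(p), np.arange(p), ()),
        feature_names=tuple("f%d" % i for i in range(p)),
    )


class TestSignDiscriminate:
    def test_separated_toy_fully_agrees(self):
        from ilpci.pca import ScoreTable

        table = ScoreTable(
            scores=np.array([[1.4], [0.9], [-1.6], [-2.0]]),
            region_labels=np.array(["normal", "normal", "tumor", "tumor"]),
        )
        rep = sign_discriminate(table, cr1=0.9)
        assert rep.agreement == 1.0
        assert rep.group_mean_sd["normal"][0] > 0 > rep.group_mean_sd["tumor"][0]

    def test_zero_score_ties_to_normal(self):
        from ilpci.pca import ScoreTable

        table = ScoreTable(scores=np.array([[0.0]]), region_labels=np.array(["normal"]))
        rep = sign_discriminate(table)
        assert rep.predicted[0] == "normal"
        assert rep.n_ties == 1


class TestStageMonotonicity:
    def test_strictly_increasing(self):
        assert stage_monotonicity([1, 2, 3, 4]) == 1.0

    def test_strictly_decreasing(self):
        assert stage_monotonicity([4, 3, 2, 1]) == -1.0

    def test_dict_input_sorted_by_day(self):
        assert stage_monotonicity({"15d": 4.0, "6d": 1.0, "12d": 3.0, "9d": 2.0}) == 1.0

    def test_non_monotone_below_one(self):
        assert stage_monotonicity([1, 3, 2, 4]) < 1.0

    def test_needs_three_stages(self):
        with pytest.raises(ValueError):
            stage_monotonicity([1, 2])
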