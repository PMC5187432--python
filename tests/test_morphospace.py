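"""PCA morphospace: oracle agreement, projection algebra, ellipses."""

import numpy as np
import pandas as pd
import pytest

from leafmorph.errors import DataError
from leafmorph.morphospace import (
    centroid_distances,
    fit_pca,
    group_ellipse,
    project,
)


def random_table(n=253, p=4, seed=0, names=None):
    rng = np.random.default_rng(seed)
    names = names or [f"v{i}" for i in range(p)]
    cov = rng.uniform(-0.5, 0.5, (p, p))
    cov = cov @ cov.T + np.eye(p)
    data = rng.multivariate_normal(rng.uniform(-2, 2, p), cov, size=n)
    table = pd.DataFrame(data, columns=names)
    table["taxon_id"] = [f"t{i}" for i in range(n)]
    return table


class TestFitPCA:
    def test_collinear_data_loads_on_single_axis(self):
        t = pd.DataFrame({"a": np.arange(10.0)})
        t["b"] = 3.0 * t["a"] - 1.0
        t["taxon_id"] = list("abcdefghij")
        model = fit_pca(t, ["a", "b"])
        assert model.explained_fraction[0] == pytest.approx(1.0,
                                                            abs=1e-10)

    def test_orthonormal_loadings_and_full_reconstruction(self):
        t = random_table(seed=1)
        model = fit_pca(t, ["v0", "v1", "v2", "v3"])
        gram = model.loadings.T @ model.loadings
        np.testing.assert_allclose(gram, np.eye(4), atol=1e-10)
        z = ((t[["v0", "v1", "v2", "v3"]].to_numpy() - model.center)
             / model.scale)
        np.testing.assert_allclose(model.scores @ model.loadings.T, z,
                                   atol=1e-10)

    def test_eigenvalues_match_bruteforce_correlation_eigh(self):
        t = random_table(seed=2)
        model = fit_pca(t, ["v0", "v1", "v2", "v3"])
        corr = np.corrcoef(t[["v0", "v1", "v2", "v3"]].to_numpy(),
                           rowvar=False)
        brute = np.sort(np.linalg.eigvalsh(corr))[::-1]
        np.testing.assert_allclose(model.eigenvalues, brute, atol=1e-8)
        assert model.eigenvalues.sum() == pytest.approx(4.0, abs=1e-10)

    def test_agrees_with_sklearn(self):
        from sklearn.decomposition import PCA
        t = random_table(seed=3)
        x = t[["v0", "v1", "v2", "v3"]].to_numpy()
        z = (x - x.mean(0)) / x.std(0, ddof=1)
        ref = PCA(n_components=4).fit(z)
        model = fit_pca(t, ["v0", "v1", "v2", "v3"])
        np.testing.assert_allclose(
            model.eigenvalues, ref.explained_variance_, atol=1e-8)
        for j in range(4):
            dot = abs(ref.components_[j] @ model.loadings[:, j])
            assert dot == pytest.approx(1.0, abs=1e-8)

    def test_invariance_to_variable_order_and_rescaling(self):
        t = random_table(seed=4)
        base = fit_pca(t, ["v0", "v1", "v2", "v3"])
        reordered = fit_pca(t, ["v3", "v1", "v0", "v2"])
        np.testing.assert_allclose(base.eigenvalues,
                                   reordered.eigenvalues, atol=1e-10)
        scaled = t.copy()
        scaled["v1"] = scaled["v1"] * 37.0 + 4.0  # correlation PCA
        again = fit_pca(scaled, ["v0", "v1", "v2", "v3"])
        np.testing.assert_allclose(base.eigenvalues, again.eigenvalues,
                                   atol=1e-10)
        np.testing.assert_allclose(base.scores, again.scores, atol=1e-8)

    def test_constant_variable_named_in_error(self):
        t = random_table(seed=5)
        t["v2"] = 1.0
        with pytest.raises(DataError, match="v2"):
            fit_pca(t, ["v0", "v1", "v2", "v3"])

    def test_missing_values_refused_not_imputed(self):
        t = random_table(seed=6)
        t.loc[5, "v1"] = np.nan
        with pytest.raises(DataError, match="v1"):
            fit_pca(t, ["v0", "v1", "v2", "v3"])


class TestProject:
    def test_training_row_projects_to_stored_score(self):
        t = random_table(seed=7)
        model = fit_pca(t, ["v0", "v1", "v2", "v3"])
        row = t.iloc[17]
        np.testing.assert_allclose(project(model, row), model.scores[17],
                                   atol=1e-12)

    def test_variable_means_project_to_origin(self):
        t = random_table(seed=8)
        model = fit_pca(t, ["v0", "v1", "v2", "v3"])
        query = dict(zip(model.variable_names, model.center))
        np.testing.assert_allclose(project(model, query), 0.0, atol=1e-12)

    def test_one_sd_perturbation_shifts_by_loading_vector(self):
        t = random_table(seed=9)
        model = fit_pca(t, ["v0", "v1", "v2", "v3"])
        query = dict(zip(model.variable_names, model.center))
        for j, name in enumerate(model.variable_names):
            bumped = dict(query)
            bumped[name] += model.scale[j]
            np.testing.assert_allclose(project(model, bumped),
                                       model.loadings[j], atol=1e-12)

    def test_missing_variable_listed(self):
        t = random_table(seed=10)
        model = fit_pca(t, ["v0", "v1", "v2", "v3"])
        with pytest.raises(DataError, match="v3"):
            project(model, {"v0": 1.0, "v1": 2.0, "v2": 3.0})


class TestGroupEllipse:
    def test_isotropic_group_has_round_ellipse(self):
        rng = np.random.default_rng(11)
        t = pd.DataFrame(rng.standard_normal((2000, 2)),
                         columns=["a", "b"])
        t["taxon_id"] = [str(i) for i in range(2000)]
        model = fit_pca(t, ["a", "b"])
        ell = group_ellipse(model, ["g"] * 2000)["g"]
        ratio = ell.semi_axes[0] / ell.semi_axes[1]
        assert ratio == pytest.approx(1.0, abs=0.1)

    def test_translation_equivariance(self):
        t = random_table(seed=12, n=200)
        model = fit_pca(t, ["v0", "v1", "v2", "v3"])
        ell = group_ellipse(model, ["g"] * 200)["g"]
        shifted = model
        shifted.scores = model.scores + np.array([2.0, -1.0, 0, 0])
        ell2 = group_ellipse(shifted, ["g"] * 200)["g"]
        np.testing.assert_allclose(ell2.center,
                                   ell.center + [2.0, -1.0], atol=1e-10)
        np.testing.assert_allclose(ell2.semi_axes, ell.semi_axes,
                                   atol=1e-10)

    def test_empirical_coverage_at_95(self):
        rng = np.random.default_rng(13)
        t = pd.DataFrame(
            rng.multivariate_normal([0, 0], [[2.0, 0.7], [0.7, 1.0]],
                                    size=5000), columns=["a", "b"])
        t["taxon_id"] = [str(i) for i in range(5000)]
        model = fit_pca(t, ["a", "b"])
        ell = group_ellipse(model, ["g"] * 5000, level=0.95)["g"]
        coverage = np.mean([ell.contains(p) for p in model.scores[:, :2]])
        assert coverage == pytest.approx(0.95, abs=0.02)

    def test_small_group_rejected(self):
        t = random_table(seed=14, n=10)
        model = fit_pca(t, ["v0", "v1", "v2", "v3"])
        with pytest.raises(DataError):
            group_ellipse(model, ["g"] * 8 + ["h"] * 2)

    def test_degenerate_group_flagged_not_fatal(self):
        t = pd.DataFrame({"a": np.arange(12.0)})
        t["b"] = 2.0 * t["a"]
        t["taxon_id"] = [str(i) for i in range(12)]
        model = fit_pca(t, ["a", "b"])  # all scores on PC1
        ell = group_ellipse(model, ["g"] * 12)["g"]
        assert ell.degenerate


class TestCentroidDistances:
    def test_query_at_centroid_has_zero_distance(self):
        t = random_table(seed=15, n=60)
        model = fit_pca(t, ["v0", "v1", "v2", "v3"])
        labels = ["g"] * 30 + ["h"] * 30
        centroid = model.scores[:30, :2].mean(axis=0)
        result = centroid_distances(model, centroid, labels)
        assert result["distances"]["g"] == pytest.approx(0.0, abs=1e-12)
        assert result["nearest"] == "g"

    def test_equidistant_query_reports_tie(self):
        t = random_table(seed=16, n=40)
        model = fit_pca(t, ["v0", "v1", "v2", "v3"])
        labels = np.array(["g"] * 20 + ["h"] * 20)
        c1 = model.scores[:20, :2].mean(axis=0)
        c2 = model.scores[20:, :2].mean(axis=0)
        midpoint = 0.5 * (c1 + c2)
        result = centroid_distances(model, midpoint, labels)
        assert result["tie"] is True
        assert result["nearest"] is None

    def test_inside_flag_consistent_with_ellipse(self):
        t = random_table(seed=17, n=300)
        model = fit_pca(t, ["v0", "v1", "v2", "v3"])
        labels = ["g"] * 300
        ell = group_ellipse(model, labels)
        result = centroid_distances(model, ell["g"].center, labels,
                                    ellipses=ell)
        assert result["inside"]["g"] is True
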