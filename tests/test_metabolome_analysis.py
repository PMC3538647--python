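"""Fold changes, pareto scaling, PCA and strain grouping."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from purineflux import metabolome_analysis as ma


@pytest.fixture(scope="module")
def strain_matrix():
    return ma.strain_mean_matrix()


@pytest.fixture(scope="module")
def pca_result(strain_matrix):
    return ma.run_pca(ma.pareto_scale(strain_matrix))


class TestChanges:
    def test_identity(self):
        assert ma.fold_change(3.3, 3.3) == pytest.approx(1.0)
        assert ma.percent_change(3.3, 3.3) == pytest.approx(0.0)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            ma.fold_change(1.0, 0.0)
        with pytest.raises(ValueError):
            ma.percent_change(1.0, 0.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        sample=st.floats(0.01, 1e3),
        ref=st.floats(0.01, 1e3),
        scale=st.floats(0.01, 1e3),
    )
    def test_scale_invariance(self, sample, ref, scale):
        assert ma.fold_change(sample * scale, ref * scale) == pytest.approx(
            ma.fold_change(sample, ref)
        )
        assert ma.percent_change(sample * scale, ref * scale) == pytest.approx(
            ma.percent_change(sample, ref), abs=1e-8
        )

    def test_rounding_modes(self):
        assert ma.fold_change(44.7, 1.0, "integer") == 45
        assert ma.fold_change(288.0, 1.0, "nearest10") == 290
        assert ma.percent_change(1.806, 1.0, "nearest5") == 80


class TestParetoScaling:
    def test_two_point_column_hand_computed(self):
        # mean 2, sample SD sqrt(2); scaled values -1/2^(3/4), +1/2^(3/4)
        df = pd.DataFrame({"m": [1.0, 3.0]})
        scaled = ma.pareto_scale(df)
        expected = 1.0 / np.sqrt(np.sqrt(2.0))
        np.testing.assert_allclose(scaled["m"], [-expected, expected])

    def test_constant_column_dropped_with_warning(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
        with pytest.warns(UserWarning, match="zero-variance"):
            scaled = ma.pareto_scale(df)
        assert list(scaled.columns) == ["a"]

    def test_scaled_columns_have_zero_mean(self, strain_matrix):
        scaled = ma.pareto_scale(strain_matrix)
        np.testing.assert_allclose(scaled.mean(axis=0), 0.0, atol=1e-12)

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            ma.pareto_scale(pd.DataFrame({"a": [1.0]}))


class TestStrainMatrix:
    def test_phase2_values_used_for_single_deletion_strains(self, strain_matrix):
        assert strain_matrix.loc["DpurA", "IMP"] == pytest.approx(43.99)
        assert strain_matrix.loc["DguaB2", "hypoxanthine"] == pytest.approx(16.19)

    def test_below_detection_is_zero_and_nd_dropped(self, strain_matrix):
        assert strain_matrix.loc["DpurA_DguaB2", "adenine"] == 0.0
        assert "xanthine" not in strain_matrix.columns
        assert "XMP" not in strain_matrix.columns

    def test_seven_strains(self, strain_matrix):
        assert len(strain_matrix) == 7


class TestPca:
    def test_loadings_orthonormal(self, pca_result):
        L = pca_result.loadings.to_numpy()
        np.testing.assert_allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-10)

    def test_explained_variance_sums_to_one(self, pca_result):
        assert pca_result.explained_variance.sum() == pytest.approx(1.0)

    def test_reconstruction_identity(self, strain_matrix):
        scaled = ma.pareto_scale(strain_matrix)
        pca = ma.run_pca(scaled)
        recon = pca.scores.to_numpy() @ pca.loadings.to_numpy().T
        centered = scaled.to_numpy() - scaled.to_numpy().mean(axis=0)
        np.testing.assert_allclose(recon, centered, atol=1e-8)

    def test_equal_variance_orthogonal_variables_split_evenly(self):
        df = pd.DataFrame({"x": [1.0, -1.0, 1.0, -1.0], "y": [1.0, 1.0, -1.0, -1.0]})
        pca = ma.run_pca(df)
        np.testing.assert_allclose(pca.explained_variance, [0.5, 0.5])

    def test_matches_sklearn(self, strain_matrix):
        from sklearn.decomposition import PCA

        scaled = ma.pareto_scale(strain_matrix)
        ours = ma.run_pca(scaled, 2)
        sk = PCA(n_components=2).fit(scaled.to_numpy())
        np.testing.assert_allclose(
            ours.explained_variance, sk.explained_variance_ratio_, atol=1e-10
        )
        for j in range(2):
            np.testing.assert_allclose(
                np.abs(ours.loadings.to_numpy()[:, j]), np.abs(sk.components_[j]),
                atol=1e-8,
            )

    def test_first_two_components_dominate(self, pca_result):
        assert pca_result.explained_percent[:2].sum() > 90.0

    def test_loadings_point_at_imp_and_hypoxanthine(self, pca_result):
        drivers = set(
            pca_result.loadings[["PC1", "PC2"]].abs().max(axis=1).nlargest(3).index
        )
        assert "hypoxanthine" in drivers
        assert "IMP" in drivers


class TestGrouping:
    def test_reference_strains_split_three_vs_four(self, pca_result):
        groups = ma.cluster_groups(pca_result.scores)
        assert set(groups[groups == "A"].index) == {"ATCC13032", "Dpgi", "purF_K348Q"}
        assert (groups == "B").sum() == 4

    def test_row_permutation_invariant(self, strain_matrix):
        perm = strain_matrix.sample(frac=1.0, random_state=4)
        pca = ma.run_pca(ma.pareto_scale(perm))
        groups = ma.cluster_groups(pca.scores, reference="ATCC13032")
        assert set(groups[groups == "A"].index) == {"ATCC13032", "Dpgi", "purF_K348Q"}

    def test_identical_rows_single_group(self):
        scores = pd.DataFrame({"PC1": [0.0, 0.0, 0.0], "PC2": [1.0, 1.0, 1.0]},
                              index=list("abc"))
        assert set(ma.cluster_groups(scores)) == {"A"}


class TestConfidenceEllipse:
    def test_isotropic_cloud_gives_symmetric_ellipse(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(0.0, 1.0, size=(2000, 2))
        center, width, height, _ = ma.confidence_ellipse(pts, level=0.95)
        np.testing.assert_allclose(center, [0, 0], atol=0.1)
        # both axes ~ 2*sqrt(chi2_0.95(2)) = 4.90 for unit variance
        assert width == pytest.approx(4.90, rel=0.1)
        assert height == pytest.approx(4.90, rel=0.1)

    def test_covers_about_95_percent(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(0.0, 1.0, size=(4000, 2))
        _, width, height, _ = ma.confidence_ellipse(pts, level=0.95)
        inside = ((pts[:, 0] / (width / 2)) ** 2 + (pts[:, 1] / (height / 2)) ** 2) <= 1
        assert inside.mean() == pytest.approx(0.95, abs=0.02)


class TestReportedChanges:
    """Every printed fold/percent statement from the bundled pool table."""

    def test_fold_and_percent_statements(self, strain_matrix):
        wt = strain_matrix.loc["ATCC13032"]
        assert ma.fold_change(strain_matrix.loc["DpurA_DguaB2", "IMP"], wt["IMP"],
                              "integer") == 45
        assert ma.fold_change(strain_matrix.loc["DpurA", "IMP"], wt["IMP"],
                              "integer") == 90
        assert ma.fold_change(strain_matrix.loc["DpurA_DguaB2", "hypoxanthine"],
                              wt["hypoxanthine"], "nearest10") == 290
        assert ma.fold_change(strain_matrix.loc["purF_K348Q", "inosine"],
                              wt["inosine"], "tenth") == 2.9
        assert ma.fold_change(strain_matrix.loc["DpurA_DguaB2", "inosine"],
                              wt["inosine"], "tenth") == 9.7
        assert ma.percent_change(strain_matrix.loc["purF_K348Q", "GMP"],
                                 wt["GMP"], "nearest5") == 80
        assert ma.percent_change(strain_matrix.loc["purF_K348Q", "guanine"],
                                 wt["guanine"], "nearest5") == 55
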