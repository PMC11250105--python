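"""Co-expression networks: bicor, adjacency, TOM, modules, eigengenes."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from isletpheno.network import (CoexpressionNetwork, bicor_matrix,
                                detect_modules, module_eigengenes,
                                module_trait_partial_correlation,
                                signed_adjacency, topological_overlap)


def fmat(X):
    X = np.asarray(X, float)
    return pd.DataFrame(X, index=[f"f{i}" for i in range(X.shape[0])],
                        columns=[f"d{j}" for j in range(X.shape[1])])


class TestBicor:
    def test_self_and_negated(self, rng):
        x = rng.normal(size=30)
        C = bicor_matrix(np.vstack([x, x, -x]))
        assert C[0, 1] == pytest.approx(1.0, abs=1e-12)
        assert C[0, 2] == pytest.approx(-1.0, abs=1e-12)

    def test_outlier_robustness_vs_pearson(self, rng):
        x = rng.normal(size=50)
        y = 0.9 * x + 0.2 * rng.normal(size=50)
        clean = np.corrcoef(x, y)[0, 1]
        y_out = y.copy()
        y_out[0] = 40.0  # one gross outlier
        contaminated = np.corrcoef(x, y_out)[0, 1]
        robust = bicor_matrix(np.vstack([x, y_out]))[0, 1]
        assert abs(robust - clean) < abs(contaminated - clean)

    def test_mad_zero_falls_back_to_pearson(self, rng):
        x = rng.normal(size=21)
        const_mad = np.zeros(21)
        const_mad[:2] = [5.0, -5.0]  # median 0, MAD 0, but variance > 0
        C = bicor_matrix(np.vstack([x, const_mad]))
        assert np.isfinite(C[0, 1])

    def test_needs_four_donors(self):
        with pytest.raises(ValueError):
            bicor_matrix(np.ones((3, 3)))


class TestAdjacency:
    def test_extremes_and_arithmetic(self):
        C = np.array([[1.0, 1.0, -1.0, 0.0]] * 4)
        np.fill_diagonal(C, 1.0)
        A = signed_adjacency(C, beta=8)
        assert A[0, 1] == 1.0
        assert A[0, 2] == 0.0
        assert A[0, 3] == pytest.approx(0.5 ** 8)

    def test_monotone_in_correlation(self, rng):
        c = np.sort(rng.uniform(-1, 1, 50))
        C = np.eye(51)
        C[0, 1:] = C[1:, 0] = c
        A = signed_adjacency(C, beta=8)
        assert (np.diff(A[0, 1:]) > 0).all()

    def test_out_of_range_correlation_rejected(self):
        with pytest.raises(ValueError):
            signed_adjacency(np.array([[1.0, 2.0], [2.0, 1.0]]), 8)


def tom_oracle(A):
    n = A.shape[0]
    T = np.ones((n, n))
    k = A.sum(axis=1) - np.diag(A)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l = sum(A[i, u] * A[u, j] for u in range(n) if u not in (i, j))
            T[i, j] = (l + A[i, j]) / (min(k[i], k[j]) + 1 - A[i, j])
    return T


class TestTOM:
    def test_two_node_closed_form(self):
        a = 0.37
        A = np.array([[1.0, a], [a, 1.0]])
        T = topological_overlap(A)
        assert T[0, 1] == pytest.approx(a)

    def test_identical_binary_rows_give_one(self):
        A = np.ones((4, 4))
        T = topological_overlap(A)
        np.testing.assert_allclose(T, 1.0)

    def test_matches_triple_loop_oracle(self, rng):
        A = rng.uniform(0, 1, size=(6, 6))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 1.0)
        np.testing.assert_allclose(topological_overlap(A), tom_oracle(A),
                                   atol=1e-12)

    def test_range_zero_one(self, rng):
        A = rng.uniform(0, 1, size=(40, 40))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 1.0)
        T = topological_overlap(A)
        assert T.min() >= 0.0 and T.max() <= 1.0 + 1e-12

    def test_asymmetric_input_rejected(self):
        A = np.array([[1.0, 0.2], [0.3, 1.0]])
        with pytest.raises(ValueError, match="symmetric"):
            topological_overlap(A)


def planted_matrix(rng, n_modules=3, size=25, n_noise=60, n_donors=50,
                   loading=0.9, noise=0.3):
    rows, labels = [], []
    for m in range(n_modules):
        f = rng.normal(size=n_donors)
        rows.append(loading * f[None, :]
                    + noise * rng.normal(size=(size, n_donors)))
        labels += [m + 1] * size
    rows.append(rng.normal(size=(n_noise, n_donors)))
    labels += [0] * n_noise
    return fmat(np.vstack(rows)), np.array(labels)


class TestModuleDetection:
    def test_planted_modules_recovered(self, rng):
        X, truth = planted_matrix(rng)
        net = CoexpressionNetwork(beta=8, min_module_size=10).fit(X)
        assert net.n_modules_ == 3
        assert adjusted_rand_score(truth, net.labels_) > 0.9

    def test_highly_correlated_modules_merged(self, rng):
        # two planted modules sharing one latent factor: eigengene
        # correlation ~0.95 > merge threshold 0.75 -> one module
        f = rng.normal(size=60)
        X = np.vstack([
            0.95 * f[None, :] + 0.2 * rng.normal(size=(25, 60)),
            0.95 * f[None, :] + 0.2 * rng.normal(size=(25, 60)),
            rng.normal(size=(40, 60)),
        ])
        net = CoexpressionNetwork(beta=8, min_module_size=10,
                                  merge_threshold=0.75).fit(fmat(X))
        assert net.n_modules_ == 1

    def test_pure_noise_mostly_unassigned(self, rng):
        X = fmat(rng.normal(size=(120, 40)))
        net = CoexpressionNetwork(beta=8, min_module_size=10).fit(X)
        assert (net.labels_ == 0).mean() >= 0.5

    def test_degenerate_equal_dissimilarity_single_module(self):
        from isletpheno.network import _static_cut_labels
        D = np.full((40, 40), 0.5)
        np.fill_diagonal(D, 0.0)
        labels = _static_cut_labels(D, min_module_size=10, cut_height=None)
        assert (labels == 1).all()

    def test_detect_modules_table(self, rng):
        X, truth = planted_matrix(rng)
        table = detect_modules(X, beta=8, min_module_size=10)
        assert set(table.columns) == {"feature", "module"}
        assert table["module"].max() == 3

    def test_incomplete_matrix_rejected(self):
        X = fmat(np.ones((5, 6)))
        X.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="complete"):
            CoexpressionNetwork().fit(X)


class TestEigengenes:
    def test_identical_features_module(self, rng):
        x = rng.normal(size=30)
        X = fmat(np.tile(x, (5, 1)))
        assign = pd.DataFrame({"feature": X.index, "module": 1})
        eig, ve = module_eigengenes(X, assign)
        z = (x - x.mean()) / x.std()
        np.testing.assert_allclose(eig.loc["M1"], z / np.linalg.norm(z),
                                   atol=1e-10)
        assert ve[0] == pytest.approx(1.0)

    def test_orientation_invariant_to_global_sign_flip(self, rng):
        X, _ = planted_matrix(rng, n_modules=1, n_noise=0)
        assign = pd.DataFrame({"feature": X.index, "module": 1})
        e1, _ = module_eigengenes(X, assign)
        e2, _ = module_eigengenes(-X, assign)
        np.testing.assert_allclose(e1.to_numpy(), -e2.to_numpy(), atol=1e-10)
        # each eigengene is unit norm
        assert np.linalg.norm(e1.to_numpy()) == pytest.approx(1.0)

    def test_planted_factor_recovered(self, rng):
        f = rng.normal(size=80)
        X = fmat(0.9 * f[None, :] + np.sqrt(1 - 0.81)
                 * rng.normal(size=(30, 80)))
        assign = pd.DataFrame({"feature": X.index, "module": 1})
        eig, _ = module_eigengenes(X, assign)
        assert abs(np.corrcoef(eig.loc["M1"], f)[0, 1]) > 0.95

    def test_single_feature_module_is_standardized_feature(self, rng):
        x = rng.normal(size=20)
        X = fmat(x[None, :])
        assign = pd.DataFrame({"feature": X.index, "module": 1})
        eig, ve = module_eigengenes(X, assign)
        z = (x - x.mean()) / x.std()
        np.testing.assert_allclose(eig.loc["M1"], z / np.linalg.norm(z),
                                   atol=1e-10)


class TestModuleTrait:
    def test_empty_covariates_equals_pearson(self, rng):
        eig = pd.DataFrame(rng.normal(size=(2, 30)), index=["M1", "M2"])
        traits = pd.DataFrame(rng.normal(size=(30, 2)), columns=["a", "b"])
        res = module_trait_partial_correlation(eig, traits)
        for _, row in res.iterrows():
            expected = np.corrcoef(eig.loc[row["module"]],
                                   traits[row["trait"]])[0, 1]
            assert row["r"] == pytest.approx(expected, abs=1e-12)

    def test_trait_equal_to_covariate_gives_zero(self, rng):
        eig = pd.DataFrame(rng.normal(size=(1, 40)), index=["M1"])
        z = rng.normal(size=40)
        traits = pd.DataFrame({"z_trait": z})
        res = module_trait_partial_correlation(eig, traits,
                                               pd.DataFrame({"z": z}))
        assert abs(res.loc[0, "r"]) < 1e-8

    def test_planted_coupling_recovered(self, cohort_small):
        # module 1 of the small cohort couples to the fat AUC at strength 0.6
        from isletpheno.preprocess import preprocess_proteome
        mat, _ = preprocess_proteome(cohort_small.protein)
        truth = cohort_small.omics_truth["protein"].set_index("feature_id")
        labels = truth["module"].reindex(mat.index).fillna(0).astype(int)
        assign = pd.DataFrame({"feature": mat.index, "module": labels.to_numpy()})
        eig, _ = module_eigengenes(mat, assign)
        donors = cohort_small.donors.set_index("donor_id").reindex(mat.columns)
        gt = cohort_small.donor_truth.set_index("donor_id").reindex(mat.columns)
        traits = pd.DataFrame(
            {"auc_fat": np.log10(gt["auc_fat_true"].to_numpy())},
            index=mat.columns)
        cov = donors[["purity", "culture_time", "digestion_time",
                      "cold_ischemia_time"]]
        res = module_trait_partial_correlation(eig, traits, cov)
        cell = res[(res["module"] == "M1") & (res["trait"] == "auc_fat")]
        assert cell["significant"].iloc[0]
        assert cell["r"].iloc[0] > 0.3

    def test_collinear_covariates_dropped_with_warning(self, rng, caplog):
        eig = pd.DataFrame(rng.normal(size=(1, 30)), index=["M1"])
        traits = pd.DataFrame({"t": rng.normal(size=30)})
        z = rng.normal(size=30)
        cov = pd.DataFrame({"z1": z, "z2": 2 * z})
        with caplog.at_level("WARNING"):
            res = module_trait_partial_correlation(eig, traits, cov)
        assert "collinear" in caplog.text
        assert np.isfinite(res.loc[0, "r"])
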