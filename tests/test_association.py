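"""Differential abundance, OLS trait association, BH, and correlations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from isletpheno.association import (bh_adjust, covariate_adjusted_regression,
                                    differential_abundance,
                                    pairwise_correlation, partial_correlation)


def bh_oracle(p):
    """Step-up definition: q_(i) = min_{j>=i} p_(j) m / j, capped at 1."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q_sorted = np.minimum.accumulate(
        (p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


class TestBH:
    def test_hand_computed_examples(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.04]), [0.02, 0.04])
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.3]), [0.3])

    def test_matches_definition_oracle_small_m(self, rng):
        for m in range(1, 11):
            p = rng.random(m)
            np.testing.assert_allclose(bh_adjust(p), bh_oracle(p), atol=1e-12)

    def test_q_at_least_p_and_order_preserving(self, rng):
        p = rng.random(50)
        q = bh_adjust(p)
        assert (q >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_nan_excluded_from_family(self):
        q = bh_adjust([0.01, np.nan, 0.04])
        assert np.isnan(q[1]) and not np.isnan(q[0])


def make_matrix(X, features=None, donors=None):
    X = np.asarray(X, float)
    return pd.DataFrame(
        X, index=features or [f"f{i}" for i in range(X.shape[0])],
        columns=donors or [f"d{j}" for j in range(X.shape[1])])


class TestDifferentialAbundance:
    def test_identical_groups_null(self):
        X = make_matrix(np.tile([1.0, 2.0, 3.0, 1.0, 2.0, 3.0], (4, 1)))
        res = differential_abundance(X, ["ND"] * 3 + ["T2D"] * 3, ref="ND")
        np.testing.assert_allclose(res["log2fc"], 0.0, atol=1e-12)
        np.testing.assert_allclose(res["p"], 1.0)

    def test_constant_feature_flagged_p_one(self):
        X = make_matrix(np.ones((2, 8)))
        res = differential_abundance(X, ["ND"] * 4 + ["T2D"] * 4, ref="ND")
        assert (res["flag"] == "constant").all()
        assert (res["p"] == 1.0).all()

    def test_log2fc_sign_and_scale_conversion(self):
        X = np.zeros((1, 20))
        X[0, 10:] = 1.0  # T2D one log10 unit higher
        res = differential_abundance(make_matrix(X), ["ND"] * 10 + ["T2D"] * 10,
                                     ref="ND")
        assert res.loc[0, "log2fc"] == pytest.approx(1.0 / np.log10(2))
        assert res.loc[0, "log2fc"] > 0

    def test_planted_effects_recovered_with_fdr_control(self, rng):
        # Monte-Carlo oracle scenario: |log2FC| = 0.5 on log10 scale with
        # SD 0.12, 118 vs 16 donors, 200 planted of 2000
        m, nde = 2000, 200
        X = rng.normal(0, 0.12, (m, 134))
        fc = 0.5 * np.log10(2)
        X[:100, 118:] += fc
        X[100:200, 118:] -= fc
        res = differential_abundance(make_matrix(X),
                                     ["ND"] * 118 + ["T2D"] * 16, ref="ND")
        hits = res["significant"].to_numpy()
        sensitivity = hits[:nde].mean()
        fdr = hits[nde:].sum() / max(hits.sum(), 1)
        assert sensitivity >= 0.9
        assert fdr <= 0.05

    def test_two_feature_toy_bh(self):
        # construct two features whose t-test p-values are moderate, then the
        # reported q must equal the BH oracle of the raw p
        X = make_matrix(np.array([[0.0, 0.1, 1.0, 1.1, 0.9, 1.2],
                                  [0.0, 1.0, 0.4, 1.4, 0.2, 1.6]]))
        res = differential_abundance(X, ["a"] * 2 + ["b"] * 4, ref="a")
        np.testing.assert_allclose(res["q"], bh_oracle(res["p"]), atol=1e-12)


class TestCovariateAdjustedRegression:
    def test_four_point_toy_exact_slope(self):
        X = make_matrix([[1.0, 2.0, 3.0, 4.0]])
        res = covariate_adjusted_regression(X, [1.0, 2.0, 3.0, 4.0])
        assert res.loc[0, "coefficient"] == pytest.approx(1.0)
        assert res.loc[0, "p"] < 0.05

    def test_orthogonal_covariate_leaves_slope(self, rng):
        n = 40
        trait = rng.normal(size=n)
        cov = np.repeat([0.0, 1.0], n // 2)
        trait = trait - trait.mean()
        # balanced, orthogonalized design: adjusted slope == simple slope
        y = 2.0 * trait + rng.normal(0, 0.1, n)
        X = make_matrix(y[None, :])
        adj = covariate_adjusted_regression(X, trait, pd.DataFrame({"t2d": cov}))
        simple = covariate_adjusted_regression(X, trait)
        assert adj.loc[0, "coefficient"] == pytest.approx(
            simple.loc[0, "coefficient"], rel=1e-2)

    def test_matches_statsmodels(self, rng):
        import statsmodels.api as sm
        n = 30
        trait = rng.normal(size=n)
        cov = rng.normal(size=n)
        y = 1.5 * trait - 0.7 * cov + rng.normal(size=n)
        res = covariate_adjusted_regression(make_matrix(y[None, :]), trait,
                                            pd.DataFrame({"c": cov}))
        ref = sm.OLS(y, sm.add_constant(np.column_stack([trait, cov]))).fit()
        assert res.loc[0, "coefficient"] == pytest.approx(ref.params[1])
        assert res.loc[0, "p"] == pytest.approx(ref.pvalues[1])

    def test_collinear_design_rejected(self):
        X = make_matrix(np.random.default_rng(0).normal(size=(2, 10)))
        trait = np.arange(10.0)
        with pytest.raises(ValueError, match="collinear"):
            covariate_adjusted_regression(X, trait,
                                          pd.DataFrame({"c": 2 * trait}))

    def test_module_features_enriched_for_coupled_trait(self, cohort_small):
        # module 1 was generated coupled to the fat AUC: its features should
        # rank higher than background in the trait association
        from isletpheno.preprocess import preprocess_proteome
        mat, _ = preprocess_proteome(cohort_small.protein)
        truth = cohort_small.omics_truth["protein"].set_index("feature_id")
        donors = cohort_small.donor_truth.set_index("donor_id")
        trait = np.log10(donors["auc_fat_true"].reindex(mat.columns))
        t2d = (cohort_small.donors.set_index("donor_id")["group"]
               .reindex(mat.columns) == "T2D").astype(float)
        res = covariate_adjusted_regression(
            mat, trait.to_numpy(), pd.DataFrame({"t2d": t2d.to_numpy()}))
        res = res.set_index("feature")
        in_mod = truth["module"].reindex(res.index) == 1
        ranks = (-res["statistic"].abs()).rank()
        assert stats.mannwhitneyu(ranks[in_mod], ranks[~in_mod],
                                  alternative="less").pvalue < 1e-6


class TestCorrelation:
    def test_self_correlation_is_one(self, rng):
        x = rng.normal(size=20)
        r, p = pairwise_correlation(x, x)
        assert r == pytest.approx(1.0)

    def test_partial_with_empty_set_equals_pearson(self, rng):
        x, y = rng.normal(size=(2, 25))
        r0, p0 = pairwise_correlation(x, y)
        r1, p1 = partial_correlation(x, y)
        assert r1 == pytest.approx(r0, abs=1e-12)
        assert p1 == pytest.approx(p0, rel=1e-6)

    def test_recursion_formula_three_variables(self, rng):
        # r_xy.z = (r_xy - r_xz r_yz) / sqrt((1-r_xz^2)(1-r_yz^2))
        n = 500000
        z = rng.normal(size=n)
        x = 0.5 * z + rng.normal(size=n)
        y = 0.5 * z + rng.normal(size=n)
        rxy = np.corrcoef(x, y)[0, 1]
        rxz = np.corrcoef(x, z)[0, 1]
        ryz = np.corrcoef(y, z)[0, 1]
        expected = (rxy - rxz * ryz) / np.sqrt((1 - rxz**2) * (1 - ryz**2))
        got, _ = partial_correlation(x, y, z)
        assert got == pytest.approx(expected, abs=1e-10)

    def test_recursion_closed_form_example(self):
        # with r_xy=0.8, r_xz=r_yz=0.5 the recursion gives 0.7333
        assert (0.8 - 0.25) / 0.75 == pytest.approx(0.73333, abs=1e-4)
        # construct exact data with those correlations via Cholesky
        R = np.array([[1.0, 0.8, 0.5], [0.8, 1.0, 0.5], [0.5, 0.5, 1.0]])
        L = np.linalg.cholesky(R)
        base = np.random.default_rng(1).normal(size=(3, 2000))
        # orthonormalize so the empirical correlation is exactly R
        q, _ = np.linalg.qr(base.T)
        data = (L @ q.T[:3]) * np.sqrt(2000)
        x, y, z = data
        r, _ = partial_correlation(x, y, z)
        assert r == pytest.approx(0.73333, abs=1e-4)

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        n = 60
        df = pd.DataFrame(rng.normal(size=(n, 4)), columns=list("xyzw"))
        df["x"] += 0.5 * df["z"]
        df["y"] += 0.5 * df["z"]
        ref = pingouin.partial_corr(df, x="x", y="y", covar=["z", "w"])
        r, p = partial_correlation(df["x"], df["y"], df[["z", "w"]].to_numpy())
        assert r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert p == pytest.approx(float(ref["p_val"].iloc[0]), rel=1e-6)

    def test_zero_variance_flagged(self):
        with pytest.raises(ValueError, match="zero-variance"):
            pairwise_correlation(np.ones(10), np.arange(10.0))


class TestTypeIControl:
    def test_null_data_controls_fdr(self):
        # no planted effects: the discovery fraction stays at or below the
        # nominal 5% (pooled over seeds, binomial tolerance)
        m = 400
        total_disc = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            X = make_matrix(r.normal(size=(m, 60)))
            res = differential_abundance(X, ["ND"] * 40 + ["T2D"] * 20,
                                         ref="ND")
            total_disc += int(res["significant"].sum())
        assert total_disc / (10 * m) <= 0.05
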