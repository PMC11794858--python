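"""Edgewise GLM, signed thresholding, block permutation FDR, and the
summary-statistic tests behind demographic tables."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import fcbiotype as fb
from fcbiotype.errors import FormatError


class TestEdgewiseGLM:
    def test_no_covariates_equals_pooled_t(self):
        """Algebraic identity checked numerically at 1e-10."""
        rng = np.random.default_rng(0)
        Y = rng.normal(size=(40, 50))
        g = np.r_[np.zeros(22), np.ones(18)]
        res = fb.edgewise_glm(Y, g)
        for e in range(0, 50, 7):
            t_ref, df = fb.pooled_t_from_summary(
                Y[g == 1, e].mean(), Y[g == 1, e].std(ddof=1), 18,
                Y[g == 0, e].mean(), Y[g == 0, e].std(ddof=1), 22,
            )
            assert res.t[e] == pytest.approx(t_ref, abs=1e-10)
            assert res.df == df

    def test_orthogonal_covariate_changes_t_only_via_df(self):
        """A covariate orthogonal to both the group indicator and the
        response leaves the coefficient and residual sum unchanged;
        t rescales by sqrt(df_new / df_old)."""
        rng = np.random.default_rng(1)
        n = 60
        g = np.r_[np.zeros(30), np.ones(30)]
        Y = rng.normal(size=(n, 10))
        base = fb.edgewise_glm(Y, g)
        X = np.column_stack([np.ones(n), g - g.mean()] + [Y[:, j] for j in range(10)])
        # build a covariate in the orthogonal complement of [1, g, Y]
        q, _ = np.linalg.qr(X)
        v = rng.normal(size=n)
        v = v - q @ (q.T @ v)
        res = fb.edgewise_glm(Y, g, covars=pd.DataFrame({"c": v}))
        np.testing.assert_allclose(res.effect, base.effect, atol=1e-10)
        ratio = np.sqrt((n - 2) / (n - 3))
        np.testing.assert_allclose(res.t * ratio, base.t, atol=1e-8)

    def test_null_type_one_rate(self, small_atlas):
        design = fb.null_design(seed=13, atlas=small_atlas, n_chr=80, n_hc=60)
        cohort, stack, _ = fb.simulate_cohort(design)
        res = fb.edgewise_glm(
            stack.edges, cohort.group_mask("CHR").astype(float),
            covars=cohort.covariates(),
        )
        rate = np.mean(res.p < 0.005)
        se = np.sqrt(0.005 * 0.995 / stack.n_edges)
        assert abs(rate - 0.005) < 4 * se

    def test_rank_deficient_design_rejected(self):
        Y = np.random.default_rng(2).normal(size=(20, 5))
        g = np.r_[np.zeros(10), np.ones(10)]
        with pytest.raises(FormatError, match="covariate"):
            fb.edgewise_glm(Y, g, covars=pd.DataFrame({"dup": g}))


class TestThresholdSigned:
    def test_all_nonsignificant_empty(self):
        st_ = fb.EdgewiseStats("c", np.zeros(6), np.zeros(6), np.ones(6), 10)
        m = fb.threshold_signed(st_, P=4)
        assert not m.pos_matrix.any() and not m.neg_matrix.any()

    def test_single_edge_symmetric_pair(self):
        p = np.ones(6)
        t = np.zeros(6)
        p[2], t[2] = 0.001, 3.0   # edge 2 of P=4 is pair (0,3)
        m = fb.threshold_signed(fb.EdgewiseStats("c", t, t, p, 10), P=4)
        assert m.pos_matrix.sum() == 2
        assert m.pos_matrix[0, 3] == m.pos_matrix[3, 0] == 1
        assert not m.neg_matrix.any()

    def test_pos_neg_disjoint_and_symmetric(self, default_sim):
        design, cohort, stack, truth = default_sim
        g = cohort.group_mask("CHR").astype(float)
        res = fb.edgewise_glm(stack.edges, g, covars=cohort.covariates())
        m = fb.threshold_signed(res, P=design.P)
        assert not np.any(m.pos_matrix & m.neg_matrix)
        assert np.array_equal(m.pos_matrix, m.pos_matrix.T)

    def test_planted_effect_recovery(self, default_sim):
        """At default delta, >= 80% of a biotype's affected edges are
        recovered by the thresholded contrast."""
        design, cohort, stack, truth = default_sim
        chr_idx = np.flatnonzero(cohort.group_mask("CHR"))
        b1 = chr_idx[truth.biotype_labels == 1]
        hc = np.flatnonzero(cohort.group_mask("HC"))
        sub = np.r_[b1, hc]
        g = np.r_[np.ones(b1.size), np.zeros(hc.size)]
        res = fb.edgewise_glm(stack.edges[sub], g)
        sig_pos = (res.p < 0.005) & (res.t > 0)
        sig_neg = (res.p < 0.005) & (res.t < 0)
        pos_true = truth.delta[0] > 0
        neg_true = truth.delta[0] < 0
        assert sig_pos[pos_true].mean() >= 0.8
        assert sig_neg[neg_true].mean() >= 0.8


class TestNetworkClusterFDR:
    def test_strong_single_block_detected(self, small_atlas):
        """Plant one strong block: it must be the only significant one."""
        rng = np.random.default_rng(3)
        E = small_atlas.n_edges
        n1, n0 = 40, 40
        Y = rng.normal(0, 0.15, size=(n1 + n0, E))
        na, nb = small_atlas.edge_networks()
        block = (na == "somatomotor") & (nb == "somatomotor")
        Y[:n1, block] += 0.3
        g = np.r_[np.ones(n1), np.zeros(n0)]
        # with 36 blocks in the BH family, surviving q < 0.05 at rank 1
        # needs p < 0.05/36, i.e. at least 999 permutations
        res = fb.network_cluster_fdr(Y, g, small_atlas, n_perm=999, seed=4)
        sig = res.loc[res["significant"]]
        assert len(sig) == 1
        assert {sig.iloc[0]["network_a"], sig.iloc[0]["network_b"]} == {"somatomotor"}

    def test_permutation_p_bounds(self, small_atlas):
        rng = np.random.default_rng(5)
        Y = rng.normal(size=(30, small_atlas.n_edges))
        g = np.r_[np.ones(15), np.zeros(15)]
        res = fb.network_cluster_fdr(Y, g, small_atlas, n_perm=99, seed=6)
        assert np.all(res["p"] >= 1 / 100) and np.all(res["p"] <= 1.0)
        assert np.all(res["q"] >= res["p"] - 1e-12)


class TestSummaryStatistics:
    # group summaries (mean, sd, n) of cognitive and functioning scores
    # for a 151-patient vs 88-control comparison, with the published t
    TABLE_T = [
        ("TMT", 33.93, 16.3, 28.18, 8.63, 3.064),
        ("BACS_SC", 56.75, 10.48, 66.22, 9.49, -6.971),
        ("HVLT-R", 22.99, 4.75, 26.34, 3.61, -5.719),
        ("WMS-III_SS", 15.97, 3.23, 17.43, 3.01, -3.452),
        ("BVMT-R", 26.37, 6.54, 29.91, 4.71, -4.447),
        ("Fluency", 19.4, 4.88, 23.14, 5.02, -5.650),
    ]

    @pytest.mark.parametrize("name,m1,s1,m2,s2,expected", TABLE_T)
    def test_pooled_t_reproduces_published_values(self, name, m1, s1, m2, s2, expected):
        t, df = fb.pooled_t_from_summary(m1, s1, 151, m2, s2, 88)
        assert df == 237
        assert t == pytest.approx(expected, abs=0.01)

    def test_equal_means_zero(self):
        t, _ = fb.pooled_t_from_summary(5.0, 1.0, 20, 5.0, 2.0, 30)
        assert t == 0.0

    def test_chi2_published_sex_table(self):
        chi2, df = fb.chi2_contingency([[79, 72], [40, 48]])
        assert chi2 == pytest.approx(1.048, abs=0.005)
        assert df == 1

    def test_chi2_hand_calculation(self):
        chi2, df = fb.chi2_contingency([[10, 0], [0, 10]])
        assert chi2 == pytest.approx(20.0, abs=1e-12)

    def test_chi2_proportional_rows_zero(self):
        chi2, _ = fb.chi2_contingency([[10, 20], [5, 10]])
        assert chi2 == pytest.approx(0.0, abs=1e-12)

    def test_chi2_matches_scipy_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            tab = rng.integers(1, 50, size=(rng.integers(2, 4), rng.integers(2, 4)))
            ours, df = fb.chi2_contingency(tab)
            ref = stats.chi2_contingency(tab, correction=False)
            assert ours == pytest.approx(ref.statistic, rel=1e-12)
            assert df == ref.dof

    def test_chi2_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            fb.chi2_contingency([[0, 0], [5, 3]])

    def test_anova_equal_means_zero(self):
        F, _, _ = fb.anova_from_summary([3.0, 3.0, 3.0], [1.0, 1.2, 0.9], [10, 12, 9])
        assert F == pytest.approx(0.0, abs=1e-12)

    def test_anova_two_groups_is_t_squared(self):
        t, _ = fb.pooled_t_from_summary(5.0, 1.1, 20, 4.2, 0.9, 25)
        F, df1, df2 = fb.anova_from_summary([5.0, 4.2], [1.1, 0.9], [20, 25])
        assert F == pytest.approx(t**2, rel=1e-12)
        assert (df1, df2) == (1, 43)

    def test_anova_matches_raw_data_oracle(self):
        """Summary-statistic F equals scipy's F on the raw samples."""
        rng = np.random.default_rng(7)
        groups = [rng.normal(m, 1.0, size=n) for m, n in ((0, 12), (0.5, 15), (1.0, 9))]
        F_ref = stats.f_oneway(*groups).statistic
        F, _, _ = fb.anova_from_summary(
            [g.mean() for g in groups],
            [g.std(ddof=1) for g in groups],
            [len(g) for g in groups],
        )
        assert F == pytest.approx(F_ref, rel=1e-10)

    def test_anova_se_conversion(self):
        means, sds, ns = [1.0, 2.0], [1.5, 2.5], [10, 16]
        F_sd, _, _ = fb.anova_from_summary(means, sds, ns, dispersion_kind="sd")
        ses = [s / np.sqrt(n) for s, n in zip(sds, ns)]
        F_se, _, _ = fb.anova_from_summary(means, ses, ns, dispersion_kind="se")
        assert F_se == pytest.approx(F_sd, rel=1e-12)
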