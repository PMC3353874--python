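"""Correlation statistics, clustering, screens, ANOVA, Venn, fold change."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from amtlfq import screening as scr


def _pearson_oracle(x, y):
    """Direct formula evaluation, independent of the implementation path."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    r = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
        ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
    )
    t = r * np.sqrt((n - 2) / (1 - r**2))
    p = 2 * stats.t.sf(abs(t), n - 2)
    return r, p


class TestPearson:
    def test_self_correlation(self):
        x = [1.0, 2.0, 5.0, 3.0]
        assert scr.pearson_r_p(x, x).r == pytest.approx(1.0)

    def test_affine_anticorrelation(self):
        x = np.array([1.0, 2.0, 5.0, 3.0])
        rec = scr.pearson_r_p(x, -x + 7)
        assert rec.r == pytest.approx(-1.0)
        assert rec.p == 0.0

    def test_matches_direct_formula_and_scipy(self):
        x = [1, 2, 3, 4, 5]
        y = [2, 1, 4, 3, 6]
        rec = scr.pearson_r_p(x, y)
        r0, p0 = _pearson_oracle(x, y)
        assert rec.r == pytest.approx(r0, abs=1e-10)
        assert rec.p == pytest.approx(p0, abs=1e-10)
        sp = stats.pearsonr(x, y)
        assert rec.r == pytest.approx(sp.statistic, abs=1e-10)
        assert rec.p == pytest.approx(sp.pvalue, abs=1e-10)

    def test_random_instances_match_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            n = int(rng.integers(5, 60))
            x, y = rng.normal(size=n), rng.normal(size=n)
            rec = scr.pearson_r_p(x, y)
            r0, p0 = _pearson_oracle(x, y)
            assert rec.r == pytest.approx(r0, abs=1e-10)
            assert rec.p == pytest.approx(p0, abs=1e-10)

    def test_pairwise_complete_and_min_n(self):
        x = [1.0, 2.0, np.nan, 4.0, 5.0]
        y = [1.0, 2.0, 3.0, np.nan, 5.0]
        rec = scr.pearson_r_p(x, y)
        assert rec.n_obs == 3
        with pytest.raises(ValueError):
            scr.pearson_r_p([1.0, np.nan], [1.0, 2.0])

    def test_zero_variance_flagged(self):
        rec = scr.pearson_r_p([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert np.isnan(rec.r)


class TestSpearman:
    def test_monotone_pair(self):
        x = [1.0, 3.0, 9.0, 27.0]
        assert scr.spearman_r_p(x, np.exp(x)).r == pytest.approx(1.0)

    def test_midrank_hand_computation(self):
        # ranks x = [1.5, 1.5, 3], y = [1, 2, 3]; Pearson = 1.5/sqrt(1.5*2)
        rec = scr.spearman_r_p([1.0, 1.0, 2.0], [1.0, 2.0, 3.0])
        assert rec.r == pytest.approx(1.5 / np.sqrt(3.0), abs=1e-12)

    def test_matches_scipy(self):
        rng = np.random.default_rng(9)
        x, y = rng.normal(size=40), rng.normal(size=40)
        rec = scr.spearman_r_p(x, y)
        sp = stats.spearmanr(x, y)
        assert rec.r == pytest.approx(sp.statistic, abs=1e-12)


class TestScreen:
    def _matrix(self, rows, samples):
        return pd.DataFrame(rows, index=[f"p{i}" for i in range(len(rows))], columns=samples)

    def test_exact_copy_selected_with_r_one(self):
        samples = [f"s{i}" for i in range(12)]
        bio = pd.Series(np.arange(12, dtype=float), index=samples, name="b")
        mat = self._matrix([bio.to_numpy(), np.random.default_rng(0).normal(size=12)], samples)
        res = scr.biomarker_screen(mat, bio, min_n=10)
        assert "p0" in set(res.selected["protein_id"])
        sel = res.selected.set_index("protein_id")
        assert sel.loc["p0", "r"] == pytest.approx(1.0)

    def test_magnitude_cutoff_is_hard(self):
        # a protein with |r| just below 0.3 is rejected regardless of p
        rng = np.random.default_rng(1)
        n = 2000
        b = rng.normal(size=n)
        x = 0.29 * b + np.sqrt(1 - 0.29**2) * rng.normal(size=n)
        r_emp = np.corrcoef(x, b)[0, 1]  # ~0.29, p astronomically small
        assume_ok = abs(r_emp) < 0.3
        samples = [f"s{i}" for i in range(n)]
        mat = self._matrix([x], samples)
        res = scr.biomarker_screen(mat, pd.Series(b, index=samples, name="b"))
        if assume_ok:
            assert res.selected.empty
            tested = res.all_tested.set_index("protein_id")
            assert tested.loc["p0", "p"] < 1e-6

    def test_positive_plus_negative_equals_total(self, small_study):
        inf = small_study.panel.loc[
            small_study.panel["group"] == "infected", "sample_id"
        ].tolist()
        bio = small_study.panel.set_index("sample_id").loc[inf, "neopterin"]
        res = scr.biomarker_screen(small_study.true_log2[inf], bio)
        assert res.n_positive + res.n_negative == len(res.selected)

    def test_order_permutation_invariant(self, small_study):
        inf = small_study.panel.loc[
            small_study.panel["group"] == "infected", "sample_id"
        ].tolist()
        bio = small_study.panel.set_index("sample_id").loc[inf, "neopterin"]
        mat = small_study.true_log2[inf]
        res1 = scr.biomarker_screen(mat, bio)
        res2 = scr.biomarker_screen(mat.sample(frac=1.0, random_state=2), bio)
        assert set(res1.selected["protein_id"]) == set(res2.selected["protein_id"])

    def test_constant_biomarker_aborts(self):
        samples = ["a", "b", "c"]
        mat = self._matrix([[1.0, 2.0, 3.0]], samples)
        with pytest.raises(ValueError, match="constant"):
            scr.biomarker_screen(mat, pd.Series([5.0, 5.0, 5.0], index=samples), min_n=3)

    def test_spearman_mode_matches_per_protein_calls(self, small_study):
        inf = small_study.panel.loc[
            small_study.panel["group"] == "infected", "sample_id"
        ].tolist()
        bio = small_study.panel.set_index("sample_id").loc[inf, "neopterin"]
        mat = small_study.true_log2[inf].iloc[:10]
        res = scr.biomarker_screen(mat, bio, method="spearman")
        tested = res.all_tested.set_index("protein_id")
        for pid in mat.index:
            rec = scr.spearman_r_p(mat.loc[pid], bio)
            assert tested.loc[pid, "r"] == pytest.approx(rec.r, abs=1e-12)


class TestSampleCorr:
    def test_identical_columns_correlate_perfectly(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=30)
        mat = pd.DataFrame({"a": v, "b": v, "c": rng.normal(size=30)})
        meta = pd.DataFrame(
            {"subject_id": ["s1", "s1", "s2"], "group": ["g", "g", "g"]},
            index=["a", "b", "c"],
        )
        corr, summ = scr.sample_corr_summary(mat, meta)
        assert corr.loc["a", "b"] == pytest.approx(1.0)
        assert summ["within_subject"] == pytest.approx(1.0)

    def test_permutation_invariance(self, small_study):
        mat = small_study.true_log2
        meta = small_study.panel.set_index("sample_id")
        _, s1 = scr.sample_corr_summary(mat, meta)
        perm = mat[mat.columns[::-1]]
        _, s2 = scr.sample_corr_summary(perm, meta)
        for k in s1:
            assert s1[k] == pytest.approx(s2[k], abs=1e-12)

    def test_within_subject_exceeds_between(self, small_study):
        _, summ = scr.sample_corr_summary(
            small_study.true_log2, small_study.panel.set_index("sample_id")
        )
        assert summ["within_subject"] > summ["between_subject_within_infected"]
        assert summ["between_subject_within_infected"] > summ["between_group"]


class TestCluster:
    def test_hand_traced_average_linkage(self):
        r = np.array(
            [
                [1.0, 0.9, 0.1, 0.0],
                [0.9, 1.0, 0.2, 0.1],
                [0.1, 0.2, 1.0, 0.8],
                [0.0, 0.1, 0.8, 1.0],
            ]
        )
        corr = pd.DataFrame(r, index=list("abcd"), columns=list("abcd"))
        res = scr.cluster_order(corr, n_clusters=2)
        # hand trace: merge (a,b)@0.1, (c,d)@0.2, then clusters@mean=0.9
        assert np.allclose(res.linkage[:, 2], [0.1, 0.2, 0.9])
        labels = res.labels
        assert labels["a"] == labels["b"] != labels["c"] == labels["d"]

    def test_block_diagonal_recovered_exactly(self):
        rng = np.random.default_rng(5)
        latent = np.repeat([0, 1], 10)
        profiles = rng.normal(0, 1, (40, 2))  # one protein profile per block
        x = profiles[:, latent] + rng.normal(0, 0.05, (40, 20))
        mat = pd.DataFrame(x, columns=[f"s{i}" for i in range(20)])
        corr = mat.corr()
        res = scr.cluster_order(corr, n_clusters=2)
        got = res.labels.to_numpy()
        assert scr.adjusted_rand_index(latent, got) == 1.0

    def test_heights_nondecreasing(self, small_study):
        corr = small_study.true_log2.corr()
        res = scr.cluster_order(corr)
        assert (np.diff(res.linkage[:, 2]) >= -1e-12).all()
        assert sorted(res.leaf_order) == sorted(corr.index)

    def test_asymmetric_rejected(self):
        bad = pd.DataFrame([[1.0, 0.5], [0.4, 1.0]], index=["a", "b"], columns=["a", "b"])
        with pytest.raises(ValueError, match="symmetric"):
            scr.cluster_order(bad)

    def test_shift_invariance_through_recorrelation(self, small_study):
        mat = small_study.true_log2.copy()
        res1 = scr.cluster_order(mat.corr(), n_clusters=3)
        mat2 = mat.copy()
        mat2["P01_w000"] = mat2["P01_w000"] + 42.0  # constant shift of one sample
        res2 = scr.cluster_order(mat2.corr(), n_clusters=3)
        assert np.allclose(res1.linkage[:, 2], res2.linkage[:, 2], atol=1e-8)


class TestAri:
    def test_matches_sklearn(self):
        sk = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(2)
        for _ in range(20):
            a = rng.integers(0, 4, 50)
            b = rng.integers(0, 3, 50)
            assert scr.adjusted_rand_index(a, b) == pytest.approx(
                sk.adjusted_rand_score(a, b), abs=1e-12
            )


class TestVenn:
    def test_enumerated_example(self):
        regions = scr.venn_partition({1, 2}, {2, 3}, {2})
        assert regions["A_only"] == {1}
        assert regions["B_only"] == {3}
        assert regions["A_B_C"] == {2}
        for key in ("C_only", "A_B", "A_C", "B_C"):
            assert regions[key] == set()

    def test_disjoint_sets(self):
        regions = scr.venn_partition({1}, {2}, {3})
        assert regions["A_B"] == regions["A_B_C"] == set()
        assert sum(len(v) for v in regions.values()) == 3

    def test_identical_sets_all_triple(self):
        s = {1, 2, 3}
        regions = scr.venn_partition(s, s, s)
        assert regions["A_B_C"] == s
        assert sum(len(v) for k, v in regions.items() if k != "A_B_C") == 0

    def test_counts_partition_union(self):
        rng = np.random.default_rng(1)
        a = set(rng.integers(0, 50, 20).tolist())
        b = set(rng.integers(0, 50, 20).tolist())
        c = set(rng.integers(0, 50, 20).tolist())
        regions = scr.venn_partition(a, b, c)
        assert sum(len(v) for v in regions.values()) == len(a | b | c)


class TestFoldChange:
    def test_identical_groups_fc_one(self):
        mat = pd.DataFrame(
            [[1.0, 1.0, 2.0, 2.0]], index=["p"], columns=list("abcd")
        )
        fc = scr.protein_fold_change(mat, ["a", "c"], ["b", "d"])
        assert fc.loc["p", "log2_fc"] == pytest.approx(0.0)
        assert fc.loc["p", "linear_fc"] == pytest.approx(1.0)

    def test_one_log2_unit_is_twofold(self):
        mat = pd.DataFrame([[11.0, 11.0, 10.0, 10.0]], index=["p"], columns=list("abcd"))
        fc = scr.protein_fold_change(mat, ["a", "b"], ["c", "d"])
        assert fc.loc["p", "linear_fc"] == pytest.approx(2.0)
        assert fc.loc["p", "direction"] == "up"

    def test_planted_reduction_recovered(self):
        rng = np.random.default_rng(21)
        pre = 15.0 + rng.normal(0, 0.05, 20)
        post = pre - np.log2(1.5)
        mat = pd.DataFrame(
            [np.concatenate([pre, post])],
            index=["p"],
            columns=[f"s{i}" for i in range(40)],
        )
        fc = scr.protein_fold_change(mat, [f"s{i}" for i in range(20, 40)], [f"s{i}" for i in range(20)])
        assert fc.loc["p", "linear_fc"] == pytest.approx(1.5, abs=0.05)
        assert fc.loc["p", "direction"] == "down"

    def test_absent_group_flagged(self):
        mat = pd.DataFrame([[1.0, np.nan]], index=["p"], columns=["a", "b"])
        fc = scr.protein_fold_change(mat, ["a"], ["b"])
        assert not fc.loc["p", "defined"]


class TestAnova:
    def test_hand_computed_three_groups(self):
        # sums of squares by hand for values: g1=(1,2), g2=(3,5), g3=(8,9)
        mat = pd.DataFrame([[1.0, 2.0, 3.0, 5.0, 8.0, 9.0]], index=["p"],
                           columns=list("abcdef"))
        groups = pd.Series(["g1", "g1", "g2", "g2", "g3", "g3"], index=list("abcdef"))
        res = scr.anova_protein(mat, groups)
        means = np.array([1.5, 4.0, 8.5])
        grand = mat.loc["p"].mean()
        ss_between = 2 * ((means - grand) ** 2).sum()
        ss_within = 0.5 + 2.0 + 0.5
        f_hand = (ss_between / 2) / (ss_within / 3)
        assert res.loc["p", "F"] == pytest.approx(f_hand, abs=1e-10)
        sp_f, sp_p = stats.f_oneway([1.0, 2.0], [3.0, 5.0], [8.0, 9.0])
        assert res.loc["p", "p"] == pytest.approx(sp_p, abs=1e-12)

    def test_null_f_expectation_near_one(self):
        rng = np.random.default_rng(30)
        mat = pd.DataFrame(rng.normal(size=(4000, 20)),
                           columns=[f"s{i}" for i in range(20)])
        groups = pd.Series(["a"] * 10 + ["b"] * 10, index=mat.columns)
        res = scr.anova_protein(mat, groups)
        # E[F] = dfw/(dfw-2) = 18/16 = 1.125 under the null
        assert res["F"].mean() == pytest.approx(18 / 16, abs=0.08)

    def test_degenerate_groups_flagged(self):
        mat = pd.DataFrame([[1.0, 2.0, np.nan, np.nan]], index=["p"], columns=list("abcd"))
        groups = pd.Series(["g1", "g1", "g2", "g2"], index=list("abcd"))
        res = scr.anova_protein(mat, groups)
        assert not res.loc["p", "ok"]

    def test_missing_data_path_matches_scipy(self):
        rng = np.random.default_rng(31)
        x = rng.normal(size=12)
        x[3] = np.nan
        mat = pd.DataFrame([x], index=["p"], columns=[f"s{i}" for i in range(12)])
        groups = pd.Series(["a"] * 6 + ["b"] * 6, index=mat.columns)
        res = scr.anova_protein(mat, groups)
        g1 = np.delete(x[:6], 3)
        sp_f, sp_p = stats.f_oneway(g1, x[6:])
        assert res.loc["p", "F"] == pytest.approx(sp_f, abs=1e-10)


def test_benjamini_hochberg_matches_statsmodels():
    sm = pytest.importorskip("statsmodels.stats.multitest")
    rng = np.random.default_rng(14)
    p = rng.uniform(size=200)
    ours = scr.benjamini_hochberg(p)
    theirs = sm.multipletests(p, method="fdr_bh")[1]
    assert np.allclose(ours, theirs, atol=1e-12)
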