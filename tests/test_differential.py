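"""Rank-sum tests, corrections, regulon/gene differential calls, DETGs."""

import itertools

import anndata as ad
import numpy as np
import pandas as pd
import pytest

from regulonkit import differential as dd
from regulonkit.consensus import aggregate_runs
from regulonkit.grn import RunRegulon


def enumeration_wilcoxon_p(x, y):
    """Oracle: exact two-sided p by explicit enumeration of all group
    assignments of the pooled sample (tie-free data)."""
    from scipy.stats import rankdata

    pooled = np.concatenate([x, y])
    n1 = len(x)
    n = len(pooled)
    ranks = rankdata(pooled)
    center = n1 * (n - n1) / 2

    def u_of(idx):
        rs = ranks[list(idx)].sum()
        return rs - n1 * (n1 + 1) / 2

    obs = abs(u_of(range(n1)) - center)
    total = hits = 0
    for comb in itertools.combinations(range(n), n1):
        total += 1
        if abs(u_of(comb) - center) >= obs - 1e-12:
            hits += 1
    return hits / total


class TestWilcoxon:
    def test_worked_exact_example(self):
        u, p = dd.wilcoxon_rank_sum([1, 2], [3, 4], mode="exact")
        assert u == 0
        assert p == pytest.approx(2 / 6)

    def test_identical_samples_p_one(self):
        _, p = dd.wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], mode="normal")
        assert p > 0.9

    def test_exact_matches_enumeration_oracle(self, rng):
        for _ in range(10):
            n1, n2 = int(rng.integers(2, 6)), int(rng.integers(2, 6))
            pooled = rng.permutation(np.arange(1.0, n1 + n2 + 1))
            x, y = pooled[:n1], pooled[n1:]
            _, p = dd.wilcoxon_rank_sum(x, y, mode="exact")
            assert p == pytest.approx(enumeration_wilcoxon_p(x, y), abs=1e-12)

    def test_normal_close_to_permutation_at_n20(self, rng):
        x = rng.normal(size=20)
        y = rng.normal(size=20) + 0.3
        _, p_norm = dd.wilcoxon_rank_sum(x, y, mode="normal")
        # Monte-Carlo permutation oracle
        from scipy.stats import rankdata

        pooled = np.concatenate([x, y])
        ranks = rankdata(pooled)
        obs = abs(ranks[:20].sum() - ranks.sum() / 2)
        hits = 0
        B = 100_000
        for _ in range(B):
            perm = rng.permutation(ranks)
            if abs(perm[:20].sum() - ranks.sum() / 2) >= obs - 1e-9:
                hits += 1
        assert abs(p_norm - hits / B) < 0.01

    def test_exact_mode_preconditions(self):
        with pytest.raises(ValueError, match="16"):
            dd.wilcoxon_rank_sum(np.arange(10), np.arange(10) + 100, mode="exact")
        with pytest.raises(ValueError, match="tie"):
            dd.wilcoxon_rank_sum([1, 1], [2, 3], mode="exact")
        with pytest.raises(ValueError, match="empty"):
            dd.wilcoxon_rank_sum([], [1], mode="normal")


class TestCorrections:
    def test_single_p_unchanged(self):
        assert dd.bh_fdr([0.03]) == [0.03]

    def test_hand_step_up(self):
        np.testing.assert_allclose(dd.bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_adjusted_not_below_raw_and_monotone(self, rng):
        p = rng.random(50)
        adj = np.array(dd.bh_fdr(list(p)))
        assert (adj >= p - 1e-15).all()
        p2 = p.copy()
        p2[10] = min(1.0, p2[10] + 0.3)
        adj2 = np.array(dd.bh_fdr(list(p2)))
        assert (adj2 >= adj - 1e-12).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            dd.bh_fdr([0.5, 1.2])

    @pytest.mark.parametrize(
        "p,m,expected", [(0.001, 100, 0.1), (0.5, 10, 1.0), (0.2, 1, 0.2)]
    )
    def test_bonferroni_closed_form(self, p, m, expected):
        assert dd.bonferroni([p], m) == [pytest.approx(expected)]

    def test_bonferroni_m_smaller_than_tests_rejected(self):
        with pytest.raises(ValueError):
            dd.bonferroni([0.1, 0.2], m=1)


class TestDifferentialRegulons:
    @staticmethod
    def _auc(rng, n_a=40, n_b=40, shift=0.0):
        cells = [f"a{i}" for i in range(n_a)] + [f"b{i}" for i in range(n_b)]
        base = rng.random(n_a + n_b) * 0.5
        base[:n_a] += shift
        return (
            pd.DataFrame({"R": base}, index=cells),
            [f"a{i}" for i in range(n_a)],
            [f"b{i}" for i in range(n_b)],
        )

    def test_small_shift_fails_delta_gate(self, rng):
        auc, a, b = self._auc(rng, shift=0.1)
        res = dd.differential_regulons(auc, a, b, alpha=0.05, min_abs_auc_diff=0.15)
        assert res.iloc[0]["p_adj"] < 0.05
        assert not res.iloc[0]["significant"]

    def test_large_shift_significant(self, rng):
        auc, a, b = self._auc(rng, shift=0.3)
        res = dd.differential_regulons(auc, a, b)
        assert bool(res.iloc[0]["significant"])

    def test_group_swap_antisymmetric(self, rng):
        auc, a, b = self._auc(rng, shift=0.2)
        r1 = dd.differential_regulons(auc, a, b)
        r2 = dd.differential_regulons(auc, b, a)
        assert r1.iloc[0]["delta_auc"] == pytest.approx(-r2.iloc[0]["delta_auc"])
        assert r1.iloc[0]["p"] == pytest.approx(r2.iloc[0]["p"], rel=1e-9)

    def test_overlapping_groups_rejected(self, rng):
        auc, a, b = self._auc(rng)
        with pytest.raises(ValueError):
            dd.differential_regulons(auc, a, a)

    def test_null_false_positive_rate_controlled(self, rng):
        # exchangeable pool: significant fraction across many replicates <= alpha
        n_sig = n_tot = 0
        for _ in range(200):
            auc = pd.DataFrame(
                rng.random((60, 4)), columns=list("wxyz"),
                index=[f"c{i}" for i in range(60)],
            )
            res = dd.differential_regulons(
                auc, [f"c{i}" for i in range(30)], [f"c{i}" for i in range(30, 60)],
                min_abs_auc_diff=0.0,
            )
            n_sig += int(res["significant"].sum())
            n_tot += len(res)
        rate = n_sig / n_tot
        se = np.sqrt(0.05 * 0.95 / n_tot)
        assert rate <= 0.05 + 3 * se


class TestFoldChange:
    def test_ratio_1p5_gives_0585(self):
        g1 = np.log1p(np.full(50, 15.0))
        g2 = np.log1p(np.full(50, 10.0))
        assert dd.log2_fold_change(g1, g2, pseudocount=1e-9) == pytest.approx(
            np.log2(1.5), abs=1e-6
        )

    def test_identical_groups_zero(self, rng):
        x = rng.random(30)
        assert dd.log2_fold_change(x, x) == 0.0

    def test_swap_negates(self, rng):
        x, y = rng.random(30), rng.random(30)
        assert dd.log2_fold_change(x, y) == pytest.approx(-dd.log2_fold_change(y, x))


def _norm_adata(X, cells=None):
    cells = cells or [f"c{i}" for i in range(X.shape[0])]
    return ad.AnnData(
        X=np.asarray(X, dtype=float),
        obs=pd.DataFrame(index=pd.Index(cells, name="cell")),
        var=pd.DataFrame(index=pd.Index([f"g{j}" for j in range(X.shape[1])], name="gene")),
    )


class TestHurdle:
    def test_label_permutation_of_identical_sample_null(self, rng):
        half = np.log1p(rng.poisson(3.0, size=(40, 5)))
        X = np.vstack([half, half])
        norm = _norm_adata(X)
        labels = pd.Series(["g1"] * 40 + ["g2"] * 40, index=norm.obs_names)
        res = dd.hurdle_de_test(norm, labels)
        assert (res["p"] > 0.9).all()
        assert (res["stat"].fillna(0) < 1e-8).all()

    def test_matches_statsmodels_lrt(self, rng):
        import statsmodels.api as sm
        from scipy.stats import chi2

        X = np.log1p(rng.poisson(2.0, size=(120, 6)).astype(float))
        X[rng.random(X.shape) < 0.3] = 0.0
        norm = _norm_adata(X)
        labels = pd.Series(["g1"] * 60 + ["g2"] * 60, index=norm.obs_names)
        res = dd.hurdle_de_test(norm, labels).set_index("gene")
        group = np.array([1.0] * 60 + [0.0] * 60)
        for j in range(6):
            col = X[:, j]
            det = (col > 0).astype(float)
            lr_full = sm.Logit(det, sm.add_constant(group)).fit(disp=0)
            lr_null = sm.Logit(det, np.ones((120, 1))).fit(disp=0)
            chi_d = 2 * (lr_full.llf - lr_null.llf)
            pos = col > 0
            ols_full = sm.OLS(col[pos], sm.add_constant(group[pos])).fit()
            ols_null = sm.OLS(col[pos], np.ones((pos.sum(), 1))).fit()
            chi_c = 2 * (ols_full.llf - ols_null.llf)
            stat = chi_d + chi_c
            assert res.loc[f"g{j}", "stat"] == pytest.approx(stat, abs=1e-6)
            assert res.loc[f"g{j}", "p"] == pytest.approx(chi2.sf(stat, 2), abs=1e-8)

    def test_full_detection_reduces_to_gaussian_part(self, rng):
        X = np.log1p(rng.poisson(5.0, size=(60, 4)) + 1.0)  # never zero
        norm = _norm_adata(X)
        labels = pd.Series(["g1"] * 30 + ["g2"] * 30, index=norm.obs_names)
        res = dd.hurdle_de_test(norm, labels)
        assert np.allclose(res["chi2_detection"], 0.0)
        assert np.allclose(res["stat"], res["chi2_positive"])

    def test_sparse_gene_flagged_with_p_one(self, rng):
        X = np.log1p(rng.poisson(3.0, size=(30, 2)).astype(float))
        X[:, 1] = 0.0
        X[0, 1] = 1.0
        norm = _norm_adata(X)
        labels = pd.Series(["g1"] * 15 + ["g2"] * 15, index=norm.obs_names)
        res = dd.hurdle_de_test(norm, labels).set_index("gene")
        assert res.loc["g1", "flag"] == "insufficient_cells"
        assert res.loc["g1", "p"] == 1.0

    def test_covariate_mode_runs_and_stays_calibrated_on_null(self, rng):
        X = np.log1p(rng.poisson(2.0, size=(80, 10)).astype(float))
        X[rng.random(X.shape) < 0.3] = 0.0
        norm = _norm_adata(X)
        labels = pd.Series(["g1"] * 40 + ["g2"] * 40, index=norm.obs_names)
        res = dd.hurdle_de_test(norm, labels, include_detection_covariate=True)
        assert (res["p"] > 0.001).all()


class TestDegFilterAndDetgs:
    def test_gate_logic_on_hand_built_table(self):
        stats = pd.DataFrame(
            {
                "gene": list("abcdef"),
                "p": [1e-6, 1e-6, 1e-6, 0.5, 1e-6, 1e-6],
                "pct_1": [0.10, 0.50, 0.50, 0.50, 0.50, 0.50],
                "pct_2": [0.10, 0.45, 0.10, 0.10, 0.10, 0.10],
                "log2fc": [2.0, 2.0, 0.50, 2.0, 2.0, -2.0],
            }
        )
        out = dd.deg_filter(stats, lfc_threshold=0.585, min_pct=0.15,
                            min_diff_pct=0.15, alpha=0.05, m=6)
        # a fails min_pct, b fails min_diff_pct, c fails lfc, d fails p
        assert sorted(out["gene"]) == ["e", "f"]
        assert dict(zip(out["gene"], out["direction"])) == {"e": "up", "f": "down"}

    def _regulon(self):
        runs = [[RunRegulon("T", ["a", "b", "c"], {"a": 3.0, "b": 2.0, "c": 1.0})]] * 2
        return aggregate_runs(runs)[0]

    def test_disjoint_sets_empty(self):
        degs = pd.DataFrame({"gene": ["x", "y"], "p_adj": [0.01, 0.01]})
        assert len(dd.extract_detgs(self._regulon(), degs)) == 0

    def test_subset_degs_all_returned_in_rank_order(self):
        degs = pd.DataFrame({"gene": ["c", "a"], "p_adj": [0.01, 0.02]})
        out = dd.extract_detgs(self._regulon(), degs)
        assert list(out["gene"]) == ["a", "c"]
        assert list(out["rank"]) == [1, 3]
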