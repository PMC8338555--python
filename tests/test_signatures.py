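import itertools

import numpy as np
import pandas as pd
import pytest

from festflow.signatures import (
    CHECKPOINT_GENES,
    GeneSet,
    checkpoint_score,
    default_exhaustion_set,
    dose_response_summary,
    marker_genes,
    module_score,
    rank_sum_pvalue,
    score_correlated_genes,
)


def make_expr(rng, n_cells=400, n_genes=120, extra_genes=(), flat=False):
    genes = [f"G{i:03d}" for i in range(n_genes)] + list(extra_genes)
    if flat:
        base = np.full(len(genes), 2.0)  # exchangeable genes: E[score] = 0
    else:
        base = rng.gamma(2.0, 1.0, size=len(genes))  # heterogeneous gene means
    X = rng.normal(base, 0.5, size=(n_cells, len(genes)))
    return pd.DataFrame(X, columns=genes,
                        index=[f"c{i}" for i in range(n_cells)])


class TestModuleScore:
    def test_random_set_scores_near_zero(self, rng):
        expr = make_expr(rng, n_cells=2000, flat=True)
        gene_set = GeneSet("random", tuple(rng.choice(expr.columns, 15, replace=False)))
        score = module_score(expr, gene_set, seed=0)
        assert abs(score.mean()) < 0.02

    def test_shift_invariance_to_global_constant(self, rng):
        expr = make_expr(rng)
        gene_set = GeneSet("s", tuple(expr.columns[:10]))
        s1 = module_score(expr, gene_set, seed=3)
        s2 = module_score(expr + 7.5, gene_set, seed=3)
        np.testing.assert_allclose(s1, s2, atol=1e-6)

    def test_planted_subpopulation_shift_recovered(self, rng):
        # large gene universe keeps shifted genes from dominating any
        # control bin, so the recovered shift stays close to the planted one
        expr = make_expr(rng, n_cells=1000, n_genes=600)
        gene_set = GeneSet("prog", tuple(expr.columns[:12]))
        sub = np.zeros(len(expr), dtype=bool)
        sub[:250] = True
        expr.loc[sub, list(gene_set.genes)] += 1.0
        score = module_score(expr, gene_set, seed=0)
        diff = score[sub].mean() - score[~sub].mean()
        assert diff == pytest.approx(1.0, abs=0.1)

    def test_seed_reproducibility(self, rng):
        expr = make_expr(rng)
        gene_set = GeneSet("s", tuple(expr.columns[:8]))
        np.testing.assert_array_equal(
            module_score(expr, gene_set, seed=5),
            module_score(expr, gene_set, seed=5))

    def test_missing_genes_dropped_with_warning(self, rng):
        expr = make_expr(rng)
        gene_set = GeneSet("s", ("G000", "NOT_A_GENE"))
        with pytest.warns(UserWarning, match="absent"):
            module_score(expr, gene_set, seed=0)

    def test_fully_missing_set_is_error(self, rng):
        expr = make_expr(rng)
        with pytest.raises(ValueError):
            with pytest.warns(UserWarning):
                module_score(expr, GeneSet("s", ("NOPE1", "NOPE2")), seed=0)


class TestCheckpointScore:
    def test_high_checkpoint_cells_score_higher(self, rng):
        expr = make_expr(rng, extra_genes=CHECKPOINT_GENES)
        hi = np.zeros(len(expr), dtype=bool)
        hi[:150] = True
        expr.loc[hi, list(CHECKPOINT_GENES)] += 2.0
        score = checkpoint_score(expr, seed=0)
        assert score[hi].mean() > score[~hi].mean() + 1.0
        # group shift detectable by rank-sum
        assert rank_sum_pvalue(score[hi].to_numpy(), score[~hi].to_numpy()) < 1e-6

    def test_missing_member_warns(self, rng):
        expr = make_expr(rng, extra_genes=CHECKPOINT_GENES[:5])
        with pytest.warns(UserWarning, match="absent"):
            checkpoint_score(expr, seed=0)

    def test_cell_order_permutation_permutes_scores(self, rng):
        expr = make_expr(rng, extra_genes=CHECKPOINT_GENES)
        s1 = checkpoint_score(expr, seed=2)
        perm = rng.permutation(expr.index)
        s2 = checkpoint_score(expr.loc[perm], seed=2)
        np.testing.assert_allclose(s1.loc[perm], s2)

    def test_packaged_exhaustion_list_loads(self):
        gs = default_exhaustion_set()
        assert len(gs.genes) >= 10


class TestScoreCorrelatedGenes:
    def test_gene_equal_to_score_ranked_first(self, rng):
        expr = make_expr(rng)
        score = expr["G007"].copy()
        out = score_correlated_genes(expr, score, top_k=5)
        assert out.iloc[0]["gene"] == "G007"
        assert out.iloc[0]["correlation"] == pytest.approx(1.0)

    def test_excluded_genes_never_appear(self, rng):
        expr = make_expr(rng, extra_genes=CHECKPOINT_GENES)
        score = checkpoint_score(expr, seed=0)
        out = score_correlated_genes(
            expr, score, exclude=GeneSet("cp", CHECKPOINT_GENES), top_k=30)
        assert not set(out["gene"]) & set(CHECKPOINT_GENES)

    def test_constant_gene_flagged_zero(self, rng):
        expr = make_expr(rng, n_genes=30)
        expr["FLAT"] = 1.0
        out = score_correlated_genes(expr, expr["G000"], top_k=31)
        row = out.set_index("gene").loc["FLAT"]
        assert row["correlation"] == 0.0 and row["constant"]

    def test_group_specific_correlation_difference(self, rng):
        expr = make_expr(rng, n_cells=600, n_genes=40)
        groups = pd.Series(["MPR"] * 300 + ["nonMPR"] * 300, index=expr.index)
        score = pd.Series(rng.normal(size=600), index=expr.index)
        expr["TARGET"] = rng.normal(size=600) * 0.6
        expr.loc[groups == "MPR", "TARGET"] += 0.8 * score[groups == "MPR"]
        out = score_correlated_genes(expr, score, groups=groups, top_k=41)
        row = out.set_index("gene").loc["TARGET"]
        assert row["correlation_MPR"] > 0.5
        assert abs(row["correlation_nonMPR"]) < 0.25
        assert row["correlation_diff"] > 0.4


def exact_rank_sum_p(x, y):
    """Enumeration oracle: two-sided p of the rank-sum statistic over all
    assignments of the pooled values to the two groups."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = pd.Series(pooled).rank().to_numpy()
    obs = ranks[:n1].sum()
    mu = n1 * (len(pooled) + 1) / 2
    count = total = 0
    for comb in itertools.combinations(range(len(pooled)), n1):
        stat = ranks[list(comb)].sum()
        total += 1
        if abs(stat - mu) >= abs(obs - mu) - 1e-9:
            count += 1
    return count / total


class TestMarkerGenes:
    def test_identical_groups_yield_no_markers(self, rng):
        expr = make_expr(rng, n_cells=100, n_genes=30)
        groups = pd.Series(["a"] * 50 + ["b"] * 50, index=expr.index)
        out = marker_genes(expr, groups)
        assert len(out) == 0

    @pytest.mark.parametrize("n1,n2", [(5, 5), (8, 6), (4, 8)])
    def test_rank_sum_matches_enumeration_oracle(self, rng, n1, n2):
        x, y = rng.normal(size=n1), rng.normal(1.0, 1.0, size=n2)
        assert rank_sum_pvalue(x, y) == pytest.approx(exact_rank_sum_p(x, y), abs=1e-9)

    def test_planted_fold_changes_thresholded(self, rng):
        # two groups; planted genes at log2FC = 1 recovered, ~0.14 excluded
        n = 300
        genes = [f"g{i}" for i in range(40)]
        X = rng.normal(1.0, 0.3, size=(2 * n, 40)).clip(min=0)
        expr = pd.DataFrame(X, columns=genes,
                            index=[f"c{i}" for i in range(2 * n)])
        groups = pd.Series(["hi"] * n + ["lo"] * n, index=expr.index)
        strong, weak = genes[:5], genes[5:10]
        base = np.expm1(expr.loc[groups == "hi", strong])
        expr.loc[groups == "hi", strong] = np.log1p(2 * base + 1)  # ~2-fold
        expr.loc[groups == "hi", weak] = np.log1p(
            1.1 * np.expm1(expr.loc[groups == "hi", weak]))        # ~1.1-fold
        out = marker_genes(expr, groups)
        hi_markers = set(out.loc[out["group"] == "hi", "gene"])
        assert set(strong) <= hi_markers
        assert not set(weak) & hi_markers

    def test_bonferroni_is_p_times_m(self, rng):
        expr = make_expr(rng, n_cells=60, n_genes=25)
        groups = pd.Series(["a"] * 30 + ["b"] * 30, index=expr.index)
        expr.loc[groups == "a", "G000"] += 2.0
        out = marker_genes(expr, groups, lfc_min=0.0, min_pct=0.0, alpha=1.0)
        row = out.set_index(["group", "gene"]).loc[("a", "G000")]
        assert row["p_adj"] == pytest.approx(min(1.0, row["p_value"] * 25))

    def test_small_group_skipped_with_warning(self, rng):
        expr = make_expr(rng, n_cells=20, n_genes=30)
        groups = pd.Series(["a"] * 2 + ["b"] * 18, index=expr.index)
        with pytest.warns(UserWarning, match="fewer than"):
            marker_genes(expr, groups)


class TestDoseResponse:
    def test_constant_scores_have_zero_sem(self):
        scores = pd.Series([1.0] * 12)
        dose = pd.Series([1, 1, 10, 10, 100, 100] * 2)
        group = pd.Series(["MANA"] * 6 + ["flu"] * 6)
        out = dose_response_summary(scores, dose, group)
        assert (out["sem"].dropna() == 0).all()

    def test_planted_trend_detected_only_in_responsive_group(self, rng):
        doses = np.repeat([1.0, 10.0, 100.0, 1000.0], 40)
        dose = pd.Series(np.tile(doses, 2))
        group = pd.Series(["resp"] * 160 + ["flat"] * 160)
        scores = pd.Series(np.where(group == "resp",
                                    0.3 * np.log(dose) + rng.normal(0, 0.3, 320),
                                    rng.normal(0, 0.3, 320)))
        out = dose_response_summary(scores, dose, group).drop_duplicates("group")
        by = out.set_index("group")
        assert by.loc["resp", "spearman_rho"] > 0.5
        assert by.loc["resp", "spearman_p"] < 1e-4
        assert abs(by.loc["flat", "spearman_rho"]) < 0.2

    def test_group_means_aggregate_to_overall_mean(self, rng):
        scores = pd.Series(rng.normal(size=60))
        dose = pd.Series([1, 10] * 30)
        group = pd.Series(["a"] * 30 + ["b"] * 30)
        out = dose_response_summary(scores, dose, group)
        weighted = (out["mean"] * out["n"]).sum() / out["n"].sum()
        assert weighted == pytest.approx(scores.mean())

    def test_single_dose_rejected(self):
        with pytest.raises(ValueError):
            dose_response_summary(pd.Series([1.0, 2.0]), pd.Series([5, 5]),
                                  pd.Series(["a", "a"]))
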