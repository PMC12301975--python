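"""Transcriptome statistics: filters, ranking, GSEA, length imbalance,
signatures, immune scores and the simple DE test, checked against hand
computations and brute-force oracles."""

import itertools
import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from kosynergy import (
    bh_adjust,
    call_degs,
    core_signature,
    filter_expressed,
    foldchange_comparison,
    gsea_preranked,
    immune_score,
    length_imbalance,
    make_ranked_list,
    rank_metric,
    simple_de_test,
    wilcoxon_ranksum,
)


def deg_table(rows):
    """Rows of (gene_id, log2fc, padj[, length])."""
    return pd.DataFrame(
        [
            {
                "gene_id": r[0],
                "log2fc": r[1],
                "pvalue": r[2] / 2,
                "padj": r[2],
                "mean_count": 100.0,
                "transcript_length": r[3] if len(r) > 3 else 1000,
            }
            for r in rows
        ]
    )


class TestFilterExpressed:
    def test_boundary_strictly_above_ten_in_exactly_three(self):
        counts = pd.DataFrame(
            {
                "s1": [11, 10, 0],
                "s2": [11, 10, 0],
                "s3": [11, 10, 0],
                "s4": [0, 10, 0],
            },
            index=["pass", "at_threshold", "zero"],
        )
        assert filter_expressed(counts) == ["pass"]

    def test_all_zero_matrix_gives_empty_list(self):
        counts = pd.DataFrame(np.zeros((4, 5), dtype=int))
        assert filter_expressed(counts) == []

    def test_engineered_toy_matrix(self):
        counts = pd.DataFrame(
            [
                [50, 60, 70, 0, 0, 0],
                [11, 12, 13, 14, 0, 0],
                [11, 11, 0, 0, 0, 0],
                [9, 9, 9, 9, 9, 9],
                [0, 0, 0, 0, 0, 0],
            ],
            index=list("abcde"),
        )
        assert filter_expressed(counts) == ["a", "b"]

    def test_too_few_samples_warns(self):
        counts = pd.DataFrame([[100, 100]], index=["g"])
        with pytest.warns(UserWarning):
            assert filter_expressed(counts) == []


class TestBHAdjust:
    def test_hand_computed_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    def test_dominates_input_and_is_permutation_equivariant(self, pvals):
        p = np.array(pvals)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-12).all()
        assert (adj <= 1.0 + 1e-12).all()
        perm = np.random.default_rng(0).permutation(p.size)
        np.testing.assert_allclose(bh_adjust(p[perm]), adj[perm])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestCallDegs:
    def test_thresholds_are_strict(self):
        table = deg_table(
            [
                ("at_fc", 1.0, 0.01),
                ("up", 2.0, 0.04),
                ("down_ns", -1.5, 0.06),
                ("down", -1.2, 0.01),
                ("at_padj", 1.4, 0.05),
            ]
        )
        up, down = call_degs(table)
        assert up == {"up"}
        assert down == {"down"}


class TestRankMetric:
    @pytest.mark.parametrize(
        "padj,lfc,expected",
        [(0.01, 3.0, 2.0), (0.05, -2.0, math.log10(0.05)), (1.0, 5.0, 0.0)],
    )
    def test_worked_values(self, padj, lfc, expected):
        assert rank_metric(padj, lfc) == pytest.approx(expected)

    def test_zero_padj_clamped_with_warning(self):
        with pytest.warns(UserWarning):
            v = rank_metric(0.0, 2.0)
        assert np.isfinite(v) and v == pytest.approx(300.0)

    def test_zero_fold_change_scores_zero_with_warning(self):
        with pytest.warns(UserWarning):
            assert rank_metric(0.01, 0.0) == 0.0

    @settings(deadline=None, derandomize=True)
    @given(
        st.floats(min_value=1e-10, max_value=1.0),
        st.floats(min_value=0.01, max_value=10.0),
    )
    def test_antisymmetric_in_sign(self, padj, lfc):
        assert rank_metric(padj, -lfc) == pytest.approx(-rank_metric(padj, lfc))

    def test_monotone_decreasing_in_padj(self):
        assert rank_metric(0.001, 1.0) > rank_metric(0.01, 1.0) > rank_metric(0.5, 1.0)

    def test_ranked_list_breaks_ties_by_gene_id(self):
        table = deg_table([("zeta", 2.0, 0.01), ("alpha", 2.0, 0.01), ("mid", 1.0, 0.5)])
        ranked = make_ranked_list(table)
        assert list(ranked.index) == ["alpha", "zeta", "mid"]
        assert (np.diff(ranked.to_numpy()) <= 0).all()


def brute_force_es(scores, hit_mask, weight):
    """Independent running-sum oracle: walk the full list, increment on hits
    by |score|^weight (normalised), decrement on misses by 1/(N-k); return
    the deviation of maximum magnitude."""
    scores = np.asarray(scores, dtype=float)
    n = scores.size
    k = int(hit_mask.sum())
    w = np.abs(scores) ** weight
    w_sum = w[hit_mask].sum()
    running = 0.0
    best = 0.0
    for i in range(n):
        if hit_mask[i]:
            running += w[i] / w_sum
        else:
            running -= 1.0 / (n - k)
        # strict improvement keeps the first-reached extreme on magnitude ties
        if abs(running) > abs(best) + 1e-12:
            best = running
    return best


class TestGseaPreranked:
    def ranked(self, scores):
        return pd.Series(
            np.asarray(scores, dtype=float),
            index=[f"g{i:02d}" for i in range(len(scores))],
        )

    def test_top_block_reaches_maximal_enrichment(self):
        ranked = self.ranked([5, 4, 3, 2, 1, -1, -2, -3, -4, -5])
        res = gsea_preranked(
            ranked, {"top": {"g00", "g01", "g02"}}, weight=0.0, n_perm=200,
            min_size=2, seed=0,
        )[0]
        assert res.es == pytest.approx(1.0)
        assert res.leading_edge == ["g00", "g01", "g02"]

    def test_bottom_block_scores_negative(self):
        ranked = self.ranked([5, 4, 3, 2, 1, -1, -2, -3, -4, -5])
        res = gsea_preranked(
            ranked, {"bottom": {"g07", "g08", "g09"}}, weight=1.0, n_perm=200,
            min_size=2, seed=0,
        )[0]
        assert res.es < 0
        assert set(res.leading_edge) <= {"g07", "g08", "g09"}

    @pytest.mark.parametrize("weight", [0.0, 1.0])
    def test_es_matches_brute_force_oracle_exhaustively(self, weight, rng):
        """Every subset of size 2-4 of every list length 5-8."""
        for n in range(5, 9):
            scores = np.sort(rng.normal(0, 2, n))[::-1]
            ranked = self.ranked(scores)
            genes = list(ranked.index)
            for k in (2, 3, 4):
                for combo in itertools.combinations(range(n), k):
                    mask = np.zeros(n, dtype=bool)
                    mask[list(combo)] = True
                    expected = brute_force_es(scores, mask, weight)
                    res = gsea_preranked(
                        ranked, {"s": {genes[i] for i in combo}}, weight=weight,
                        n_perm=100, min_size=2, seed=0,
                    )[0]
                    assert res.es == pytest.approx(expected, abs=1e-12)

    def test_deterministic_under_seed_and_sensitive_to_it(self):
        rng = np.random.default_rng(5)
        ranked = self.ranked(np.sort(rng.normal(0, 2, 200))[::-1])
        genes = list(ranked.index)
        sets = {"a": set(genes[:20]), "b": set(genes[50:70])}
        r1 = gsea_preranked(ranked, sets, n_perm=300, seed=11)
        r2 = gsea_preranked(ranked, sets, n_perm=300, seed=11)
        assert [(x.nes, x.p_perm, x.fdr) for x in r1] == [
            (x.nes, x.p_perm, x.fdr) for x in r2
        ]

    def test_size_gates_skip_sets_with_warning(self):
        ranked = self.ranked(range(30, 0, -1))
        with pytest.warns(UserWarning, match="skipped"):
            res = gsea_preranked(
                ranked, {"tiny": {"g00", "g01"}}, n_perm=100, min_size=15, seed=0
            )
        assert res == []

    def test_empty_intersection_rejected(self):
        ranked = self.ranked([3, 2, 1])
        with pytest.raises(ValueError, match="empty intersection"):
            gsea_preranked(ranked, {"none": {"absent"}}, n_perm=100, min_size=1, seed=0)

    def test_planted_up_set_enriched_at_top(self):
        """GSEA recovers a planted enrichment from the DE generator."""
        from kosynergy import SimulationConfig, simulate_deg_table

        table, truth = simulate_deg_table(SimulationConfig(n_genes=2000, seed=13))
        ranked = make_ranked_list(table)
        sets = {
            "up": set(truth.gene_sets["planted_up"]),
            "down": set(truth.gene_sets["planted_down"]),
            "decoy": set(truth.gene_sets["decoy_null"]),
        }
        res = {r.name: r for r in gsea_preranked(ranked, sets, n_perm=300, seed=3)}
        assert res["up"].es > 0.5 and res["up"].p_perm < 0.01
        assert res["down"].es < -0.5 and res["down"].p_perm < 0.01
        assert res["decoy"].p_perm > 0.05


def enumerate_ranksum_p(x, y):
    """Oracle: exact two-sided rank-sum p over all group assignments."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    m = len(x)
    center = m * (len(pooled) + 1) / 2
    obs = abs(ranks[:m].sum() - center)
    assignments = list(itertools.combinations(range(len(pooled)), m))
    hits = sum(
        1 for c in assignments if abs(ranks[list(c)].sum() - center) >= obs - 1e-12
    )
    return hits / len(assignments)


class TestWilcoxonRanksum:
    def test_extreme_two_vs_two_is_one_third(self):
        _, p = wilcoxon_ranksum([1, 2], [3, 4])
        assert p == pytest.approx(1 / 3)

    def test_identical_samples_give_p_one(self):
        _, p = wilcoxon_ranksum([5, 6, 7], [5, 6, 7])
        assert p == pytest.approx(1.0)

    def test_exact_matches_scipy_on_tie_free_samples(self, rng):
        for m, n in [(3, 4), (5, 5), (6, 6), (2, 9)]:
            x = rng.normal(size=m)
            y = rng.normal(size=n)
            _, p = wilcoxon_ranksum(x, y)
            expected = stats.mannwhitneyu(
                x, y, alternative="two-sided", method="exact"
            ).pvalue
            assert p == pytest.approx(expected, rel=1e-9)

    def test_exact_handles_ties_via_enumeration(self):
        x = [1.0, 2.0, 2.0, 5.0]
        y = [2.0, 3.0, 4.0]
        _, p = wilcoxon_ranksum(x, y)
        assert p == pytest.approx(enumerate_ranksum_p(np.array(x), np.array(y)))

    def test_boundary_exact_and_normal_agree(self, rng):
        """At combined n=12 the exact p and the continuity-corrected normal
        approximation differ by less than 0.02."""
        x = rng.normal(0, 1, 6)
        y = rng.normal(0.5, 1, 6)
        _, exact_p = wilcoxon_ranksum(x, y)
        approx_p = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic"
        ).pvalue
        assert abs(exact_p - approx_p) < 0.02

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_ranksum([], [1.0])


class TestLengthImbalance:
    def test_short_up_long_down_worked_example(self):
        table = deg_table(
            [
                ("u1", 2.0, 0.01, 500),
                ("u2", 2.0, 0.01, 600),
                ("d1", -2.0, 0.01, 3000),
                ("d2", -2.0, 0.01, 4000),
                ("ns", 0.1, 0.9, 1000),
            ]
        )
        r = length_imbalance(table)
        assert r.direction == "up-shorter"
        assert r.pvalue == pytest.approx(1 / 3)
        assert r.median_up == 550 and r.median_down == 3500

    def test_no_degs_is_undefined(self):
        table = deg_table([("a", 0.2, 0.9), ("b", -0.1, 0.8)])
        with pytest.raises(ValueError, match="undefined"):
            length_imbalance(table)


class TestCoreSignature:
    def test_three_tissue_worked_example(self):
        sig = core_signature(
            {"T1": {"A", "B", "C"}, "T2": {"B", "C", "D"}, "T3": {"B", "C", "E"}}
        )
        assert sig.intersection == ["B", "C"]
        assert sig.pairwise_overlap[("T1", "T2")] == 2

    def test_disjoint_sets_give_empty_intersection(self):
        sig = core_signature({"a": {"X"}, "b": {"Y"}})
        assert sig.intersection == []

    def test_subset_tissue_dominates(self):
        sig = core_signature({"a": {"X", "Y"}, "b": {"X", "Y", "Z"}, "c": {"X", "Y", "W"}})
        assert sig.intersection == ["X", "Y"]

    def test_order_independent_and_idempotent(self):
        sets = {"a": {"P", "Q", "R"}, "b": {"Q", "R", "S"}, "c": {"R", "Q"}}
        i1 = core_signature(sets).intersection
        i2 = core_signature(dict(reversed(list(sets.items())))).intersection
        assert i1 == i2
        again = core_signature({t: set(i1) | s for t, s in sets.items()})
        assert set(i1) <= set(again.intersection)

    def test_fewer_than_two_tissues_rejected(self):
        with pytest.raises(ValueError):
            core_signature({"only": {"A"}})
        with pytest.raises(ValueError):
            core_signature({})


class TestFoldChangeComparison:
    def test_identical_mappings_give_null_result(self):
        fc = {"a": 1.0, "b": 2.0, "c": 3.0}
        r = foldchange_comparison({"a", "b", "c"}, fc, dict(fc))
        assert r.median_difference == 0.0
        assert r.pvalue == 1.0

    def test_constant_offset_all_positive(self):
        single = {g: float(i) for i, g in enumerate("abcdef")}
        double = {g: v + 0.5 for g, v in single.items()}
        r = foldchange_comparison(set(single), double, single)
        assert r.median_difference == pytest.approx(0.5)
        assert (r.pairs["difference"] > 0).all()

    def test_signed_rank_p_matches_sign_flip_enumeration(self, rng):
        """n=5 pairs: exact signed-rank p equals enumeration of all 2^5 sign
        assignments of the absolute differences."""
        diff = np.array([0.8, -0.3, 1.2, 0.5, -0.9])
        single = {f"g{i}": 0.0 for i in range(5)}
        double = {f"g{i}": diff[i] for i in range(5)}
        ranks = stats.rankdata(np.abs(diff))
        w_obs = ranks[diff > 0].sum()
        total = ranks.sum()
        dev = abs(w_obs - total / 2)
        hits = 0
        for signs in itertools.product([0, 1], repeat=5):
            w = sum(r for r, s in zip(ranks, signs) if s)
            hits += abs(w - total / 2) >= dev - 1e-12
        expected = hits / 2**5
        r = foldchange_comparison(set(single), double, single)
        assert r.pvalue == pytest.approx(expected, rel=1e-9)

    def test_missing_gene_rejected(self):
        with pytest.raises(ValueError):
            foldchange_comparison({"a"}, {"a": 1.0}, {})


class TestImmuneScore:
    def test_constant_matrix_scores_zero(self):
        expr = pd.DataFrame(
            np.full((4, 3), 5.0), index=list("abcd"), columns=["s1", "s2", "s3"]
        )
        scores = immune_score(expr, {"pop": {"a", "b"}})
        assert (scores["pop"] == 0).all()

    def test_doubled_sample_gets_top_score(self):
        expr = pd.DataFrame(
            {"s1": [1.0, 1.0, 9.0], "s2": [2.0, 2.0, 9.0], "s3": [1.0, 1.0, 9.0]},
            index=["m1", "m2", "other"],
        )
        scores = immune_score(expr, {"P": {"m1", "m2"}})
        assert scores["P"].idxmax() == "s2"

    def test_hand_computed_three_sample_scores(self):
        expr = pd.DataFrame(
            {"s1": [1.0, 3.0, 2.0, 0.0], "s2": [2.0, 4.0, 2.0, 0.0],
             "s3": [3.0, 5.0, 2.0, 0.0]},
            index=["m1", "m2", "m3", "m4"],
        )
        scores = immune_score(expr, {"P": {"m1", "m2", "m3", "m4"}})
        # marker means are 1.5, 2.0, 2.5; z-scores (pop. sd) -1.2247, 0, 1.2247
        np.testing.assert_allclose(
            scores["P"].to_numpy(), [-1.22474487, 0.0, 1.22474487], atol=1e-8
        )

    def test_missing_markers_warn_and_sparse_population_skipped(self):
        expr = pd.DataFrame(
            {"s1": [1.0, 2.0], "s2": [2.0, 1.0]}, index=["m1", "m2"]
        )
        with pytest.warns(UserWarning):
            scores = immune_score(
                expr, {"ok": {"m1", "m2", "absent"}, "thin": {"m1", "nope"}}
            )
        assert list(scores.columns) == ["ok"]

    def test_nothing_scorable_rejected(self):
        expr = pd.DataFrame({"s1": [1.0]}, index=["m1"])
        with pytest.raises(ValueError):
            immune_score(expr, {"P": {"x", "y"}})


class TestSimpleDeTest:
    def _null_counts(self, rng, n_genes=200, n=5):
        counts = pd.DataFrame(
            rng.poisson(100, (n_genes, 2 * n)),
            index=[f"g{i}" for i in range(n_genes)],
            columns=[f"s{i}" for i in range(2 * n)],
        )
        groups = ["a"] * n + ["b"] * n
        return counts, groups

    def test_null_simulation_yields_no_calls(self, rng):
        sig = 0
        for _ in range(20):
            counts, groups = self._null_counts(rng)
            table = simple_de_test(counts, groups)
            sig += int((table["padj"] < 0.05).sum())
        assert sig <= 2

    def test_label_swap_flips_every_sign(self, rng):
        counts, groups = self._null_counts(rng, n_genes=50)
        t1 = simple_de_test(counts, groups)
        swapped = ["b" if g == "a" else "a" for g in groups]
        t2 = simple_de_test(counts, swapped)
        np.testing.assert_allclose(t2["log2fc"], -t1["log2fc"], atol=1e-12)
        np.testing.assert_allclose(t2["pvalue"], t1["pvalue"], atol=1e-12)

    def test_degenerate_groups_rejected(self, rng):
        counts, _ = self._null_counts(rng, n_genes=10, n=2)
        with pytest.raises(ValueError):
            simple_de_test(counts, ["a", "a", "a", "b"])
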