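"""Expression normalization, DEG filters and overlap statistics."""

import numpy as np
import pandas as pd
import pytest

from synquant import genesets, synthgen
from synquant.genesets import (
    ExpressionTable,
    bh_adjust,
    deg_filter,
    expression_filter,
    hypergeom_overlap,
    overlap_report,
    permute_external,
    permute_internal,
    rpkm,
)
from synquant.reference import hypergeom_tail_enumeration
from synquant.types import GeneSetCollection, normalize_symbols


def _table(counts: dict, lengths: dict, labels):
    df = pd.DataFrame(counts)
    return ExpressionTable(df, pd.Series(lengths), list(labels))


class TestRpkm:
    def test_hand_example(self):
        t = _table({"s1": [10, 999990]}, {0: 1000, 1: 1000}, ["a"])
        out = rpkm(t)
        assert out.loc[0, "s1"] == pytest.approx(10.0)

    def test_zero_count_zero_rpkm(self):
        t = _table({"s1": [0, 100]}, {0: 500, 1: 500}, ["a"])
        assert rpkm(t).loc[0, "s1"] == 0.0

    def test_scaling_library_leaves_rpkm_unchanged(self):
        counts = {"s1": [10, 20, 70]}
        t1 = _table(counts, {0: 1000, 1: 2000, 2: 500}, ["a"])
        t2 = _table({"s1": [20, 40, 140]}, {0: 1000, 1: 2000, 2: 500}, ["a"])
        pd.testing.assert_frame_equal(rpkm(t1), rpkm(t2))

    def test_zero_library_rejected(self):
        t = _table({"s1": [0, 0]}, {0: 100, 1: 100}, ["a"])
        with pytest.raises(ValueError, match="library"):
            rpkm(t)


class TestExpressionFilter:
    @staticmethod
    def _mat(g1, g2):
        # one gene, two groups of two samples with the given group means
        return pd.DataFrame(
            {"a1": [g1], "a2": [g1], "b1": [g2], "b2": [g2]}, index=["GENE1"]
        ), ["trt", "trt", "ctl", "ctl"]

    def test_one_group_above_cutoff_retained(self):
        mat, labels = self._mat(0.4, 0.6)
        assert expression_filter(mat, labels) == ["GENE1"]

    def test_both_groups_below_cutoff_dropped(self):
        mat, labels = self._mat(0.3, 0.3)
        assert expression_filter(mat, labels) == []

    def test_cutoff_is_strict(self):
        mat, labels = self._mat(0.5, 0.5)
        assert expression_filter(mat, labels) == []

    def test_zero_cutoff_keeps_any_expression(self):
        mat, labels = self._mat(0.0, 0.01)
        assert expression_filter(mat, labels, min_rpkm=0.0) == ["GENE1"]

    def test_per_sample_variant(self):
        mat = pd.DataFrame({"a1": [1.0], "a2": [0.0]}, index=["G"])
        assert expression_filter(mat, ["t", "t"], per_sample=True) == ["G"]


class TestDegFilter:
    def test_threshold_rules(self):
        table = pd.DataFrame(
            {
                "log2fc": [0.25, 0.4, -0.5, 0.31, 1.0],
                "fdr": [0.01, 0.04, 0.001, 0.05, 0.3],
            },
            index=["A", "B", "C", "D", "E"],
        )
        out = deg_filter(table)
        assert out["up"] == ["B"]  # A fails lfc, D fails strict fdr, E fails fdr
        assert out["down"] == ["C"]
        assert out["all"] == ["B", "C"]

    def test_fdr_computed_from_pvalues_when_absent(self):
        table = pd.DataFrame(
            {"log2fc": [1.0, 1.0], "pvalue": [0.001, 0.9]}, index=["A", "B"]
        )
        out = deg_filter(table)
        assert out["all"] == ["A"]

    def test_recovers_planted_degs_from_count_matrix(self):
        # extreme planted effects + exact externally supplied p-values:
        # the rpkm -> expression filter -> DEG filter chain must recover
        # the planted set with no false calls
        lfc = np.zeros(200)
        lfc[:20] = 1.0
        lfc[20:40] = -1.0
        counts, truth, labels = synthgen.gen_count_matrix(
            200, 4, dispersion=1e-12, planted_lfc=lfc, baseline_mean=5000.0, seed=3
        )
        table = ExpressionTable(
            counts.drop(columns="length_bp"), counts["length_bp"], labels
        )
        mat = rpkm(table)
        kept = expression_filter(mat, labels)
        assert kept == list(counts.index)  # high baseline: everything expressed
        labels_arr = np.asarray(labels)
        est_lfc = np.log2(
            mat.loc[:, labels_arr == "treatment"].mean(axis=1)
            / mat.loc[:, labels_arr == "control"].mean(axis=1)
        )
        deg_table = pd.DataFrame(
            {
                "log2fc": est_lfc,
                "pvalue": np.where(truth["true_log2fc"] != 0, 0.0, 1.0),
            },
            index=counts.index,
        )
        out = deg_filter(deg_table)
        assert set(out["up"]) == set(counts.index[:20])
        assert set(out["down"]) == set(counts.index[20:40])


class TestBhAdjust:
    def test_hand_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_equal_ps_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.1] * 5), [0.1] * 5)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestHypergeomOverlap:
    def test_disjoint_sets_p_one(self):
        bg = [f"g{i}" for i in range(20)]
        k, p, _ = hypergeom_overlap(bg[:5], bg[10:15], bg)
        assert k == 0 and p == 1.0

    def test_worked_example_five_over_210(self):
        bg = [f"g{i}" for i in range(10)]
        k, p, _ = hypergeom_overlap(bg[:4], bg[:5], bg)
        assert k == 4
        assert p == pytest.approx(5 / 210, rel=1e-12)

    def test_internal_equals_background_forces_full_overlap(self):
        bg = [f"g{i}" for i in range(12)]
        k, p, _ = hypergeom_overlap(bg, bg[:7], bg)
        assert k == 7 and p == pytest.approx(1.0)

    def test_matches_enumeration_on_small_universes(self):
        for n_bg, n_ext, n_int in [(8, 3, 4), (10, 5, 4), (12, 6, 5), (7, 7, 3)]:
            bg = [f"g{i}" for i in range(n_bg)]
            for k in range(max(0, n_int + n_ext - n_bg), min(n_int, n_ext) + 1):
                internal = bg[:k] + bg[n_ext : n_ext + n_int - k]
                got_k, got_p, _ = hypergeom_overlap(internal, bg[:n_ext], bg)
                assert got_k == k
                want = float(hypergeom_tail_enumeration(n_bg, n_ext, n_int, k))
                assert got_p == pytest.approx(want, rel=1e-10)

    def test_case_insensitive_overlap(self):
        bg = ["Shank2", "NRXN1", "pten", "GABRA5", "NOS1"]
        k1, p1, _ = hypergeom_overlap(["SHANK2", "PTEN"], ["shank2", "Pten"], bg)
        k2, p2, _ = hypergeom_overlap(["shank2", "pten"], ["SHANK2", "PTEN"], bg)
        assert (k1, p1) == (k2, p2) and k1 == 2

    def test_normalization_idempotent(self):
        syms = ["a", "A", " b ", "B"]
        once = normalize_symbols(syms)
        assert normalize_symbols(once) == once == ["A", "B"]


class TestPermutations:
    def test_full_universe_p_one(self):
        bg = [f"g{i}" for i in range(30)]
        assert permute_external(bg, bg, bg, n_perm=50, seed=0) == 1.0
        assert permute_internal(bg, bg, bg, n_perm=50, seed=0) == 1.0

    def test_planted_complete_overlap_reports_floor(self):
        col, _ = synthgen.gen_gene_universe(200, 20, 20, enrichment_factor=10.0, seed=1)
        p = permute_external(col.sets["internal"], col.sets["external"],
                             col.background, n_perm=1000, seed=2)
        assert p == 0.001

    def test_fixed_seed_reproducible(self):
        col, _ = synthgen.gen_gene_universe(300, 30, 25, enrichment_factor=2.0, seed=3)
        args = (col.sets["internal"], col.sets["external"], col.background, 200)
        assert permute_external(*args, seed=9) == permute_external(*args, seed=9)

    def test_agrees_with_hypergeometric_under_the_null(self):
        col, _ = synthgen.gen_gene_universe(500, 50, 40, enrichment_factor=1.0, seed=4)
        k, p_hyp, _ = hypergeom_overlap(col.sets["internal"], col.sets["external"],
                                        col.background)
        p_perm = permute_external(col.sets["internal"], col.sets["external"],
                                  col.background, n_perm=4000, seed=5)
        assert abs(p_perm - p_hyp) < 0.03

    def test_two_way_symmetry_with_shared_universe(self):
        col, _ = synthgen.gen_gene_universe(400, 40, 40, enrichment_factor=2.0, seed=6)
        p_ext = permute_external(col.sets["internal"], col.sets["external"],
                                 col.background, n_perm=3000, seed=7)
        p_int = permute_internal(col.sets["internal"], col.sets["external"],
                                 col.background, n_perm=3000, seed=8)
        assert abs(p_ext - p_int) < 0.05

    def test_background_smaller_than_external_rejected(self):
        with pytest.raises(ValueError, match="background"):
            permute_external(["A"], ["A", "B", "C"], ["A", "B"], n_perm=10, seed=0)


class TestOverlapReport:
    def test_single_pair_bh_equals_raw(self):
        col, _ = synthgen.gen_gene_universe(300, 30, 25, enrichment_factor=3.0, seed=9)
        externals = GeneSetCollection(
            sets={"ext": col.sets["external"]},
            background=col.background,
            expressed_universe=col.background,
        )
        report = overlap_report({"deg": col.sets["internal"]}, externals,
                                n_perm=100, seed=1)
        assert len(report) == 1
        assert report.loc[0, "p_bh"] == pytest.approx(report.loc[0, "p_hypergeom"])

    def test_disjoint_external_sets_all_trivial(self):
        bg = [f"g{i}" for i in range(100)]
        externals = GeneSetCollection(
            sets={"e1": bg[50:60], "e2": bg[60:70], "e3": bg[70:80]},
            background=bg,
        )
        report = overlap_report({"deg": bg[:20]}, externals, n_perm=50, seed=2)
        assert (report["k_overlap"] == 0).all()
        assert (report["p_hypergeom"] == 1.0).all()

    def test_enriched_set_attains_minimal_adjusted_p(self):
        wins = 0
        n_rep = 30
        for s in range(n_rep):
            col, _ = synthgen.gen_gene_universe(800, 60, 40,
                                                enrichment_factor=4.0, seed=100 + s)
            rng = np.random.default_rng(200 + s)
            bg = np.asarray(col.background, dtype=object)
            sets = {"enriched": col.sets["external"]}
            for j in range(3):
                sets[f"null{j}"] = list(rng.choice(bg, size=40, replace=False))
            externals = GeneSetCollection(sets=sets, background=col.background,
                                          expressed_universe=col.background)
            report = overlap_report({"deg": col.sets["internal"]}, externals,
                                    n_perm=1, seed=s)
            best = report.loc[report["p_bh"].idxmin(), "external_set"]
            wins += best == "enriched"
        assert wins / n_rep >= 0.95
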