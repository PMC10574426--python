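"""Hypergeometric ORA, BH adjustment and planted-term recovery."""

from fractions import Fraction

import numpy as np
import pytest

import _oracles as oracle
from herbnet.enrichment import (
    GeneSetCollection,
    GeneSetTerm,
    bh_adjust,
    hypergeom_upper,
    run_ora,
)
from herbnet.synthetic import PlantedTerm, SyntheticSpec, gen_annotations
from herbnet.targets import TargetSet


class TestHypergeomUpper:
    @pytest.mark.parametrize(
        "N,K,n,k,expected",
        [
            (10, 4, 3, 2, Fraction(1, 3)),  # enumeration over C(10,3) draws
            (5, 2, 2, 2, Fraction(1, 10)),  # 1 / C(5,2)
            (7, 3, 3, 0, Fraction(1)),      # P(X >= 0) = 1
        ],
    )
    def test_known_values(self, N, K, n, k, expected):
        assert hypergeom_upper(N, K, n, k) == pytest.approx(float(expected), rel=1e-12)

    def test_matches_enumeration_for_all_small_cases(self):
        for N in range(1, 13):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(min(K, n) + 1):
                        expected = float(oracle.hypergeom_upper_enum(N, K, n, k))
                        assert hypergeom_upper(N, K, n, k) == pytest.approx(
                            expected, rel=1e-10, abs=1e-14
                        ), (N, K, n, k)

    def test_infeasible_arguments(self):
        with pytest.raises(ValueError):
            hypergeom_upper(10, 11, 3, 1)
        with pytest.raises(ValueError):
            hypergeom_upper(10, 4, 3, 4)


class TestBhAdjust:
    def test_hand_evaluated_stepup(self):
        assert bh_adjust([0.01, 0.02, 0.04]) == pytest.approx([0.03, 0.03, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3]) == [0.3]

    def test_all_equal_fixed_point(self):
        assert bh_adjust([0.05] * 4) == pytest.approx([0.05] * 4)

    def test_returned_in_input_order(self):
        out = bh_adjust([0.04, 0.01, 0.02])
        assert out == pytest.approx([0.04, 0.03, 0.03])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    def test_monotone_and_matches_naive(self):
        rng = np.random.default_rng(123)
        for _ in range(50):
            p = rng.random(int(rng.integers(1, 40))).tolist()
            adj = bh_adjust(p)
            assert adj == pytest.approx(oracle.bh_stepup_naive(p), rel=1e-12)
            # monotone: adjusted order respects raw order
            order = np.argsort(p, kind="stable")
            assert all(
                adj[order[i]] <= adj[order[i + 1]] + 1e-15
                for i in range(len(p) - 1)
            )
            # adjustment never lowers a p-value below its raw value
            assert all(a >= r - 1e-15 for a, r in zip(adj, p))

    def test_readjustment_can_inflate(self):
        """Step-up adjusted values are not p-values: re-adjusting them can
        raise them further (the procedure is not idempotent)."""
        q = bh_adjust([0.927, 0.3307])
        assert q == pytest.approx([0.927, 0.6614])
        assert bh_adjust(q) == pytest.approx([0.927, 0.927])

    def test_cross_check_against_statsmodels(self):
        statsmodels = pytest.importorskip("statsmodels.stats.multitest")
        rng = np.random.default_rng(5)
        p = rng.random(25)
        ours = bh_adjust(p.tolist())
        theirs = statsmodels.multipletests(p, method="fdr_bh")[1]
        assert ours == pytest.approx(theirs.tolist(), rel=1e-12)


def make_collection(term_specs):
    return GeneSetCollection(
        terms=[
            GeneSetTerm(term_id=f"T{i:03d}", term_name=f"t{i}", category=cat,
                        members=frozenset(members))
            for i, (cat, members) in enumerate(term_specs)
        ]
    )


class TestRunOra:
    def test_zero_overlap_terms_dropped(self):
        coll = make_collection(
            [("KEGG", {"G1", "G2"}), ("KEGG", {"G8", "G9"})]
        )
        study = TargetSet.from_symbols(["G1"])
        results = run_ora(study, coll, alpha=1.0)
        assert [r.term_id for r in results] == ["T000"]

    def test_empty_study_background_overlap_rejected(self):
        coll = make_collection([("KEGG", {"G1"})])
        with pytest.raises(ValueError, match="background"):
            run_ora(TargetSet.from_symbols(["ZZZ"]), coll)

    def test_alpha_one_returns_all_sorted(self):
        coll = make_collection(
            [("KEGG", {f"G{i}" for i in range(10)}),
             ("KEGG", {"G0", "G1"}),
             ("KEGG", {"G0", "G50", "G51", "G52"})]
        )
        study = TargetSet.from_symbols(["G0", "G1", "G2"])
        results = run_ora(study, coll, alpha=1.0)
        assert len(results) == 3
        assert all(
            results[i].p_adjust <= results[i + 1].p_adjust for i in range(2)
        )

    def test_gene_ratio_bookkeeping_exact(self):
        coll = make_collection(
            [("KEGG", {f"G{i}" for i in range(8)}),
             ("BP", {"G0", "G1", "G20"})]
        )
        study = TargetSet.from_symbols(["G0", "G1", "G2", "G20"])
        for r in run_ora(study, coll, alpha=1.0):
            # rational bookkeeping: ratio * |study ∩ background| == count
            assert r.gene_ratio * r.gene_ratio.denominator == r.count * 1
            assert r.gene_ratio == Fraction(r.count, r.gene_ratio.denominator)

    def test_bh_applied_within_category(self):
        # identical overlap pattern in two categories: m differs, p_adjust differs
        kegg_terms = [("KEGG", {"G0", "G1"}), ("KEGG", {"G0", "G5"}),
                      ("KEGG", {"G1", "G6"}), ("KEGG", {"G7", "G8"})]
        bp_terms = [("BP", {"G0", "G1"})]
        coll = make_collection(kegg_terms + bp_terms)
        study = TargetSet.from_symbols(["G0", "G1"])
        results = {r.term_id: r for r in run_ora(study, coll, alpha=1.0)}
        kegg_best = results["T000"]
        bp_best = results["T004"]
        assert kegg_best.p_value == pytest.approx(bp_best.p_value, rel=1e-12)
        assert kegg_best.p_adjust >= bp_best.p_adjust  # m=3 tested KEGG terms vs 1 BP

    def test_planted_term_ranks_first(self):
        background = TargetSet.from_symbols([f"G{i:06d}" for i in range(500)])
        study = TargetSet.from_symbols([f"G{i:06d}" for i in range(50)])
        spec = SyntheticSpec(
            seed=11, n_terms=25,
            planted_terms=[PlantedTerm("T0001", effect=1.0, size=40, category="KEGG")],
        )
        coll = gen_annotations(spec, study, background)
        results = [r for r in run_ora(study, coll, background=background,
                                      alpha=0.05, top_k=20)
                   if r.category == "KEGG"]
        assert results and results[0].term_id == "T0001"
        assert results[0].p_adjust < 0.05
        assert results[0].count == 40  # effect 1.0: the whole term is study genes


class TestNullCalibration:
    def test_raw_p_rejection_rate_near_nominal(self):
        """With no planted enrichment, P(p < 0.05) stays within binomial
        99% bounds of the nominal level.

        Term sizes of 750-1000 genes against a 20000-gene background and a
        2000-gene study keep the hypergeometric's discreteness negligible,
        so the attainable level is close to 0.05.
        """
        background = TargetSet.from_symbols([f"G{i:06d}" for i in range(20000)])
        n_reps, n_terms = 200, 10
        rng = np.random.default_rng(99)
        rejections, total = 0, 0
        for rep in range(n_reps):
            study_genes = rng.choice(sorted(background.members), size=2000,
                                     replace=False)
            study = TargetSet.from_symbols(study_genes)
            spec = SyntheticSpec(seed=10_000 + rep, n_terms=n_terms,
                                 term_size_range=(750, 1000))
            coll = gen_annotations(spec, study, background)
            for r in run_ora(study, coll, background=background, alpha=1.0):
                total += 1
                rejections += r.p_value < 0.05
        assert total == n_reps * n_terms
        half_width = 2.5758 * np.sqrt(0.05 * 0.95 / total)
        assert abs(rejections / total - 0.05) < half_width
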