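"""GO-based module assessment: levels, enrichment, ER/COV/IC/OMPSDF."""

from fractions import Fraction
from math import comb

import pytest

from dcbmine import Module
from dcbmine.errors import DomainError, StructureError
from dcbmine.evaluate import (
    AnnotationSet,
    basic_stats,
    coverage,
    enrich,
    enrich_modules,
    enrichment_ratio,
    individual_coverage,
    ompsdf,
    term_levels,
)

from conftest import make_net


def mod(genes, subspace=(0,), dens=1.0):
    return Module(frozenset(genes), frozenset(subspace), dens)


class TestTermLevels:
    def test_lone_root_is_level_zero(self):
        assert term_levels([("t1", "root")]) == {"root": 0, "t1": 1}

    def test_chain(self):
        lv = term_levels([("t1", "root"), ("t2", "t1")])
        assert lv["t2"] == 2

    def test_shortest_of_multiple_paths(self):
        edges = [("a", "root"), ("b", "a"), ("t", "b"),           # length 3
                 ("c", "root"), ("d", "c"), ("e", "d"), ("f", "e"), ("t", "f")]
        assert term_levels(edges)["t"] == 3

    def test_multiple_roots_take_minimum(self):
        lv = term_levels([("t", "r1"), ("x", "r2"), ("t", "x")])
        assert lv["t"] == 1

    def test_cycle_rejected(self):
        with pytest.raises(StructureError):
            term_levels([("a", "b"), ("b", "a")])


def exact_enrich_tail(n_bg, n_with_term, n_mod, observed) -> Fraction:
    """Independent oracle: hypergeometric tail by direct summation."""
    total = comb(n_bg, n_mod)
    acc = Fraction(0)
    for x in range(observed, min(n_mod, n_with_term) + 1):
        acc += Fraction(comb(n_with_term, x) * comb(n_bg - n_with_term, n_mod - x), total)
    return acc


class TestEnrich:
    def make_annotations(self, assignments):
        return AnnotationSet.from_tables(assignments, term_level={"T": 7})

    def test_worked_example_22_over_120(self):
        # 10-gene background, 3 carry T; module of 3 genes, 2 carry T
        background = {f"g{i}" for i in range(10)}
        ann = self.make_annotations([("g0", "T"), ("g1", "T"), ("g5", "T")])
        [(term, p)] = enrich({"g0", "g1", "g2"}, ann, background)
        assert term == "T"
        assert p == pytest.approx(22 / 120)

    def test_all_background_has_term(self):
        background = {"a", "b", "c"}
        ann = self.make_annotations([(g, "T") for g in background])
        [(_, p)] = enrich({"a", "b"}, ann, background)
        assert p == pytest.approx(1.0)

    def test_module_equals_background(self):
        background = {"a", "b", "c", "d"}
        ann = self.make_annotations([("a", "T"), ("b", "T")])
        [(_, p)] = enrich(background, ann, background)
        assert p == pytest.approx(1.0)

    def test_empty_background_rejected(self):
        with pytest.raises(DomainError):
            enrich(set(), self.make_annotations([]), set())

    def test_matches_exact_summation_small_backgrounds(self):
        for n_bg in range(3, 11):
            background = {f"g{i}" for i in range(n_bg)}
            for n_term in range(1, n_bg + 1):
                ann = self.make_annotations([(f"g{i}", "T") for i in range(n_term)])
                for n_mod in range(1, n_bg + 1):
                    module = {f"g{i}" for i in range(n_mod)}
                    res = enrich(module, ann, background)
                    observed = min(n_mod, n_term)
                    expected = float(
                        exact_enrich_tail(n_bg, n_term, n_mod, observed)
                    )
                    [(_, p)] = res
                    assert p == pytest.approx(expected, abs=1e-12)

    def test_bh_correction_never_below_raw(self):
        background = {f"g{i}" for i in range(8)}
        ann = AnnotationSet.from_tables(
            [("g0", "T1"), ("g1", "T1"), ("g2", "T2"), ("g0", "T2"), ("g5", "T3")],
            term_level={"T1": 7, "T2": 8, "T3": 2},
        )
        mods = [mod({"g0", "g1"}), mod({"g2", "g5"})]
        for r in enrich_modules(mods, ann, background):
            assert r.p_corrected >= r.p_raw
            assert 0.0 <= r.p_corrected <= 1.0


def deep_annotations(gene_terms, levels):
    return AnnotationSet.from_tables(gene_terms, term_level=levels)


class TestSummaryMetrics:
    def setup_method(self):
        # two modules; T1 is deep and private to genes of module 0
        self.background = {f"g{i}" for i in range(12)}
        self.ann = deep_annotations(
            [("g0", "T1"), ("g1", "T1"), ("g2", "T1"),
             ("g6", "T2"), ("g7", "T2"), ("g8", "T3")],
            {"T1": 8, "T2": 8, "T3": 1},
        )
        self.mods = [mod({"g0", "g1", "g2"}), mod({"g6", "g7", "g8"})]
        self.results = enrich_modules(self.mods, self.ann, self.background)

    def test_enrichment_ratio_half(self):
        # module 0: T1 p = C(3,3)/C(12,3) tiny -> enriched deep
        # module 1: T2 covers 2 of 3, T3 shallow
        er = enrichment_ratio(self.mods, self.results, self.ann,
                              p_threshold=0.05, deep_level=7)
        assert er == pytest.approx(50.0)

    def test_deep_level_zero_counts_everything(self):
        er0 = enrichment_ratio(self.mods, self.results, self.ann,
                               p_threshold=0.05, deep_level=0)
        er7 = enrichment_ratio(self.mods, self.results, self.ann,
                               p_threshold=0.05, deep_level=7)
        assert er0 >= er7

    def test_coverage_fraction_of_dataset_terms(self):
        cov = coverage(self.results, self.ann, self.background, p_threshold=0.05)
        # dataset terms: T1, T2, T3; only T1 ends up significant
        assert cov == pytest.approx(100.0 / 3)

    def test_no_annotations_zero(self):
        empty = AnnotationSet.from_tables([], term_level={})
        assert enrichment_ratio(self.mods, [], empty) == 0.0
        assert coverage([], empty, self.background) == 0.0


class TestIndividualCoverage:
    def test_worked_two_gene_example(self):
        # g1 carries 2 terms, 1 covered (0.5); g2 carries 1 term, covered (1.0)
        ann = deep_annotations(
            [("g1", "TA"), ("g1", "TB"), ("g2", "TC")],
            {"TA": 7, "TB": 7, "TC": 7},
        )
        mods = [mod({"g1", "g2"})]
        from dcbmine.evaluate import EnrichmentResult

        # hand-built enrichment outcomes: TA and TC significant, TB not
        forced = [
            EnrichmentResult(0, "TA", 0.001, 0.001, 7),
            EnrichmentResult(0, "TB", 0.9, 0.9, 7),
            EnrichmentResult(0, "TC", 0.001, 0.001, 7),
        ]
        assert individual_coverage(mods, forced, ann, p_threshold=0.05) == (
            pytest.approx(75.0)
        )

    def test_all_covered_is_100(self):
        ann = deep_annotations([("a", "T"), ("b", "T")], {"T": 7})
        mods = [mod({"a", "b"})]
        from dcbmine.evaluate import EnrichmentResult

        forced = [EnrichmentResult(0, "T", 0.001, 0.001, 7)]
        assert individual_coverage(mods, forced, ann) == pytest.approx(100.0)

    def test_nothing_covered_is_0(self):
        ann = deep_annotations([("a", "T")], {"T": 7})
        assert individual_coverage([mod({"a", "b"})], [], ann) == 0.0


class TestOmpsdf:
    def qualifying_fixture(self):
        from dcbmine.evaluate import EnrichmentResult

        ann = deep_annotations(
            [("g", "T1"), ("g", "T2")], {"T1": 8, "T2": 9, "CORE": 2}
        )
        mods = [mod({"g", "a"}), mod({"g", "b"})]
        results = [
            EnrichmentResult(0, "T1", 0.001, 0.001, 8),
            EnrichmentResult(1, "T2", 0.001, 0.001, 9),
        ]
        return mods, results, ann

    def test_constructed_pair_counts_once(self):
        mods, results, ann = self.qualifying_fixture()
        assert ompsdf(mods, results, ann, core_level=3, deep_level=7) == 1

    def test_disjoint_pair_never_counts(self):
        from dcbmine.evaluate import EnrichmentResult

        mods, results, ann = self.qualifying_fixture()
        mods = [mod({"g", "a"}), mod({"x", "b"})]
        assert ompsdf(mods, results, ann) == 0

    def test_shared_core_term_blocks(self):
        from dcbmine.evaluate import EnrichmentResult

        mods, results, ann = self.qualifying_fixture()
        results = results + [
            EnrichmentResult(0, "CORE", 0.001, 0.001, 2),
            EnrichmentResult(1, "CORE", 0.001, 0.001, 2),
        ]
        assert ompsdf(mods, results, ann) == 0

    def test_partitioned_modules_give_zero(self):
        """Any partition of the gene set has no overlapping pair at all."""
        from dcbmine.evaluate import EnrichmentResult

        genes = [f"g{i}" for i in range(9)]
        mods = [mod(genes[0:3]), mod(genes[3:6]), mod(genes[6:9])]
        ann = deep_annotations(
            [(g, f"T{i}") for i, g in enumerate(genes)],
            {f"T{i}": 8 for i in range(9)},
        )
        results = [
            EnrichmentResult(m, f"T{i}", 0.001, 0.001, 8)
            for m in range(3)
            for i in range(9)
        ]
        assert ompsdf(mods, results, ann) == 0


class TestBasicStats:
    def net_for(self, genes, edges):
        return make_net(genes, edges, {g: [0.0] for g in genes})

    def test_single_triangle(self):
        net = self.net_for(list("ABC"), [("A", "B"), ("A", "C"), ("B", "C")])
        assert basic_stats([mod("ABC")], net) == (3, 1, 3.0, 1.0)

    def test_two_disjoint_triangles(self):
        net = self.net_for(
            list("ABCDEF"),
            [("A", "B"), ("A", "C"), ("B", "C"), ("D", "E"), ("D", "F"), ("E", "F")],
        )
        stats = basic_stats([mod("ABC"), mod("DEF")], net)
        assert stats == (6, 2, 3.0, 1.0)

    def test_overlapping_modules_union_of_genes(self):
        net = self.net_for(
            list("ABCDE"),
            [("A", "B"), ("B", "C"), ("C", "D"), ("D", "E"), ("C", "E")],
        )
        n_genes, n_modules, ams, _ = basic_stats([mod("ABC"), mod("CDE")], net)
        assert (n_genes, n_modules, ams) == (5, 2, 3.0)
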