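"""Significance ranking: sampling null, truncated-normal fit, hypergeometric
density p-values, rank combination and the redundancy filter."""

from fractions import Fraction
from math import comb

import numpy as np
import pytest
from scipy import integrate, stats

from dcbmine import (
    DCBParams,
    Module,
    coexpression_pvalue,
    density_pvalue,
    enumerate_dcbs,
    filter_ranked,
    fit_coexpression_null,
    rank_modules,
    sample_connected_subnetworks,
)
from dcbmine.errors import DomainError, SamplingError
from dcbmine.rank import RankedModule
from dcbmine.synth import random_profile_network

from conftest import make_net


def exact_density_tail(n_nodes: int, n_edges: int, k: int, m: int) -> Fraction:
    """Independent oracle: hypergeometric upper tail by direct summation."""
    population = comb(n_nodes, 2)
    draws = comb(k, 2)
    total = comb(population, draws)
    acc = Fraction(0)
    for x in range(m, min(draws, n_edges) + 1):
        if population - n_edges >= draws - x:
            acc += Fraction(comb(n_edges, x) * comb(population - n_edges, draws - x), total)
    return acc


class TestDensityPvalue:
    def test_worked_example_one_sixth(self):
        assert density_pvalue(5, 6, 3, 3) == pytest.approx(1 / 6)

    def test_whole_network_drawn(self):
        assert density_pvalue(5, 6, 5, 6) == pytest.approx(1.0)

    def test_zero_edges_upper_tail_is_one(self):
        assert density_pvalue(6, 4, 3, 0) == pytest.approx(1.0)

    def test_matches_exact_summation_all_small_instances(self):
        for n in range(3, 9):
            for n_edges in range(0, comb(n, 2) + 1, 3):
                for k in range(2, n + 1):
                    for m in range(0, min(comb(k, 2), n_edges) + 1):
                        expected = float(exact_density_tail(n, n_edges, k, m))
                        assert density_pvalue(n, n_edges, k, m) == pytest.approx(
                            expected, abs=1e-12
                        )

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            density_pvalue(5, 6, 1, 0)
        with pytest.raises(DomainError):
            density_pvalue(5, 6, 3, 4)  # more edges than C(3,2)


class TestCoexpressionNull:
    def test_parameter_recovery_from_clipped_normal(self):
        rng = np.random.default_rng(123)
        counts = np.clip(rng.normal(10, 2, size=2000), 0, 30)
        null = fit_coexpression_null(counts, bounds=(0, 30))
        assert null.loc == pytest.approx(10.0, abs=0.2)
        assert null.scale == pytest.approx(2.0, abs=0.2)

    def test_constant_counts_degenerate(self):
        null = fit_coexpression_null([5, 5, 5, 5], bounds=(0, 10))
        assert null.degenerate
        assert coexpression_pvalue(null, 5) == 1.0
        assert coexpression_pvalue(null, 6) == 0.0

    def test_lower_bound_pvalue_is_one(self):
        rng = np.random.default_rng(5)
        null = fit_coexpression_null(rng.normal(4, 1, 500).clip(0, 8), (0, 8))
        assert coexpression_pvalue(null, 0) == pytest.approx(1.0)

    def test_monotone_tail(self):
        rng = np.random.default_rng(6)
        null = fit_coexpression_null(rng.normal(4, 1, 500).clip(0, 8), (0, 8))
        ps = [coexpression_pvalue(null, x) for x in np.linspace(0, 8, 17)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_pvalue_matches_quadrature(self):
        """The survival function equals numerical integration of the density."""
        rng = np.random.default_rng(7)
        null = fit_coexpression_null(rng.normal(12, 3, 1000).clip(0, 30), (0, 30))
        a = (null.lower - null.loc) / null.scale
        b = (null.upper - null.loc) / null.scale
        for observed in (5.0, 12.0, 20.0):
            quad, _ = integrate.quad(
                lambda x: stats.truncnorm.pdf(x, a, b, loc=null.loc, scale=null.scale),
                observed,
                null.upper,
            )
            assert coexpression_pvalue(null, observed) == pytest.approx(quad, abs=1e-6)


class TestSampling:
    def test_path_graph_full_size_sample_is_whole_path(self):
        genes = [f"n{i}" for i in range(6)]
        net = make_net(
            genes, list(zip(genes, genes[1:])), {g: [0.0] for g in genes}
        )
        for s in sample_connected_subnetworks(net, 6, 5, seed=0):
            assert s == frozenset(genes)

    def test_samples_are_connected_and_sized(self):
        rng = np.random.default_rng(9)
        net = random_profile_network(20, 0.15, 4, rng=rng)
        import networkx as nx

        for s in sample_connected_subnetworks(net, 4, 50, seed=1):
            assert len(s) == 4
            assert nx.is_connected(net.graph.subgraph(s))

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(10)
        net = random_profile_network(15, 0.3, 4, rng=rng)
        assert sample_connected_subnetworks(net, 3, 20, seed=7) == (
            sample_connected_subnetworks(net, 3, 20, seed=7)
        )

    def test_no_large_enough_component(self):
        net = make_net(["A", "B"], [], {"A": [0.0], "B": [0.0]})
        with pytest.raises(SamplingError):
            sample_connected_subnetworks(net, 2, 1, seed=0)


def ranked_fixture():
    """Three modules on a small planted network, ranked with few samples."""
    rng = np.random.default_rng(20)
    net = random_profile_network(15, 0.35, 6, rng=rng)
    params = DCBParams(0.5, 2.0, 2)
    modules = enumerate_dcbs(net, params, min_size=2)
    assert modules
    return net, modules


class TestRankModules:
    def test_dominating_module_is_rank_one(self):
        net = make_net(
            list("ABCDEFG"),
            [("A", "B"), ("A", "C"), ("B", "C"),        # tight triangle
             ("D", "E"), ("E", "F"), ("F", "G"), ("G", "D")],  # loose square
            {
                "A": [0, 0, 0, 0], "B": [0, 0, 0, 0], "C": [0, 0, 0, 0],
                "D": [0, 3, 6, 9], "E": [0, -3, -6, 9], "F": [1, 3, -6, 9],
                "G": [0, 3, 6, -9],
            },
        )
        mods = [
            Module(frozenset("ABC"), frozenset({0, 1, 2, 3}), 1.0),
            Module(frozenset("DEFG"), frozenset({0}), 4 / 6),
        ]
        ranked = rank_modules(mods, net, epsilon=0.5, n_samples=100, seed=0)
        assert ranked[0].module.genes == frozenset("ABC")
        assert ranked[0].p_coexpression <= ranked[1].p_coexpression
        assert ranked[0].p_density <= ranked[1].p_density
        assert ranked[0].overall_rank == 1.0

    def test_overall_rank_is_mean_of_ranks(self):
        net, modules = ranked_fixture()
        for r in rank_modules(modules, net, epsilon=2.0, n_samples=60, seed=3):
            assert r.overall_rank == (r.rank_coexpression + r.rank_density) / 2

    def test_invariant_to_input_order(self):
        net, modules = ranked_fixture()
        a = rank_modules(modules, net, epsilon=2.0, n_samples=60, seed=3)
        b = rank_modules(list(reversed(modules)), net, epsilon=2.0, n_samples=60, seed=3)
        assert a == b


class TestFilterRanked:
    @staticmethod
    def ranked_list(gene_sets):
        out = []
        for i, gs in enumerate(gene_sets):
            m = Module(frozenset(gs), frozenset({0}), 1.0)
            out.append(
                RankedModule(m, p_coexpression=0.01 * (i + 1),
                             p_density=0.01 * (i + 1),
                             rank_coexpression=i + 1, rank_density=i + 1)
            )
        return out

    def test_worked_example_drops_covered_module(self):
        ranked = self.ranked_list(["ABC", "AB", "CD"])
        kept = filter_ranked(ranked)
        assert [sorted(r.module.genes) for r in kept] == [["A", "B", "C"], ["C", "D"]]

    def test_disjoint_all_kept(self):
        ranked = self.ranked_list(["AB", "CD", "EF"])
        assert len(filter_ranked(ranked)) == 3

    def test_duplicate_of_top_module_removed(self):
        ranked = self.ranked_list(["ABC", "DE", "ABC"])
        assert len(filter_ranked(ranked)) == 2

    def test_top_n_stops_after_keeping_n(self):
        ranked = self.ranked_list(["AB", "CD", "EF", "GH"])
        assert len(filter_ranked(ranked, top_n=2)) == 2

    def test_kept_modules_never_covered_by_predecessors(self):
        net, modules = ranked_fixture()
        ranked = rank_modules(modules, net, epsilon=2.0, n_samples=60, seed=3)
        kept = filter_ranked(ranked)
        covered = set()
        for r in kept:
            assert not r.module.genes <= covered
            covered |= r.module.genes
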