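"""Over-representation, PPI edge enrichment, classification, chord export."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

import miscvar as mv
from miscvar import fixtures
from miscvar.enrichment import sample_null_selection
from miscvar.simulate import generate_toy_interactome


def toy_interactome(edges, nodes=()):
    inter = mv.Interactome.from_edges([(a, b, 0.9) for a, b in edges])
    for n in nodes:
        inter.graph.add_node(n)
    return inter


class TestSubgraphStats:
    def test_complete_graph(self):
        inter = toy_interactome(itertools.combinations("ABCD", 2))
        assert mv.subgraph_stats(inter, set("ABCD")) == (4, 6)

    def test_empty_selection(self):
        inter = toy_interactome([("A", "B")])
        assert mv.subgraph_stats(inter, set()) == (0, 0)

    def test_alternating_nodes_of_a_path(self):
        path = [("N1", "N2"), ("N2", "N3"), ("N3", "N4"), ("N4", "N5"), ("N5", "N6")]
        inter = toy_interactome(path)
        assert mv.subgraph_stats(inter, {"N1", "N3", "N5"}) == (3, 0)

    def test_threshold_drops_low_confidence_edges(self):
        inter = mv.Interactome.from_edges([("A", "B", 0.39), ("B", "C", 0.41)])
        assert inter.n_edges == 1
        assert inter.nodes == {"A", "B", "C"}

    def test_self_loop_rejected(self):
        with pytest.raises(ValueError, match="self-loop"):
            mv.Interactome.from_edges([("A", "A", 0.9)])


class TestEdgeEnrichmentDensityNull:
    def test_expected_is_analytic(self):
        # background: 10 nodes, 9 edges (a star) -> rho = 9/45 = 0.2
        star = [("H", f"S{i}") for i in range(9)]
        inter = toy_interactome(star)
        sel = {"H", "S0", "S1", "S2", "S3"}
        observed, expected, _ = mv.edge_enrichment(inter, sel, null="density")
        assert expected == pytest.approx(0.2 * 5 * 4 / 2)
        assert observed == 4

    def test_zero_observed_edges_gives_p_one(self):
        star = [("H", f"S{i}") for i in range(9)]
        inter = toy_interactome(star)
        _, _, p = mv.edge_enrichment(inter, {"S0", "S1", "S2"}, null="density")
        assert p == 1.0

    def test_p_is_binomial_upper_tail(self):
        inter = generate_toy_interactome(seed=3, n_nodes=12, density=0.4)
        sel = sorted(inter.nodes)[:6]
        observed, _, p = mv.edge_enrichment(inter, sel, null="density")
        rho = inter.density()
        assert p == pytest.approx(float(sps.binom.sf(observed - 1, 15, rho)), rel=1e-12)

    def test_fewer_than_two_nodes_rejected(self):
        inter = toy_interactome([("A", "B")])
        with pytest.raises(ValueError, match="at least 2"):
            mv.edge_enrichment(inter, {"A"}, null="density")


class TestEdgeEnrichmentPermutationNull:
    def test_agrees_with_exhaustive_enumeration(self):
        """Monte-Carlo permutation p matches the exact degree-weighted tail.

        On a 6-node background with k=3 the null has only C(6,3)=20 support
        sets; the exact p is the probability-weighted mass of subsets with
        at least as many internal edges as observed.
        """
        edges = [("A", "B"), ("B", "C"), ("C", "D"), ("D", "E"), ("E", "F"), ("A", "C")]
        inter = toy_interactome(edges)
        sel = ["A", "B", "C"]
        observed, _, p_mc = mv.edge_enrichment(
            inter, sel, null="degree_permute", n_perm=10000, seed=7
        )

        # exact tail: sequential weighted sampling without replacement
        nodes = sorted(inter.nodes)
        deg = {n: inter.graph.degree(n) for n in nodes}

        def subset_prob(subset):
            total = 0.0
            for order in itertools.permutations(subset):
                prob, remaining = 1.0, sum(deg.values())
                for node in order:
                    prob *= deg[node] / remaining
                    remaining -= deg[node]
                total += prob
            return total

        exact = 0.0
        for subset in itertools.combinations(nodes, 3):
            n_edges = inter.graph.subgraph(subset).number_of_edges()
            if n_edges >= observed:
                exact += subset_prob(subset)
        assert p_mc == pytest.approx(exact, abs=3 * math.sqrt(exact * (1 - exact) / 10000) + 1e-4)

    def test_deterministic_given_seed(self):
        inter = generate_toy_interactome(seed=5, n_nodes=15, density=0.3)
        sel = sorted(inter.nodes)[:5]
        r1 = mv.edge_enrichment(inter, sel, null="degree_permute", n_perm=500, seed=9)
        r2 = mv.edge_enrichment(inter, sel, null="degree_permute", n_perm=500, seed=9)
        assert r1 == r2

    def test_add_one_estimator_never_zero(self):
        inter = generate_toy_interactome(seed=5, n_nodes=15, density=0.3)
        sel = sorted(inter.nodes)[:5]
        _, _, p = mv.edge_enrichment(inter, sel, null="degree_permute", n_perm=50, seed=2)
        assert p >= 1 / 51


class TestOverrepresentation:
    def test_matches_exhaustive_enumeration_on_tiny_universe(self):
        """Hypergeometric upper tail equals direct enumeration over draws."""
        universe = frozenset("ABCDEF")
        term_genes = frozenset("ABC")
        selection = frozenset("ABC")
        term_map = mv.TermMap(terms={"T1": ("term one", term_genes)}, universe=universe)
        (res,) = mv.overrepresentation(term_map, selection)

        k = len(selection)
        hits = 0
        total = 0
        for draw in itertools.combinations(sorted(universe), k):
            total += 1
            if len(set(draw) & term_genes) >= res.overlap:
                hits += 1
        assert res.p_value == pytest.approx(hits / total, abs=1e-12)

    def test_disjoint_term_has_p_one(self):
        term_map = mv.TermMap(
            terms={"T1": ("x", frozenset("DE"))}, universe=frozenset("ABCDE")
        )
        (res,) = mv.overrepresentation(term_map, {"A", "B"})
        assert res.overlap == 0 and res.p_value == 1.0

    def test_bh_step_up_arithmetic(self):
        """Reported q-values equal a hand-rolled BH step-up on the p-values."""
        rng = np.random.default_rng(4)
        universe = frozenset(f"G{i}" for i in range(25))
        terms = {
            f"T{i}": (f"t{i}", frozenset(rng.choice(sorted(universe), 4, replace=False)))
            for i in range(6)
        }
        term_map = mv.TermMap(terms=terms, universe=universe)
        results = mv.overrepresentation(term_map, set(sorted(universe)[:8]))

        by_p = sorted(results, key=lambda r: r.p_value)
        m = len(by_p)
        raw = [r.p_value * m / (i + 1) for i, r in enumerate(by_p)]
        stepped = [min(min(raw[i:]), 1.0) for i in range(m)]
        for r, q in zip(by_p, stepped):
            assert r.q_value == pytest.approx(q, abs=1e-12)

    def test_q_monotone_in_sorted_p_order(self):
        rng = np.random.default_rng(0)
        universe = frozenset(f"G{i}" for i in range(30))
        terms = {
            f"T{i}": (f"t{i}", frozenset(rng.choice(sorted(universe), 5, replace=False)))
            for i in range(8)
        }
        term_map = mv.TermMap(terms=terms, universe=universe)
        results = mv.overrepresentation(term_map, set(sorted(universe)[:10]))
        by_p = sorted(results, key=lambda r: r.p_value)
        qs = [r.q_value for r in by_p]
        assert qs == sorted(qs)
        assert all(r.q_value >= min(x.p_value for x in results) for r in results)

    def test_empty_term_skipped(self):
        term_map = mv.TermMap(
            terms={"T1": ("x", frozenset()), "T2": ("y", frozenset("AB"))},
            universe=frozenset("ABC"),
        )
        results = mv.overrepresentation(term_map, {"A"})
        assert [r.term for r in results] == ["T2"]

    def test_gmt_round_trip(self, tmp_path):
        path = tmp_path / "terms.gmt"
        path.write_text("T1\tfirst term\tA\tB\nT2\tsecond term\tB\tC\tD\n")
        tm = mv.TermMap.from_gmt(path)
        assert tm.terms["T2"][1] == {"B", "C", "D"}
        assert tm.universe == {"A", "B", "C", "D"}


class TestPermutationNullCalibration:
    def test_p_values_uniform_under_the_null(self):
        """Selections drawn from the degree-weighted null yield ~uniform p."""
        inter = generate_toy_interactome(seed=7, n_nodes=60, density=0.3)
        rng = np.random.default_rng(123)
        pvals = []
        for i in range(500):
            sel = sample_null_selection(inter, 18, rng)
            _, _, p = mv.edge_enrichment(
                inter, sel, null="degree_permute", n_perm=199, seed=1000 + i
            )
            pvals.append(p)
        assert sps.kstest(pvals, "uniform").pvalue > 0.01


class TestClassifyPathways:
    def test_study_fixture_classification(self):
        cls = mv.classify_pathways(
            fixtures.pathway_labels("study"),
            fixtures.pathway_labels("literature"),
            fixtures.pathway_labels("combined"),
        )
        assert "Complement system" in cls.study_only
        assert "Blood coagulation" in cls.literature_only
        assert "Angiogenesis" in cls.combined_only
        assert "Response to virus" in cls.shared
        assert len(cls.study_only) == 3
        assert len(cls.combined_only) == 3

    def test_sets_are_pairwise_disjoint(self):
        cls = mv.classify_pathways(
            fixtures.pathway_labels("study"),
            fixtures.pathway_labels("literature"),
            fixtures.pathway_labels("combined"),
        )
        groups = [cls.study_only, cls.literature_only, cls.shared, cls.combined_only]
        for a, b in itertools.combinations(groups, 2):
            assert not (a & b)

    def test_union_reconstruction(self):
        s, l, c = frozenset("AB"), frozenset("BC"), frozenset("BD")
        cls = mv.classify_pathways(s, l, c)
        assert cls.study_only | cls.literature_only | cls.shared | cls.combined_only \
            == s | l | (c - (s | l))

    def test_all_empty(self):
        cls = mv.classify_pathways([], [], [])
        assert cls == mv.PathwayClassification(
            frozenset(), frozenset(), frozenset(), frozenset()
        )


class TestChordMatrix:
    def test_type_ii_interferon_row_sums_to_three(self):
        matrix = mv.chord_matrix(
            {"HLA-A", "IRF3", "TP53"}, fixtures.pathway_gene_sets("study")
        )
        assert matrix.loc["Type 2 interferon signaling pathway"].sum() == 3

    def test_empty_gene_set_gives_no_columns(self):
        matrix = mv.chord_matrix(set(), fixtures.pathway_gene_sets("study"))
        assert matrix.shape[1] == 0

    def test_gene_in_no_pathway_omitted(self):
        matrix = mv.chord_matrix(
            {"HLA-A", "NOT_IN_ANY_PATHWAY"}, fixtures.pathway_gene_sets("study")
        )
        assert "NOT_IN_ANY_PATHWAY" not in matrix.columns

    def test_entries_are_memberships(self):
        pathway_map = {"PW1": {"A", "B"}, "PW2": {"B"}}
        matrix = mv.chord_matrix({"A", "B", "C"}, pathway_map)
        assert list(matrix.columns) == ["A", "B"]
        assert matrix.loc["PW1"].tolist() == [1, 1]
        assert matrix.loc["PW2"].tolist() == [0, 1]
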