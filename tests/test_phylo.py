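import itertools
import random

import dendropy
import numpy as np
import pytest

from markerani.phylo import (
    informative_sites,
    nj_tree,
    pair_incompatibility,
    phi_test,
    rf_distance,
    tree_bipartitions,
)
from markerani.seqio import GeneAlignment
from markerani.simulate import SimConfig, simulate_panel

from tree_oracle import (
    enumerate_unrooted_trees,
    fitch_steps,
    graph_splits,
    graph_to_newick,
)


def newick(s: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=s, schema="newick")


class TestNjTree:
    def test_recovers_additive_four_taxon_tree_with_lengths(self):
        """Additive matrix for ((a:1,b:2):5,(c:3,d:4)): NJ recovers the split
        and the exact branch lengths."""
        ids = ["a", "b", "c", "d"]
        # path lengths through internal edge of length 5
        m = np.array(
            [
                [0, 3, 9, 10],
                [3, 0, 10, 11],
                [9, 10, 0, 7],
                [10, 11, 7, 0],
            ],
            float,
        )
        tree = nj_tree(m, ids)
        splits = tree_bipartitions(tree)
        assert splits == {frozenset({frozenset({"a", "b"}), frozenset({"c", "d"})})}
        lengths = {
            lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()
        }
        assert lengths == pytest.approx({"a": 1, "b": 2, "c": 3, "d": 4})

    def test_three_taxa_star(self):
        tree = nj_tree(np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float), ["a", "b", "c"])
        assert {lf.taxon.label for lf in tree.leaf_node_iter()} == {"a", "b", "c"}
        assert tree_bipartitions(tree) == set()

    def test_asymmetric_matrix_rejected(self):
        m = np.array([[0, 1, 2], [1.001, 0, 2], [2, 2, 0]])
        with pytest.raises(ValueError):
            nj_tree(m, ["a", "b", "c"])

    def test_negative_entries_rejected(self):
        m = np.array([[0, -1.0, 2], [-1.0, 0, 2], [2, 2, 0]])
        with pytest.raises(ValueError):
            nj_tree(m, ["a", "b", "c"])

    def test_exact_recovery_on_random_additive_matrices(self):
        """NJ reconstructs the generating topology from additive distances."""
        rng = random.Random(31)
        leaves = list("abcdef")
        trees = enumerate_unrooted_trees(leaves)
        for g in rng.sample(trees, 10):
            lengths = {tuple(sorted(e, key=str)): rng.uniform(0.5, 3.0) for e in g.edges()}
            import networkx as nx

            m = np.zeros((6, 6))
            for i, a in enumerate(leaves):
                for j in range(i + 1, 6):
                    path = nx.shortest_path(g, a, leaves[j])
                    d = sum(
                        lengths[tuple(sorted((u, v), key=str))]
                        for u, v in zip(path, path[1:])
                    )
                    m[i, j] = m[j, i] = d
            tree = nj_tree(m, leaves)
            assert tree_bipartitions(tree) == graph_splits(g, set(leaves))


class TestRfDistance:
    def test_identical_trees_zero(self):
        t = "(a,(b,(c,(d,e))));"
        assert rf_distance(newick(t), newick(t)) == 0.0

    def test_single_nni_is_two(self):
        t1 = newick("((a,b),(c,d),e);")  # splits {ab, cd}
        t2 = newick("((a,(c,d)),b,e);")  # splits {cd, acd} — one NNI away
        assert rf_distance(t1, t2) == 2.0

    def test_caterpillar_vs_balanced_matches_oracle(self):
        cat = newick("(a,(b,(c,(d,(e,f)))));")
        bal = newick("((a,(b,c)),(d,(e,f)));")
        b1 = tree_bipartitions(cat)
        b2 = tree_bipartitions(bal)
        assert rf_distance(cat, bal) == len(b1 ^ b2)
        assert rf_distance(cat, bal, normalize=True) == len(b1 ^ b2) / 6

    def test_leaf_set_mismatch_is_error(self):
        with pytest.raises(ValueError, match="leaf-set"):
            rf_distance(newick("(a,(b,c));"), newick("(a,(b,d));"))

    def test_metric_properties_on_random_triples(self):
        rng = random.Random(7)
        leaves = list("abcdef")
        trees = enumerate_unrooted_trees(leaves)
        for _ in range(10):
            g1, g2, g3 = rng.sample(trees, 3)
            t1, t2, t3 = (
                newick(graph_to_newick(g, set(leaves))) for g in (g1, g2, g3)
            )
            d12 = rf_distance(t1, t2)
            d21 = rf_distance(t2, t1)
            assert d12 == d21
            assert rf_distance(t1, t1) == 0
            assert d12 <= rf_distance(t1, t3) + rf_distance(t3, t2)


class TestPairIncompatibility:
    def test_three_gametes_compatible(self):
        ci = {"a": "A", "b": "A", "c": "T", "d": "T"}
        cj = {"a": "A", "b": "T", "c": "T", "d": "T"}
        assert pair_incompatibility(ci, cj) == 0

    def test_four_gametes_incompatible(self):
        ci = {"a": "A", "b": "A", "c": "T", "d": "T"}
        cj = {"a": "A", "b": "T", "c": "A", "d": "T"}
        assert pair_incompatibility(ci, cj) == 1

    def test_gap_taxa_dropped_pairwise(self):
        ci = {"a": "A", "b": "A", "c": "T", "d": "T"}
        cj = {"a": "A", "b": "T", "c": "-", "d": "T"}
        assert pair_incompatibility(ci, cj) == 0  # the 4th gamete was gapped

    def test_too_few_taxa_after_filtering(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            pair_incompatibility({"a": "A", "b": "-"}, {"a": "A", "b": "T"})

    def test_matches_parsimony_oracle_on_multistate_columns(self):
        """Cycle rank equals the exhaustive minimal-extra-steps oracle (all
        topologies, Fitch parsimony) on random 3-state columns, <= 6 taxa."""
        rng = random.Random(19)
        for n in (4, 5, 6):
            leaves = list("abcdef")[:n]
            trees = enumerate_unrooted_trees(leaves)
            for _ in range(15):
                ci = {l: rng.choice("ACG") for l in leaves}
                cj = {l: rng.choice("ACG") for l in leaves}
                oracle = (
                    min(
                        fitch_steps(t, leaves, ci) + fitch_steps(t, leaves, cj)
                        for t in trees
                    )
                    - (len(set(ci.values())) - 1)
                    - (len(set(cj.values())) - 1)
                )
                assert pair_incompatibility(ci, cj) == oracle

    def test_invariant_to_state_relabeling(self):
        ci = {"a": "A", "b": "A", "c": "T", "d": "T", "e": "G"}
        cj = {"a": "C", "b": "T", "c": "C", "d": "T", "e": "T"}
        swap = {"A": "G", "G": "T", "T": "A", "C": "C"}
        ci2 = {k: swap[v] for k, v in ci.items()}
        assert pair_incompatibility(ci, cj) == pair_incompatibility(ci2, cj)


def clonal_alignment(seed: int, length: int = 800) -> GeneAlignment:
    """One gene evolved on a single species tree (no transfer)."""
    panel, _ = simulate_panel(
        SimConfig(
            seed=seed,
            n_species=4,
            strains_per_species=2,
            n_genes=1,
            gene_length=(length, length),
            inter_divergence=(0.10, 0.25),
            intra_divergence=(0.01, 0.04),
            genome_filler_bp=0,
        )
    )
    return panel.gene_alignments[0]


class TestPhiTest:
    def test_homoplasy_free_alignment(self):
        rows = {"a": "AAAA", "b": "AAAT", "c": "TTAA", "d": "TTAA"}
        aln = GeneAlignment("g", {k: v * 40 for k, v in rows.items()})
        res = phi_test(aln, n_permutations=100, seed=3)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_too_few_informative_sites(self):
        aln = GeneAlignment("g", {"a": "ACGT", "b": "ACGT", "c": "ACGT", "d": "ACGA"})
        res = phi_test(aln)
        assert res.p_value is None
        assert "informative" in res.status

    def test_needs_four_sequences(self):
        with pytest.raises(ValueError, match="4 sequences"):
            phi_test(GeneAlignment("g", {"a": "ACGT", "b": "ACGA"}))

    def test_reproducible_given_seed(self):
        aln = clonal_alignment(5)
        r1 = phi_test(aln, n_permutations=100, seed=42)
        r2 = phi_test(aln, n_permutations=100, seed=42)
        assert (r1.statistic, r1.p_value) == (r2.statistic, r2.p_value)

    def test_invariant_to_taxon_order(self):
        aln = clonal_alignment(6)
        shuffled = GeneAlignment(
            aln.gene_name, {k: aln.rows[k] for k in sorted(aln.rows, reverse=True)}
        )
        r1 = phi_test(aln, n_permutations=60, seed=1)
        r2 = phi_test(shuffled, n_permutations=60, seed=1)
        assert r1.statistic == r2.statistic
        assert r1.p_value == r2.p_value

    def test_informative_sites_definition(self):
        aln = GeneAlignment(
            "g",
            {
                "a": "AAC-",
                "b": "AACA",
                "c": "ATGA",
                "d": "ATGC",
            },
        )
        # col0 constant; col1 two states twice each; col2 two states twice;
        # col3 has states A(2) C(1) and a gap -> not informative
        assert informative_sites(aln) == [1, 2]
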