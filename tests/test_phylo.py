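"""Phylogeny: distances, NJ consistency on additive matrices, bootstrap
behavior, and Newick round-trips."""

import math

import numpy as np
import pytest

from orthoprof.phylo import (
    DistanceMatrix, MultipleAlignment, additive_distance_matrix,
    bootstrap_support, edge_length_map, kimura_correction, leaf_labels,
    neighbor_joining, p_distance_matrix, parse_newick, random_additive_tree,
    support_values, tree_bipartitions, write_newick,
)
from orthoprof.synthetic import simulate_alignment_on_tree


class TestDistances:
    def test_identical_rows_have_zero_distance(self):
        aln = MultipleAlignment(["x", "y"], ["ACDEF", "ACDEF"])
        assert p_distance_matrix(aln).values[0, 1] == 0.0

    def test_simple_mismatch_count(self):
        aln = MultipleAlignment(["x", "y"], ["AAAA", "AAAC"])
        assert p_distance_matrix(aln).values[0, 1] == pytest.approx(0.25)

    def test_pairwise_gap_deletion(self):
        aln = MultipleAlignment(["x", "y"], ["A-CD", "AACD"])
        # 3 comparable columns, 0 mismatches
        assert p_distance_matrix(aln).values[0, 1] == 0.0

    def test_zero_comparable_columns_is_error_naming_pair(self):
        aln = MultipleAlignment(["left", "right"], ["A--", "-AA"])
        with pytest.raises(ValueError, match="left.*right"):
            p_distance_matrix(aln)

    def test_kimura_value(self):
        assert kimura_correction(0.5) == pytest.approx(-math.log(0.45), abs=1e-9)

    def test_kimura_saturation_error(self):
        aln = MultipleAlignment(["u", "v"], ["AAAAAAAAAA", "CCCCCCCCCC"])
        with pytest.raises(ValueError, match="saturation"):
            p_distance_matrix(aln, correction="kimura")

    def test_kimura_strictly_increasing(self):
        ps = np.linspace(0.0, 0.8, 30)
        ds = [kimura_correction(p) for p in ps]
        assert all(b > a for a, b in zip(ds, ds[1:]))

    def test_column_slice_restricts_computation(self):
        aln = MultipleAlignment(["x", "y"], ["AAAACC", "AAAAGG"])
        assert p_distance_matrix(aln, col_slice=(1, 4)).values[0, 1] == 0.0
        assert p_distance_matrix(aln, col_slice=(5, 6)).values[0, 1] == 1.0

    def test_matrix_axioms_on_simulated_alignment(self):
        rng = np.random.default_rng(31)
        seqs = simulate_alignment_on_tree(
            "((A:0.2,B:0.2):0.1,(C:0.2,D:0.2):0.1);", 300, rng)
        aln = MultipleAlignment(list(seqs), list(seqs.values()))
        dm = p_distance_matrix(aln)
        assert np.allclose(dm.values, dm.values.T)
        assert np.all(np.diag(dm.values) == 0)
        assert np.all(dm.values >= 0)


class TestNeighborJoining:
    def test_three_taxon_exact_lengths(self):
        dm = DistanceMatrix(["A", "B", "C"],
                            np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0]], float))
        lengths = edge_length_map(neighbor_joining(dm))
        assert lengths["A"] == pytest.approx(0.5)
        assert lengths["B"] == pytest.approx(1.5)
        assert lengths["C"] == pytest.approx(2.5)

    def test_two_taxa_single_edge(self):
        dm = DistanceMatrix(["A", "B"], np.array([[0, 3.5], [3.5, 0]]))
        tree = neighbor_joining(dm)
        pdm = additive_distance_matrix(tree)
        assert pdm.values[0, 1] == pytest.approx(3.5)

    def test_four_taxon_additive_matrix_recovered(self):
        # tree ((A:1,B:2):1,(C:3,D:4)) -> known pairwise path lengths
        ids = ["A", "B", "C", "D"]
        d = np.array([
            [0, 3, 5, 6],
            [3, 0, 6, 7],
            [5, 6, 0, 7],
            [6, 7, 7, 0],
        ], float)
        tree = neighbor_joining(DistanceMatrix(ids, d))
        assert tree_bipartitions(tree) == {frozenset({"C", "D"})}
        lengths = edge_length_map(tree)
        assert lengths["A"] == pytest.approx(1.0)
        assert lengths["B"] == pytest.approx(2.0)
        assert lengths["C"] == pytest.approx(3.0)
        assert lengths["D"] == pytest.approx(4.0)
        assert lengths[frozenset({"C", "D"})] == pytest.approx(1.0)

    def test_consistency_on_random_additive_matrices(self):
        rng = np.random.default_rng(32)
        for _ in range(25):
            n = int(rng.integers(4, 9))
            tree = random_additive_tree(n, rng)
            recovered = neighbor_joining(additive_distance_matrix(tree))
            assert tree_bipartitions(recovered) == tree_bipartitions(tree)
            truth, got = edge_length_map(tree), edge_length_map(recovered)
            for key, val in truth.items():
                assert got[key] == pytest.approx(val, abs=1e-9)

    def test_topology_agrees_with_independent_nj_implementation(self):
        # cross-check against scikit-bio's neighbor joining
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(37)
        for _ in range(10):
            tree = random_additive_tree(int(rng.integers(4, 8)), rng)
            dm = additive_distance_matrix(tree)
            mine = neighbor_joining(dm)
            theirs = skbio_nj(SkbioDM(dm.values, ids=dm.ids))
            theirs_parsed = parse_newick(str(theirs).strip())
            assert tree_bipartitions(mine) == tree_bipartitions(theirs_parsed)

    def test_invalid_matrix_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["A", "B"], np.array([[0, 1], [2, 0]], float))
        with pytest.raises(ValueError):
            DistanceMatrix(["A", "B"], np.array([[0, np.inf], [np.inf, 0]]))


class TestBootstrap:
    def test_fully_resolving_columns_give_unit_support(self):
        # every column repeats one pattern that cleanly splits AB|CD
        col = {"A": "A", "B": "A", "C": "C", "D": "C"}
        col2 = {"A": "A", "B": "C", "C": "G", "D": "H"}  # all-distinct filler
        ids = list("ABCD")
        seqs = ["".join([col[i], col2[i]] * 30) for i in ids]
        boot = bootstrap_support(MultipleAlignment(ids, seqs), n_reps=20, seed=1)
        assert set(boot.supports.values()) == {1.0}

    def test_supports_are_fractions(self):
        rng = np.random.default_rng(33)
        seqs = simulate_alignment_on_tree(
            "(((A:0.3,B:0.3):0.2,(C:0.3,D:0.3):0.2):0.1,(E:0.3,F:0.3):0.3);",
            200, rng)
        boot = bootstrap_support(MultipleAlignment(list(seqs), list(seqs.values())),
                                 n_reps=30, seed=2)
        assert all(0.0 <= s <= 1.0 for s in boot.supports.values())
        assert boot.n_success + boot.n_failed == 30

    def test_strong_signal_recovers_true_bipartitions(self):
        rng = np.random.default_rng(34)
        nwk = "(((A:0.15,B:0.15):0.2,(C:0.15,D:0.15):0.2):0.1,(E:0.15,F:0.15):0.3);"
        seqs = simulate_alignment_on_tree(nwk, 500, rng)
        boot = bootstrap_support(MultipleAlignment(list(seqs), list(seqs.values())),
                                 n_reps=100, seed=3)
        for part in tree_bipartitions(parse_newick(nwk)):
            assert boot.supports.get(part, 0.0) >= 0.70

    def test_deterministic_under_fixed_seed(self):
        rng = np.random.default_rng(35)
        seqs = simulate_alignment_on_tree(
            "((A:0.2,B:0.2):0.2,(C:0.2,D:0.2):0.2);", 150, rng)
        aln = MultipleAlignment(list(seqs), list(seqs.values()))
        b1 = bootstrap_support(aln, n_reps=25, seed=9)
        b2 = bootstrap_support(aln, n_reps=25, seed=9)
        assert b1.supports == b2.supports

    def test_invalid_rep_count_rejected(self):
        aln = MultipleAlignment(["a", "b"], ["AC", "AC"])
        with pytest.raises(ValueError):
            bootstrap_support(aln, n_reps=0)


class TestNewick:
    def test_round_trip_topology_lengths_supports(self):
        rng = np.random.default_rng(36)
        tree = random_additive_tree(6, rng)
        # attach fake supports to internal nodes
        for node in tree.preorder_node_iter():
            if node is not tree.seed_node and not node.is_leaf():
                node.label = repr(1 / 3)
        text = write_newick(tree)
        back = parse_newick(text)
        assert tree_bipartitions(back) == tree_bipartitions(tree)
        for key, val in edge_length_map(tree).items():
            assert edge_length_map(back)[key] == pytest.approx(val, abs=1e-9)
        assert set(support_values(back).values()) == {1 / 3}

    def test_two_leaf_parse(self):
        tree = parse_newick("(A:1,B:2);")
        assert leaf_labels(tree) == ["A", "B"]

    def test_malformed_input_raises_parse_error(self):
        with pytest.raises(ValueError, match="parse error"):
            parse_newick("((A:1,B:2;")
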