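"""Distances, neighbor joining, bootstrap supports, rooting, Newick IO."""

import numpy as np
import pytest

from rfamide import phylo
from rfamide.precursor import InputError
from _oracles import least_squares_topology, random_additive_matrix


def make_aln(rows: dict[str, str]) -> phylo.MultipleAlignment:
    return phylo.MultipleAlignment(list(rows), list(rows.values()))


def test_p_distance_and_poisson():
    aln = make_aln({"X": "AAAAAAAAAA", "Y": "AAAAAAAAGG", "Z": "AAAAAAAAAA"})
    p = phylo.pairwise_distance(aln, model="p")
    assert p.matrix[0, 1] == pytest.approx(0.2)
    assert p.matrix[0, 2] == 0.0
    poisson = phylo.pairwise_distance(aln, model="poisson")
    assert poisson.matrix[0, 1] == pytest.approx(-np.log(0.8), abs=1e-5)
    assert poisson.matrix[0, 2] == 0.0


def test_poisson_dominates_p():
    rng = np.random.default_rng(11)
    rows = ["".join("ACDEFG"[i] for i in rng.integers(0, 6, 60))
            for _ in range(4)]
    aln = phylo.MultipleAlignment(["a", "b", "c", "d"], rows)
    p = phylo.pairwise_distance(aln, "p").matrix
    poisson = phylo.pairwise_distance(aln, "poisson").matrix
    assert np.all(poisson >= p)
    assert np.all((poisson == p) == (p == 0))


def test_gap_modes_differ():
    aln = make_aln({"X": "A-AA", "Y": "AGAA", "Z": "AGCA"})
    pairwise = phylo.pairwise_distance(aln, "p", gap_mode="pairwise")
    complete = phylo.pairwise_distance(aln, "p", gap_mode="complete")
    # X vs Z: pairwise deletion compares 3 sites (1 mismatch), complete
    # deletion drops the gapped column entirely
    assert pairwise.matrix[0, 2] == pytest.approx(1 / 3)
    assert complete.matrix[0, 2] == pytest.approx(1 / 3)
    assert pairwise.matrix[1, 2] == pytest.approx(1 / 4)
    assert complete.matrix[1, 2] == pytest.approx(1 / 3)


def test_saturated_pair_raises():
    aln = make_aln({"X": "AAAA", "Y": "GGGG", "Z": "AAAA"})
    with pytest.raises(phylo.UndefinedDistanceError, match="X.*Y"):
        phylo.pairwise_distance(aln, "poisson")


def test_nj_three_taxa_branch_lengths():
    dm = phylo.DistanceMatrix(["A", "B", "C"],
                              np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float))
    tree = phylo.neighbor_joining(dm)
    lengths = {leaf.taxon.label: leaf.edge.length
               for leaf in tree.leaf_node_iter()}
    assert lengths == {"A": pytest.approx(1.0), "B": pytest.approx(1.0),
                       "C": pytest.approx(3.0)}


def test_nj_four_taxa_additive():
    d = np.array([[0, 2, 3, 3], [2, 0, 3, 3], [3, 3, 0, 2], [3, 3, 2, 0]], float)
    tree = phylo.neighbor_joining(phylo.DistanceMatrix(list("ABCD"), d))
    assert phylo.leaf_bipartitions(tree) == {frozenset({"C", "D"})}
    lengths = {leaf.taxon.label: leaf.edge.length
               for leaf in tree.leaf_node_iter()}
    assert all(v == pytest.approx(1.0) for v in lengths.values())
    internal = [n.edge.length for n in tree.preorder_node_iter()
                if not n.is_leaf() and n is not tree.seed_node]
    assert internal == [pytest.approx(1.0)]


def test_nj_label_order_invariance():
    rng = np.random.default_rng(5)
    d, _ = random_additive_matrix(list("ABCDE"), rng)
    ref_splits = phylo.leaf_bipartitions(
        phylo.neighbor_joining(phylo.DistanceMatrix(list("ABCDE"), d)))
    perm = [3, 1, 4, 0, 2]
    labels = ["ABCDE"[i] for i in perm]
    shuffled = phylo.DistanceMatrix(labels, d[np.ix_(perm, perm)])
    assert phylo.leaf_bipartitions(phylo.neighbor_joining(shuffled)) == ref_splits


def test_nj_asymmetric_rejected():
    bad = np.array([[0, 1, 2], [1.5, 0, 2], [2, 2, 0]])
    with pytest.raises(InputError):
        phylo.DistanceMatrix(list("ABC"), bad)


@pytest.mark.parametrize("n_taxa,seed", [(4, 0), (5, 1), (6, 2), (6, 3)])
def test_nj_matches_least_squares_oracle(n_taxa, seed):
    """On additive matrices NJ recovers the unique least-squares topology."""
    labels = [f"T{i}" for i in range(n_taxa)]
    rng = np.random.default_rng(seed)
    d, true_splits = random_additive_matrix(labels, rng)
    nj_splits = phylo.leaf_bipartitions(
        phylo.neighbor_joining(phylo.DistanceMatrix(labels, d)))
    ls_splits, resid = least_squares_topology(labels, d)
    assert resid < 1e-18
    assert nj_splits == ls_splits == true_splits


def test_negative_branch_clamped_with_warning():
    # strongly non-additive matrix known to produce a negative NJ estimate
    d = np.array([
        [0, 5, 9, 9, 8],
        [5, 0, 10, 10, 9],
        [9, 10, 0, 8, 7],
        [9, 10, 8, 0, 3],
        [8, 9, 7, 3, 0],
    ], float)
    d[0, 1] = d[1, 0] = 0.1  # force imbalance
    with pytest.warns(UserWarning, match="clamped"):
        tree = phylo.neighbor_joining(phylo.DistanceMatrix(list("ABCDE"), d))
    for node in tree.preorder_node_iter():
        if node.edge.length is not None:
            assert node.edge.length >= 0


def test_bootstrap_clean_signal_full_support():
    aln = make_aln({"A": "A" * 20, "B": "A" * 20,
                    "C": "G" * 10 + "A" * 10, "D": "G" * 10 + "A" * 10})
    for seed in (0, 7):
        _, supports = phylo.bootstrap_support(aln, n_reps=50, seed=seed)
        assert supports == {frozenset({"C", "D"}): 100.0}


def test_bootstrap_single_rep_supports_binary():
    aln = make_aln({"A": "AAAAAAAAAACCCCCCCCCC", "B": "AAAAAAAAAACCCCCCCCGG",
                    "C": "GGGGGAAAAACCCCCCCCCC", "D": "GGGGGAAAAACCCCCCCCGG"})
    _, supports = phylo.bootstrap_support(aln, n_reps=1, seed=0)
    assert set(supports.values()) <= {0.0, 100.0}


def test_bootstrap_seed_reproducible():
    rng = np.random.default_rng(4)
    rows = {lab: "".join("ACDEFGHIKL"[i] for i in rng.integers(0, 10, 40))
            for lab in "ABCDE"}
    aln = make_aln(rows)
    t1, s1 = phylo.bootstrap_support(aln, n_reps=20, seed=9)
    t2, s2 = phylo.bootstrap_support(aln, n_reps=20, seed=9)
    assert s1 == s2
    assert phylo.write_newick(t1) == phylo.write_newick(t2)


def test_rooting_roundtrip_and_supports_preserved():
    aln = make_aln({"A": "A" * 20, "B": "A" * 20,
                    "C": "G" * 10 + "A" * 10, "D": "G" * 10 + "A" * 10})
    tree, supports = phylo.bootstrap_support(aln, n_reps=20, seed=1)
    unrooted_splits = phylo.leaf_bipartitions(tree)
    rooted = phylo.root_with_outgroup(tree, "A")
    assert rooted.seed_node.num_child_nodes() == 2
    assert phylo.leaf_bipartitions(rooted) == unrooted_splits
    # the support stays attached to the CD bipartition, nowhere else
    for node in rooted.preorder_node_iter():
        if node.is_leaf() or node is rooted.seed_node:
            continue
        side = sorted(l.taxon.label for l in node.leaf_iter())
        if side == ["C", "D"]:
            assert node.label == "100"
        else:
            assert node.label is None
    # original tree untouched
    assert tree.seed_node.num_child_nodes() == 3


def test_rooting_three_taxa_shape():
    dm = phylo.DistanceMatrix(["A", "B", "C"],
                              np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float))
    rooted = phylo.root_with_outgroup(phylo.neighbor_joining(dm), "C")
    children = {tuple(sorted(l.taxon.label for l in c.leaf_iter()))
                for c in rooted.seed_node.child_nodes()}
    assert children == {("C",), ("A", "B")}


def test_root_missing_outgroup():
    dm = phylo.DistanceMatrix(["A", "B", "C"], np.zeros((3, 3)))
    tree = phylo.neighbor_joining(dm)
    with pytest.raises(InputError):
        phylo.root_with_outgroup(tree, "Z")


def test_newick_roundtrip_with_lengths():
    text = "((A:1.0,B:1.0):1.0,C:3.0);"
    assert phylo.write_newick(phylo.read_newick(text)) == text


def test_newick_missing_lengths_stay_absent():
    tree = phylo.read_newick("(A,B,C);")
    assert all(leaf.edge.length is None for leaf in tree.leaf_node_iter())


def test_newick_support_label_preserved():
    tree = phylo.read_newick("((A:1,B:1)98:1,(C:1,D:1):1);")
    assert "98" in phylo.write_newick(tree)


def test_newick_malformed_raises():
    with pytest.raises(InputError):
        phylo.read_newick("((A:1,B:1;")
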