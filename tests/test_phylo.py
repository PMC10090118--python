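import subprocess

import numpy as np
import pytest

from stuckenia.msa import Alignment, progressive_msa
from stuckenia.phylo import (
    DistanceMatrix,
    TreeNode,
    UndefinedDistanceError,
    bipartitions,
    bootstrap_support,
    nj_tree,
    p_distance_matrix,
    tn93_distance_matrix,
    to_newick,
)


def _aln(*rows):
    return Alignment([f"s{i}" for i in range(len(rows))], list(rows))


# --------------------------------------------------------------------------
# distances


def test_p_distance_examples():
    assert p_distance_matrix(_aln("ACGT", "ACGT"))[("s0", "s1")] == 0.0
    assert p_distance_matrix(_aln("ACGT", "ACGA"))[("s0", "s1")] == 0.25
    # pairwise deletion: the gapped column is excluded
    assert p_distance_matrix(_aln("AC-T", "ACGT"))[("s0", "s1")] == 0.0


def test_ambiguity_codes_are_missing_data_for_distances():
    # K vs G would be a mismatch by characters; as missing data it is skipped
    assert p_distance_matrix(_aln("AKGT", "AGGT"))[("s0", "s1")] == 0.0


def test_complete_deletion_drops_column_for_all_pairs():
    aln = _aln("ACGT", "AC-T", "ACGA")
    pd_pw = p_distance_matrix(aln, "pairwise")
    pd_cd = p_distance_matrix(aln, "complete")
    assert pd_pw[("s0", "s2")] == 0.25
    assert pd_cd[("s0", "s2")] == pytest.approx(1 / 3)


def test_no_comparable_columns_is_an_error():
    with pytest.raises(UndefinedDistanceError, match="s0"):
        p_distance_matrix(_aln("A--A", "-GG-"))


def test_tn93_zero_for_identical_rows():
    assert tn93_distance_matrix(_aln("ACGTACGT", "ACGTACGT"))[("s0", "s1")] == 0.0


def test_tn93_reduces_to_kimura_two_parameter_at_equal_frequencies():
    """With equal base frequencies and equal A<->G / C<->T transition
    proportions, TN93 must equal the K2P closed form computed independently."""
    s1 = "A" * 10 + "G" * 10 + "C" * 10 + "T" * 10
    s2 = (
        "G" + "T" + "A" * 8          # one A->G (ts), one A->T (tv)
        + "A" + "C" + "G" * 8        # one G->A (ts), one G->C (tv)
        + "T" + "G" + "C" * 8        # one C->T (ts), one C->G (tv)
        + "C" + "A" + "T" * 8        # one T->C (ts), one T->A (tv)
    )
    assert len(s2) == 40
    P, Q = 4 / 40, 4 / 40  # total transition and transversion proportions
    k2p = -0.5 * np.log(1 - 2 * P - Q) - 0.25 * np.log(1 - 2 * Q)
    got = tn93_distance_matrix(_aln(s1, s2))[("s0", "s1")]
    assert got == pytest.approx(k2p, abs=1e-12)


def test_tn93_approaches_p_distance_for_small_divergence():
    s1 = "ACGT" * 100
    s2 = "ACGA" + "ACGT" * 99  # one difference in 400 sites
    p = p_distance_matrix(_aln(s1, s2))[("s0", "s1")]
    d = tn93_distance_matrix(_aln(s1, s2))[("s0", "s1")]
    assert abs(d - p) < 1e-4


def test_tn93_never_below_p_distance():
    rng = np.random.default_rng(5)
    bases = np.array(list("ACGT"))
    for _ in range(20):
        s1 = "".join(bases[rng.integers(0, 4, 200)])
        s2 = list(s1)
        for k in rng.integers(0, 200, 40):
            s2[k] = bases[rng.integers(0, 4)]
        aln = _aln(s1, "".join(s2))
        p = p_distance_matrix(aln)[("s0", "s1")]
        d = tn93_distance_matrix(aln)[("s0", "s1")]
        if not np.isnan(d):
            assert d >= p - 1e-12


def test_tn93_saturated_pair_is_flagged_not_silently_numeric():
    dm = tn93_distance_matrix(_aln("A" * 30, "G" * 30))
    assert np.isnan(dm[("s0", "s1")])
    assert ("s0", "s1") in dm.flags


def test_tn93_matches_ape_reference_implementation(tmp_path):
    """Oracle: ape's dist.dna(model='TN93') on gap-free pairs, where its
    pooled-frequency convention coincides with per-pair frequencies."""
    rng = np.random.default_rng(0)
    bases = np.array(list("ACGT"))
    for trial in range(3):
        s1 = "".join(bases[rng.integers(0, 4, 300)])
        s2 = list(s1)
        for k in rng.integers(0, 300, 25):
            s2[k] = bases[rng.integers(0, 4)]
        aln = _aln(s1, "".join(s2))
        fa = tmp_path / f"pair{trial}.fasta"
        aln.to_fasta(fa)
        r = subprocess.run(
            [
                "Rscript", "-e",
                f'suppressMessages(library(ape));'
                f'd<-read.dna("{fa}", format="fasta");'
                f'cat(sprintf("%.10f",'
                f'as.matrix(dist.dna(d, model="TN93", pairwise.deletion=TRUE))[1,2]))',
            ],
            capture_output=True, text=True, check=True,
        )
        mine = tn93_distance_matrix(aln)[("s0", "s1")]
        assert mine == pytest.approx(float(r.stdout), abs=1e-8)


def test_distance_matrix_contract_enforced():
    with pytest.raises(ValueError, match="symmetric"):
        DistanceMatrix(("a", "b"), np.array([[0.0, 1.0], [2.0, 0.0]]))
    with pytest.raises(ValueError, match="diagonal"):
        DistanceMatrix(("a", "b"), np.array([[1.0, 1.0], [1.0, 0.0]]))


# --------------------------------------------------------------------------
# neighbor-joining


def _tree_distances(tree: TreeNode):
    """Leaf-to-leaf path lengths of a tree (the additivity oracle)."""
    dists = {}

    def paths(node, acc):
        if node.is_leaf:
            return {node.name: acc}
        out = {}
        for c in node.children:
            out.update(paths(c, acc + c.length))
        return out

    def collect(node):
        sub = []
        for c in node.children:
            sub.append(paths(c, c.length))
        for i in range(len(sub)):
            for j in range(i + 1, len(sub)):
                for la, da in sub[i].items():
                    for lb, db in sub[j].items():
                        dists[frozenset((la, lb))] = da + db
        for c in node.children:
            collect(c)

    collect(tree)
    return dists


def test_nj_recovers_known_quartet_exactly():
    # additive matrix of ((A:1,B:2):1,(C:3,D:1))
    labels = ("A", "B", "C", "D")
    M = np.array(
        [[0, 3, 5, 3], [3, 0, 6, 4], [5, 6, 0, 4], [3, 4, 4, 0]], dtype=float
    )
    tree = nj_tree(DistanceMatrix(labels, M))
    parts = set(bipartitions(tree))
    assert parts == {frozenset({"C", "D"})}  # canonical side excludes A
    got = _tree_distances(tree)
    for i, la in enumerate(labels):
        for j in range(i + 1, 4):
            assert got[frozenset((la, labels[j]))] == pytest.approx(M[i, j])


def test_nj_three_taxa_solves_three_point_equations():
    M = np.array([[0, 2, 3], [2, 0, 5], [3, 5, 0]], dtype=float)
    tree = nj_tree(DistanceMatrix(("a", "b", "c"), M))
    lengths = {c.name: c.length for c in tree.children}
    assert lengths["a"] == pytest.approx((2 + 3 - 5) / 2)
    assert lengths["b"] == pytest.approx((2 + 5 - 3) / 2)
    assert lengths["c"] == pytest.approx((3 + 5 - 2) / 2)


def _random_additive_matrix(rng, n_leaves):
    """Random binary tree with integer branch lengths; returns its
    path-length matrix and bipartition set (the generating truth)."""
    nodes = [TreeNode(name=f"L{i}", length=float(rng.integers(1, 9)))
             for i in range(n_leaves)]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        a, b = nodes[j], nodes[i]
        new = TreeNode(children=[a, b], length=float(rng.integers(1, 9)))
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)] + [new]
    root = TreeNode(children=nodes)
    dists = _tree_distances(root)
    labels = sorted(l.name for l in root.leaves())
    M = np.zeros((len(labels), len(labels)))
    for x, la in enumerate(labels):
        for y in range(x + 1, len(labels)):
            M[x, y] = M[y, x] = dists[frozenset((la, labels[y]))]
    return labels, M, set(bipartitions(root)), dists


def test_nj_exact_on_random_additive_matrices():
    rng = np.random.default_rng(123)
    for _ in range(20):
        n = int(rng.integers(4, 9))
        labels, M, true_parts, true_d = _random_additive_matrix(rng, n)
        tree = nj_tree(DistanceMatrix(tuple(labels), M))
        assert set(bipartitions(tree)) == true_parts
        got = _tree_distances(tree)
        for k, v in true_d.items():
            assert got[k] == pytest.approx(v)


def test_nj_topology_agrees_with_skbio():
    import skbio

    rng = np.random.default_rng(77)
    labels, M, true_parts, _ = _random_additive_matrix(rng, 7)
    sk_tree = skbio.tree.nj(skbio.DistanceMatrix(M, ids=labels))
    ref = min(labels)
    sk_parts = set()
    n = len(labels)
    for node in sk_tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if ref in side:
            side = frozenset(labels) - side
        if 2 <= len(side) <= n - 2:
            sk_parts.add(side)
    assert sk_parts == true_parts  # skbio confirms the generating topology


def test_nj_rejects_degenerate_input():
    with pytest.raises(ValueError):
        nj_tree(DistanceMatrix(("a", "b"), np.zeros((2, 2))))


# --------------------------------------------------------------------------
# bootstrap + newick


def test_bootstrap_identical_sequences_has_no_supported_bipartitions():
    aln = Alignment([f"s{i}" for i in range(5)], ["ACGTACGTAC"] * 5)
    tree = bootstrap_support(aln, replicates=20, seed=1)
    assert "100" not in to_newick(tree, support_threshold=50)


def test_bootstrap_reproducible_for_same_seed(panel):
    aln = progressive_msa(panel.records())
    t1 = bootstrap_support(aln, replicates=50, seed=9)
    t2 = bootstrap_support(aln, replicates=50, seed=9)
    assert to_newick(t1) == to_newick(t2)


def test_bootstrap_supports_invariant_under_leaf_order_permutation(panel):
    aln = progressive_msa(panel.records())
    perm = Alignment(aln.ids[::-1], aln.rows[::-1])
    t1 = bootstrap_support(aln, replicates=50, seed=9)
    t2 = bootstrap_support(perm, replicates=50, seed=9)
    s1 = {side: node.support for side, node in bipartitions(t1).items()}
    s2 = {side: node.support for side, node in bipartitions(t2).items()}
    assert s1 == s2


def test_newick_three_leaf_shape():
    tree = TreeNode(children=[
        TreeNode(name="A", length=1), TreeNode(name="B", length=1),
        TreeNode(name="C", length=1),
    ])
    assert to_newick(tree) == "(A:1.000000,B:1.000000,C:1.000000);"


def test_newick_hides_support_at_or_below_threshold():
    inner = TreeNode(children=[TreeNode(name="A", length=1),
                               TreeNode(name="B", length=1)],
                     length=1, support=49.0)
    tree = TreeNode(children=[inner, TreeNode(name="C", length=1),
                              TreeNode(name="D", length=1)])
    assert "49" not in to_newick(tree, support_threshold=50)
    inner.support = 51.0
    assert ")51:" in to_newick(tree, support_threshold=50)
    inner.support = 50.0  # strictly greater-than rule
    assert "50:" not in to_newick(tree, support_threshold=50)


def test_newick_round_trips_through_dendropy(panel):
    import dendropy

    aln = progressive_msa(panel.records())
    tree = bootstrap_support(aln, replicates=25, seed=2)
    nwk = to_newick(tree, support_threshold=50)
    parsed = dendropy.Tree.get(
        data=nwk, schema="newick", preserve_underscores=True
    )
    assert {t.label for t in parsed.taxon_namespace} == set(aln.ids)
    # re-serialize and re-parse: identical leaf set and branch lengths
    lengths = sorted(
        e.length for e in parsed.preorder_edge_iter() if e.length is not None
    )
    mine = sorted(
        round(n.length, 6) for n in tree.walk() if n is not tree
    )
    assert lengths == pytest.approx(mine)
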