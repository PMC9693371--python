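import numpy as np
import pytest

from familyscan.domain_scan import MybRepeatHit
from familyscan.phylogeny import (DomainAlignment, PhyloTree, TreeNode,
                                  assign_subgroups, bootstrap_support,
                                  build_domain_alignment, nj_tree, p_distance)
from familyscan.synthetic_data import generate_reference_panel


def _hit(pid, start, width):
    return MybRepeatHit(protein_id=pid, start=start, end=start + width - 1,
                        bits=99.0, evalue=1e-30, matched_columns=width)


class TestDomainAlignment:
    def test_two_r2r3_proteins_align_without_gaps(self, pssm):
        w = pssm.width
        seqs = {"a": "M" * 10 + "A" * w + "Q" * 5 + "C" * w,
                "b": "M" * 3 + "D" * w + "Q" * 8 + "E" * w}
        hits = {"a": [_hit("a", 11, w), _hit("a", 11 + w + 5, w)],
                "b": [_hit("b", 4, w), _hit("b", 4 + w + 8, w)]}
        aln = build_domain_alignment(hits, seqs, pssm)
        assert aln.n_columns == 2 * w
        assert set("".join(aln.rows)) <= set("ADCE")

    def test_one_repeat_protein_gets_gap_block(self, pssm):
        w = pssm.width
        seqs = {"a": "A" * w + "Q" * 5 + "C" * w, "b": "D" * w}
        hits = {"a": [_hit("a", 1, w), _hit("a", w + 6, w)],
                "b": [_hit("b", 1, w)]}
        aln = build_domain_alignment(hits, seqs, pssm)
        row_b = aln.rows[aln.ids.index("b")]
        assert row_b == "D" * w + "-" * w

    def test_fewer_than_two_proteins_errors(self, pssm):
        with pytest.raises(ValueError):
            build_domain_alignment({"a": [_hit("a", 1, pssm.width)]},
                                   {"a": "A" * pssm.width}, pssm)


class TestPDistance:
    def test_one_mismatch_in_four(self):
        aln = DomainAlignment(ids=["x", "y"], rows=["AAAA", "AAAT"])
        assert p_distance(aln)[0, 1] == pytest.approx(0.25)

    def test_identical_rows_distance_zero(self):
        aln = DomainAlignment(ids=["x", "y"], rows=["WKRL", "WKRL"])
        assert p_distance(aln)[0, 1] == 0.0

    def test_matches_brute_force_with_pairwise_deletion(self):
        rng = np.random.default_rng(0)
        rows = ["".join(rng.choice(list("ACDE-"), size=40)) for _ in range(4)]
        aln = DomainAlignment(ids=list("abcd"), rows=rows)
        D = p_distance(aln)
        for i in range(4):
            for j in range(4):
                cols = [(rows[i][k], rows[j][k]) for k in range(40)
                        if rows[i][k] != "-" and rows[j][k] != "-"]
                expected = sum(x != y for x, y in cols) / len(cols)
                assert D[i, j] == pytest.approx(expected)

    def test_no_comparable_columns_errors(self):
        aln = DomainAlignment(ids=["x", "y"], rows=["AA--", "--AA"])
        with pytest.raises(ValueError):
            p_distance(aln)


def random_additive_tree(n_leaves, rng):
    """A random binary tree with positive branch lengths and its leaf names."""
    nodes = [TreeNode(name=f"t{i}", length=float(rng.uniform(0.05, 1.0)))
             for i in range(n_leaves)]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = TreeNode(length=float(rng.uniform(0.05, 1.0)))
        parent.children = [nodes[i], nodes[j]]
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)] + [parent]
    root = TreeNode(children=nodes)
    return PhyloTree(root)


class TestNeighborJoining:
    def test_two_taxa_split_distance_in_half(self):
        tree = nj_tree(np.array([[0, 0.4], [0.4, 0]]), ["a", "b"])
        assert sorted(l.length for l in tree.root.leaves()) == [0.2, 0.2]

    def test_all_zero_matrix_gives_star_tree(self):
        tree = nj_tree(np.zeros((4, 4)), list("abcd"))
        assert len(tree.root.children) == 4
        assert all(c.length == 0 for c in tree.root.children)

    def test_asymmetric_matrix_errors(self):
        D = np.array([[0, 1.0], [2.0, 0]])
        with pytest.raises(ValueError):
            nj_tree(D, ["a", "b"])

    @pytest.mark.parametrize("n_leaves", [4, 5, 6, 8])
    def test_additive_distances_recover_tree_exactly(self, n_leaves):
        rng = np.random.default_rng(n_leaves)
        true = random_additive_tree(n_leaves, rng)
        names, D = true.patristic_distances()
        est = nj_tree(D, names)
        assert est.bipartitions() == true.bipartitions()
        est_names, est_D = est.patristic_distances()
        order = [est_names.index(nm) for nm in names]
        np.testing.assert_allclose(est_D[np.ix_(order, order)], D, atol=1e-9)

    def test_topology_agrees_with_scikit_bio(self):
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(3)
        true = random_additive_tree(6, rng)
        names, D = true.patristic_distances()
        ours = nj_tree(D, names).bipartitions()
        sk_tree = skbio_nj(DistanceMatrix(D, names))
        theirs = set()
        all_names = frozenset(names)
        for node in sk_tree.non_tips():
            below = frozenset(t.name for t in node.tips())
            if 1 < len(below) < len(names) - 1:
                theirs.add(min(below, all_names - below, key=lambda s: sorted(s)))
        assert ours == theirs


def _two_clade_alignment(n_cols=60):
    a = "A" * n_cols
    b = "A" * (n_cols - 6) + "CCCCCC"
    c = "W" * n_cols
    d = "W" * (n_cols - 6) + "DDDDDD"
    return DomainAlignment(ids=list("abcd"), rows=[a, b, c, d])


class TestBootstrap:
    def test_same_seed_reproduces_supports(self):
        aln = _two_clade_alignment()
        t1 = bootstrap_support(aln, 30, seed=5)
        t2 = bootstrap_support(aln, 30, seed=5)
        assert t1.newick() == t2.newick()

    def test_single_replicate_supports_are_zero_or_hundred(self):
        aln = _two_clade_alignment()
        tree = bootstrap_support(aln, 1, seed=1)
        sups = [n.support for n in _internal(tree.root) if n.support is not None]
        assert sups and all(s in (0.0, 100.0) for s in sups)

    def test_planted_clades_get_high_support(self):
        aln = _two_clade_alignment()
        tree = bootstrap_support(aln, 100, seed=2)
        sups = [n.support for n in _internal(tree.root) if n.support is not None]
        assert sups and min(sups) >= 95

    def test_supports_invariant_under_leaf_order_permutation(self):
        aln = _two_clade_alignment()
        perm = [2, 0, 3, 1]
        aln_p = DomainAlignment(ids=[aln.ids[i] for i in perm],
                                rows=[aln.rows[i] for i in perm])
        s1 = _split_supports(bootstrap_support(aln, 50, seed=9))
        s2 = _split_supports(bootstrap_support(aln_p, 50, seed=9))
        assert s1 == s2


def _internal(node):
    out = []
    if node.children:
        out.append(node)
        for c in node.children:
            out.extend(_internal(c))
    return out


def _split_supports(tree):
    all_leaves = frozenset(tree.leaf_names)
    out = {}

    def walk(node):
        if node.is_leaf:
            return frozenset([node.name])
        below = frozenset().union(*(walk(c) for c in node.children))
        if node.support is not None:
            key = min(below, all_leaves - below, key=lambda s: sorted(s))
            out[key] = node.support
        return below

    walk(tree.root)
    return out


class TestSubgroupAssignment:
    def test_query_takes_nearest_anchor_label(self):
        q = TreeNode(name="q", length=0.1)
        ref = TreeNode(name="C17_ref", length=0.1)
        far = TreeNode(name="C1_ref", length=2.0)
        inner = TreeNode(length=0.5, children=[q, ref])
        tree = PhyloTree(TreeNode(children=[inner, far]))
        got = assign_subgroups(tree, {"C17_ref": "C17", "C1_ref": "C1"})
        assert got == [type(got[0])("q", "C17", "C17_ref")]

    def test_no_reference_leaves_errors(self):
        tree = PhyloTree(TreeNode(children=[TreeNode(name="a", length=1),
                                            TreeNode(name="b", length=1)]))
        with pytest.raises(ValueError):
            assign_subgroups(tree, {"zzz": "C1"})

    def test_equidistant_tie_breaks_to_smaller_clade(self):
        # q is 0.3 from both anchors, but shares a clade of size 2 with r1
        q = TreeNode(name="q", length=0.1)
        r1 = TreeNode(name="r1", length=0.1)
        pair = TreeNode(length=0.05, children=[q, r1])
        r2 = TreeNode(name="r2", length=0.15)
        tree = PhyloTree(TreeNode(children=[pair, r2]))
        got = assign_subgroups(tree, {"r1": "X", "r2": "Y"})
        assert got[0].subgroup == "X"

    def test_planted_panel_membership_fully_recovered(self, pssm):
        panel = generate_reference_panel(["C1", "C17", "C20"], per_label=2,
                                         n_queries_per_label=3, seed=4, pssm=pssm)
        records = panel["anchors"] + panel["queries"]
        aln = DomainAlignment(ids=[r.id for r in records],
                              rows=[r.residues for r in records])
        tree = nj_tree(p_distance(aln), aln.ids)
        got = {a.protein_id: a.subgroup
               for a in assign_subgroups(tree, panel["anchor_labels"])}
        assert got == panel["query_labels"]
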