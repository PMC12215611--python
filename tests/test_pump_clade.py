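"""Alignment distances, neighbor joining, rooting, MRCA clades."""

import itertools

import dendropy
import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix, TreeNode

from plantfit import pump_clade as pc
from plantfit import synthetic_data as sd


class TestSelectFamily:
    def test_exact_tag_matches_only(self):
        ann = pd.DataFrame(
            {
                "seq_id": ["a", "b", "c"],
                "tag": ["COG0841", "COG0841", "COG0577"],
                "genome_id": ["g1", "g1", "g2"],
            }
        )
        hits = pc.select_family(ann, tag="COG0841")
        assert list(hits["seq_id"]) == ["a", "b"]

    def test_absent_tag_is_error(self):
        ann = pd.DataFrame({"seq_id": ["a"], "tag": ["COG0577"]})
        with pytest.raises(ValueError, match="no proteins"):
            pc.select_family(ann, tag="COG0841")


class TestPairwiseDistance:
    def test_identical_sequences_have_zero_distance(self):
        dm = pc.pairwise_distance({"a": "HEAGAWGHEE", "b": "HEAGAWGHEE"})
        assert dm["a", "b"] == pytest.approx(0.0)

    def test_textbook_pair_matches_independent_dp(self):
        """Full dynamic-programming (Gotoh affine) reimplementation as an
        oracle for the aligner score on the classic textbook pair."""
        s1, s2 = "HEAGAWGHEE", "PAWHEAE"
        from Bio.Align import substitution_matrices

        blosum = substitution_matrices.load("BLOSUM50")

        def gotoh(a, b, gap_open=10, gap_extend=1):
            n, m = len(a), len(b)
            neg = -1e9
            M = np.full((n + 1, m + 1), neg)
            X = np.full((n + 1, m + 1), neg)  # gap in b
            Y = np.full((n + 1, m + 1), neg)  # gap in a
            M[0, 0] = 0.0
            for i in range(1, n + 1):
                X[i, 0] = -gap_open - (i - 1) * gap_extend
            for j in range(1, m + 1):
                Y[0, j] = -gap_open - (j - 1) * gap_extend
            for i in range(1, n + 1):
                for j in range(1, m + 1):
                    s = blosum[a[i - 1], b[j - 1]]
                    best_prev = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
                    M[i, j] = best_prev + s
                    X[i, j] = max(M[i - 1, j] - gap_open, X[i - 1, j] - gap_extend,
                                  Y[i - 1, j] - gap_open)
                    Y[i, j] = max(M[i, j - 1] - gap_open, Y[i, j - 1] - gap_extend,
                                  X[i, j - 1] - gap_open)
            return max(M[n, m], X[n, m], Y[n, m])

        s12 = gotoh(s1, s2)
        s11 = gotoh(s1, s1)
        s22 = gotoh(s2, s2)
        expected = 1.0 - s12 / min(s11, s22)
        dm = pc.pairwise_distance({"a": s1, "b": s2})
        assert dm["a", "b"] == pytest.approx(expected)

    def test_symmetry_on_random_pairs(self):
        rng = np.random.default_rng(0)
        aa = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        seqs = {f"s{i}": "".join(rng.choice(aa, size=30)) for i in range(4)}
        dm = pc.pairwise_distance(seqs)
        mat = np.asarray(dm.data)
        assert np.allclose(mat, mat.T)
        assert np.allclose(np.diag(mat), 0.0)

    def test_empty_sequence_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            pc.pairwise_distance({"a": "", "b": "PAW"})


def _tree_distances(tree):
    tips = sorted(t.name for t in tree.tips())
    out = {}
    for a, b in itertools.combinations(tips, 2):
        out[(a, b)] = tree.find(a).distance(tree.find(b))
    return out


def _random_additive_tree(rng, n_taxa):
    """A random binary tree with positive branch lengths and its distances."""
    nodes = [TreeNode(name=f"t{i}") for i in range(n_taxa)]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[j], nodes[i]
        a.length = float(rng.uniform(0.1, 2.0))
        b.length = float(rng.uniform(0.1, 2.0))
        parent = TreeNode(children=[b, a])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    for n in nodes:
        n.length = float(rng.uniform(0.1, 2.0))
    tree = TreeNode(children=nodes)
    tips = sorted(t.name for t in tree.tips())
    d = np.zeros((len(tips), len(tips)))
    for x, a in enumerate(tips):
        for y in range(x + 1, len(tips)):
            d[x, y] = d[y, x] = tree.find(a).distance(tree.find(tips[y]))
    return tree, DistanceMatrix(d, tips)


class TestNeighborJoining:
    def test_four_taxon_additive_matrix_recovered_exactly(self):
        # distances from tree ((A:1,B:2):1,(C:3,D:4))
        ids = ["A", "B", "C", "D"]
        d = np.array(
            [
                [0, 3, 5, 6],
                [3, 0, 6, 7],
                [5, 6, 0, 7],
                [6, 7, 7, 0],
            ],
            dtype=float,
        )
        tree = pc.neighbor_joining(DistanceMatrix(d, ids))
        dist = _tree_distances(tree)
        assert dist[("A", "B")] == pytest.approx(3.0)
        assert dist[("C", "D")] == pytest.approx(7.0)
        assert dist[("A", "C")] == pytest.approx(5.0)
        assert dist[("B", "D")] == pytest.approx(7.0)
        # split AB|CD: the path A-B does not touch the path C-D
        ab = tree.lca(["A", "B"])
        assert {t.name for t in ab.tips()} in ({"A", "B"}, {"C", "D"})

    def test_three_taxa_closed_form(self):
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        tree = pc.neighbor_joining(DistanceMatrix(d, ["a", "b", "c"]))
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["a"] == pytest.approx((3 + 4 - 5) / 2)
        assert lengths["b"] == pytest.approx((3 + 5 - 4) / 2)
        assert lengths["c"] == pytest.approx((4 + 5 - 3) / 2)

    def test_random_additive_trees_recovered_at_rf_zero(self):
        """50 random additive trees (<=8 taxa): NJ reproduces the topology
        (Robinson-Foulds 0, via dendropy) and all path lengths."""
        rng = np.random.default_rng(12)
        for rep in range(50):
            n_taxa = int(rng.integers(4, 9))
            true_tree, dm = _random_additive_tree(rng, n_taxa)
            est = pc.neighbor_joining(dm)
            est_d = _tree_distances(est)
            for (a, b), v in _tree_distances(true_tree).items():
                assert est_d[(a, b)] == pytest.approx(v, abs=1e-9)
            taxa = dendropy.TaxonNamespace()
            t1 = dendropy.Tree.get(data=str(true_tree), schema="newick",
                                   taxon_namespace=taxa)
            t2 = dendropy.Tree.get(data=str(est), schema="newick",
                                   taxon_namespace=taxa)
            t1.encode_bipartitions()
            t2.encode_bipartitions()
            rf = dendropy.calculate.treecompare.symmetric_difference(t1, t2)
            assert rf == 0

    def test_agrees_with_skbio_nj_on_additive_input(self):
        rng = np.random.default_rng(3)
        _, dm = _random_additive_tree(rng, 6)
        ours = pc.neighbor_joining(dm)
        import skbio.tree

        theirs = skbio.tree.nj(dm)
        ours_d = _tree_distances(ours)
        theirs_d = _tree_distances(theirs)
        for key, v in ours_d.items():
            assert theirs_d[key] == pytest.approx(v, abs=1e-6)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            pc.neighbor_joining(DistanceMatrix(np.zeros((2, 2)), ["a", "b"]))


class TestMidpointRootAndMrca:
    def test_two_leaf_midpoint(self):
        tree = TreeNode.read(["(a:1,b:3);"])
        rooted = pc.midpoint_root(tree)
        dists = {t.name: rooted.find(t.name).accumulate_to_ancestor(rooted)
                 for t in rooted.tips()}
        assert dists["a"] == pytest.approx(2.0)
        assert dists["b"] == pytest.approx(2.0)

    def test_rerooting_preserves_leaf_path_lengths(self):
        rng = np.random.default_rng(4)
        tree, _ = _random_additive_tree(rng, 7)
        before = _tree_distances(tree)
        after = _tree_distances(pc.midpoint_root(tree))
        for key, v in before.items():
            assert after[key] == pytest.approx(v, abs=1e-9)

    def test_sibling_anchors_define_their_pair(self):
        tree = TreeNode.read(["((a:1,b:1):1,(c:1,d:1):1);"])
        assert pc.mrca_clade(tree, ["a", "b"]) == ["a", "b"]
        assert pc.mrca_clade(tree, ["a", "c"]) == ["a", "b", "c", "d"]

    def test_single_anchor_is_its_own_clade(self):
        tree = TreeNode.read(["((a:1,b:1):1,c:2);"])
        assert pc.mrca_clade(tree, ["a"]) == ["a"]

    def test_unknown_anchor_is_error(self):
        tree = TreeNode.read(["((a:1,b:1):1,c:2);"])
        with pytest.raises(ValueError, match="not in tree"):
            pc.mrca_clade(tree, ["zz"])

    def test_clade_is_monotone_in_anchors(self):
        tree = TreeNode.read(["(((a:1,b:1):1,c:2):1,(d:1,e:1):2);"])
        small = set(pc.mrca_clade(tree, ["a", "b"]))
        bigger = set(pc.mrca_clade(tree, ["a", "b", "c"]))
        biggest = set(pc.mrca_clade(tree, ["a", "b", "c", "d"]))
        assert small <= bigger <= biggest


class TestPrevalenceSummary:
    def test_fraction_and_copy_number(self):
        meta = pd.DataFrame(
            {
                "seq_id": [f"s{i}" for i in range(12)],
                "genome_id": [f"g{i % 10}" for i in range(12)],
                "class": ["Alpha"] * 12,
            }
        )
        # members cover 9 of the 10 genomes; genome g0 has 2 copies (s0, s10)
        members = [f"s{i}" for i in range(9)] + ["s10"]
        prevalence, copies = pc.prevalence_summary(members, meta)
        assert prevalence["Alpha"] == pytest.approx(0.9)
        assert copies["g0"] == 2
        assert copies["g9"] == 0

    def test_missing_class_warns_when_requested(self):
        meta = pd.DataFrame(
            {"seq_id": ["s0"], "genome_id": ["g0"], "class": ["Alpha"]}
        )
        with pytest.warns(UserWarning, match="no genomes"):
            prevalence, _ = pc.prevalence_summary(["s0"], meta,
                                                  classes=["Alpha", "Beta"])
        assert list(prevalence.index) == ["Alpha"]


class TestEndToEndCladeRecovery:
    def test_designed_clade_recovered_over_seeds(self):
        for seed in range(8):
            fam = sd.simulate_protein_family(seed=seed)
            report = pc.call_clade(fam.sequences, fam.metadata)
            assert report.members == sorted(fam.clade_ids)
            assert set(report.anchors) <= set(report.members)
            assert ((report.prevalence >= 0) & (report.prevalence <= 1)).all()

    def test_pipeline_invariant_to_sequence_order(self):
        fam = sd.simulate_protein_family(seed=2)
        rev = dict(reversed(list(fam.sequences.items())))
        r1 = pc.call_clade(fam.sequences, fam.metadata)
        r2 = pc.call_clade(rev, fam.metadata)
        assert r1.members == r2.members
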