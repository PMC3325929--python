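"""TN93 distances, neighbour joining, and bootstrap support."""

import math

import dendropy
import numpy as np
import pytest

from mtpop.phylo import (
    SATURATED,
    DistanceMatrix,
    bootstrap_support,
    distance_matrix,
    nj_tree,
    p_distance,
    tn93_distance,
    tree_length,
    write_newick,
    _internal_split_masks,
)


def _random_pair(rng, L=600, p_mut=0.1):
    a = "".join(rng.choice(list("ACGT"), size=L))
    b = list(a)
    for i in range(L):
        if rng.random() < p_mut:
            b[i] = rng.choice([x for x in "ACGT" if x != a[i]])
    return a, "".join(b)


class TestTN93:
    def test_identical_sequences_zero(self):
        s = "ACGT" * 100
        assert tn93_distance(s, s) == 0.0

    def test_symmetry(self, rng):
        for _ in range(100):
            a, b = _random_pair(rng, L=200)
            assert tn93_distance(a, b) == pytest.approx(tn93_distance(b, a))

    def test_equal_frequency_limit_equals_k2p(self):
        """With equal base frequencies and P1 = P2, TN93 reduces to Kimura 2P."""
        L = 1000
        a = "ACGT" * (L // 4)
        b = list(a)
        x, y = 30, 10  # balanced transitions / transversions keep freqs equal
        idx = {base: [i for i, c in enumerate(a) if c == base] for base in "ACGT"}
        for i in idx["A"][:x]:
            b[i] = "G"
        for i in idx["G"][:x]:
            b[i] = "A"
        for i in idx["C"][:x]:
            b[i] = "T"
        for i in idx["T"][:x]:
            b[i] = "C"
        for i in idx["A"][x : x + y]:
            b[i] = "C"
        for i in idx["C"][x : x + y]:
            b[i] = "A"
        for i in idx["G"][x : x + y]:
            b[i] = "T"
        for i in idx["T"][x : x + y]:
            b[i] = "G"
        b = "".join(b)
        P = 4 * x / L  # total transition fraction
        Q = 4 * y / L
        k2p = -0.5 * math.log(1 - 2 * P - Q) - 0.25 * math.log(1 - 2 * Q)
        assert tn93_distance(a, b) == pytest.approx(k2p, rel=1e-9)

    def test_correction_never_below_p_distance(self, rng):
        for _ in range(30):
            a, b = _random_pair(rng, L=400, p_mut=0.15)
            d = tn93_distance(a, b)
            if math.isfinite(d):
                assert d >= p_distance(a, b) - 1e-12

    def test_saturation_flagged_not_raised(self):
        a = "AG" * 200
        b = "GA" * 200  # every site a purine transition
        assert tn93_distance(a, b) == SATURATED

    def test_non_acgt_sites_ignored_pairwise(self):
        a = "ACGTNNACGT"
        b = "ACGTACACGT"  # mismatches only inside the N columns
        assert tn93_distance(a, b) == 0.0


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], dtype=float)
        tree = nj_tree(DistanceMatrix(("A", "B", "C"), d))
        lengths = {
            leaf.taxon.label: leaf.edge.length for leaf in tree.leaf_node_iter()
        }
        assert lengths["A"] == pytest.approx((5 + 9 - 10) / 2)
        assert lengths["B"] == pytest.approx((5 + 10 - 9) / 2)
        assert lengths["C"] == pytest.approx((9 + 10 - 5) / 2)

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(("A", "B"), np.array([[0.0, 1.0], [1.0, 0.0]])))

    def test_additive_six_leaf_recovery(self):
        """NJ recovers topology and branch lengths from additive distances."""
        newick = "((A:0.10,B:0.20):0.05,(C:0.30,D:0.10):0.07,(E:0.20,F:0.25):0.06);"
        src = dendropy.Tree.get(data=newick, schema="newick")
        pdm = src.phylogenetic_distance_matrix()
        taxa = sorted(src.taxon_namespace, key=lambda t: t.label)
        ids = tuple(t.label for t in taxa)
        n = len(ids)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
        tree = nj_tree(DistanceMatrix(ids, d), taxon_namespace=src.taxon_namespace)
        assert _internal_split_masks(tree) == _internal_split_masks(src)
        assert tree_length(tree) == pytest.approx(tree_length(src))

    @pytest.mark.parametrize("n_leaves", [5, 8])
    def test_additive_random_tree_recovery(self, n_leaves, rng):
        """Consistency on random additive matrices up to 8 leaves."""
        ns = dendropy.TaxonNamespace([f"t{i}" for i in range(n_leaves)])
        for trial in range(5):
            # random binary unrooted tree by sequential leaf attachment
            tree = dendropy.Tree(taxon_namespace=ns)
            a, b, c = (dendropy.Node(taxon=ns[i]) for i in range(3))
            for node in (a, b, c):
                tree.seed_node.add_child(node)
                node.edge.length = float(rng.uniform(0.05, 0.5))
            leaves = [a, b, c]
            for i in range(3, n_leaves):
                target = leaves[int(rng.integers(len(leaves)))]
                parent = target.parent_node
                mid = dendropy.Node()
                parent.remove_child(target)
                parent.add_child(mid)
                mid.edge.length = float(rng.uniform(0.05, 0.5))
                mid.add_child(target)
                new_leaf = dendropy.Node(taxon=ns[i])
                new_leaf.edge.length = float(rng.uniform(0.05, 0.5))
                mid.add_child(new_leaf)
                leaves.append(new_leaf)
            tree.is_rooted = False
            pdm = tree.phylogenetic_distance_matrix()
            ids = tuple(t.label for t in ns)
            n = len(ids)
            d = np.zeros((n, n))
            for i in range(n):
                for j in range(i + 1, n):
                    d[i, j] = d[j, i] = pdm.patristic_distance(ns[i], ns[j])
            got = nj_tree(DistanceMatrix(ids, d), taxon_namespace=ns)
            assert _internal_split_masks(got) == _internal_split_masks(tree)

    def test_star_matrix_four_taxa_minimum_length(self):
        """Equal distances: any resolution, but total length is the 4-taxon optimum."""
        d = np.ones((4, 4)) - np.eye(4)
        tree = nj_tree(DistanceMatrix(("A", "B", "C", "D"), d))
        # closed-form optimum for d=1 everywhere: 4 external x 0.5, internal 0
        assert tree_length(tree) == pytest.approx(2.0)

    def test_matches_independent_nj_implementation(self, rng):
        """Topologies agree with scikit-bio's neighbour joining."""
        skbio = pytest.importorskip("skbio")
        from skbio.tree import nj as skbio_nj

        for trial in range(5):
            n = 7
            ids = tuple(f"t{i}" for i in range(n))
            m = rng.uniform(0.1, 1.0, size=(n, n))
            d = (m + m.T) / 2
            np.fill_diagonal(d, 0.0)
            mine = nj_tree(DistanceMatrix(ids, d))
            theirs = skbio_nj(skbio.DistanceMatrix(d, ids))
            ns = mine.taxon_namespace
            ref_tree = dendropy.Tree.get(
                data=str(theirs).strip(), schema="newick", taxon_namespace=ns
            )
            ref_tree.is_rooted = False
            assert _internal_split_masks(mine) == _internal_split_masks(ref_tree)

    def test_saturated_matrix_rejected(self):
        d = np.array([[0, np.inf, 1], [np.inf, 0, 1], [1, 1, 0.0]])
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(("A", "B", "C"), d))


class TestBootstrap:
    @staticmethod
    def _two_clade_alignment(rng, n_per_clade=5, L=600, n_fixed=40):
        base = "".join(rng.choice(list("ACGT"), size=L))
        fixed_sites = rng.choice(L, size=n_fixed, replace=False)
        other = list(base)
        for s in fixed_sites:
            other[s] = [x for x in "ACGT" if x != base[s]][0]
        other = "".join(other)
        seqs = {}
        for k, founder in (("a", base), ("b", other)):
            for i in range(n_per_clade):
                s = list(founder)
                for _ in range(2):  # a couple of private mutations
                    p = int(rng.integers(L))
                    s[p] = rng.choice([x for x in "ACGT" if x != s[p]])
                seqs[f"{k}{i}"] = "".join(s)
        return seqs

    def test_same_seed_identical_output(self, rng, tmp_path):
        seqs = self._two_clade_alignment(rng)
        t1 = bootstrap_support(seqs, reps=50, seed=11)
        t2 = bootstrap_support(seqs, reps=50, seed=11)
        p1, p2 = tmp_path / "a.nwk", tmp_path / "b.nwk"
        write_newick(t1, p1)
        write_newick(t2, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_seed_required(self, rng):
        with pytest.raises(ValueError):
            bootstrap_support(self._two_clade_alignment(rng), reps=10, seed=None)

    def test_deep_split_gets_high_support(self, rng):
        seqs = self._two_clade_alignment(rng)
        tree = bootstrap_support(seqs, reps=100, seed=17)
        clade_a = {sid for sid in seqs if sid.startswith("a")}
        found = None
        for node in tree.preorder_internal_node_iter():
            if node is tree.seed_node:
                continue
            leaves = {l.taxon.label for l in node.leaf_iter()}
            if leaves == clade_a or leaves == set(seqs) - clade_a:
                found = int(node.label)
        assert found is not None and found >= 99

    def test_degenerate_alignment_warns_with_full_support(self):
        seqs = {f"s{i}": "ACGT" * 25 for i in range(4)}
        with pytest.warns(UserWarning):
            tree = bootstrap_support(seqs, reps=10, seed=1)
        labels = [
            int(n.label)
            for n in tree.preorder_internal_node_iter()
            if n is not tree.seed_node and n.label is not None
        ]
        assert labels and all(v == 100 for v in labels)


def test_distance_matrix_properties(rng):
    seqs = {f"s{i}": "".join(rng.choice(list("ACGT"), size=300)) for i in range(5)}
    dm = distance_matrix(seqs)
    assert np.allclose(dm.values, dm.values.T)
    assert np.allclose(np.diag(dm.values), 0.0)
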