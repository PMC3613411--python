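"""Relative-rate tests, protein distances, NJ trees, bootstrap."""

import dendropy
import numpy as np
import pytest

from _oracles import unique_substitution_tally
from genelosskit.gene_models import read_newick
from genelosskit.rate_phylo import (
    DistanceMatrix,
    ProteinAlignment,
    bipartitions,
    bootstrap_support,
    count_unique_substitutions,
    nj,
    p_distance,
    poisson_distance,
    relative_rate_test,
    root_tree,
    tajima_chi2,
)
from genelosskit.simulate import make_relative_rate_case

AA = "ACDEFGHIKLMNPQRSTVWY"


class TestUniqueSubstitutions:
    def test_identical_rows(self):
        aln = ProteinAlignment(rows={"a": "MKV", "b": "MKV", "o": "MKV"})
        assert count_unique_substitutions(aln, "a", "b", "o") == (0, 0)

    def test_single_unique_substitution(self):
        aln = ProteinAlignment(rows={"a": "MKV", "b": "MKA", "o": "MKA"})
        assert count_unique_substitutions(aln, "a", "b", "o") == (1, 0)

    def test_gap_and_x_columns_excluded(self):
        aln = ProteinAlignment(rows={"a": "MKVA-", "b": "MXVAC",
                                     "o": "MAVAC"})
        # col 2: X in b -> excluded; col 5: gap in a -> excluded
        assert count_unique_substitutions(aln, "a", "b", "o") == (0, 0)

    def test_all_three_differ_counts_neither(self):
        aln = ProteinAlignment(rows={"a": "A", "b": "C", "o": "D"})
        n_a, n_b, n_unif = count_unique_substitutions(
            aln, "a", "b", "o", return_uninformative=True)
        assert (n_a, n_b, n_unif) == (0, 0, 1)

    def test_self_comparison_yields_zero(self):
        aln = ProteinAlignment(rows={"a": "MKVAC", "o": "MAVAD"})
        n_a, n_b = count_unique_substitutions(aln, "a", "a", "o")
        assert n_a == 0 and n_b == 0

    def test_unknown_id_rejected(self):
        aln = ProteinAlignment(rows={"a": "M", "b": "M", "o": "M"})
        with pytest.raises(KeyError):
            count_unique_substitutions(aln, "a", "b", "zzz")

    def test_simulated_triple_matches_hand_tally(self):
        aln, _ = make_relative_rate_case(0.10, 0.05, 500, seed=17)
        ours = count_unique_substitutions(aln, "lineage_a", "lineage_b",
                                          "outgroup")
        oracle = unique_substitution_tally(aln.rows["lineage_a"],
                                           aln.rows["lineage_b"],
                                           aln.rows["outgroup"])
        assert ours == oracle


class TestTajimaChi2:
    @pytest.mark.parametrize("na,nb,chi2_2dp", [
        (22, 15, 1.32), (23, 12, 3.46), (21, 19, 0.1), (18, 25, 1.14),
        (48, 10, 24.9), (52, 11, 26.68), (47, 15, 16.52), (44, 21, 8.14),
    ])
    def test_published_count_pairs(self, na, nb, chi2_2dp):
        """The eight published unique-substitution pairs reproduce the
        printed chi-squares to 2 decimal places (no continuity
        correction)."""
        assert round(tajima_chi2(na, nb).chi_square, 2) == chi2_2dp

    def test_zero_counts(self):
        r = tajima_chi2(0, 0)
        assert r.chi_square == 0.0 and r.p_value == 1.0

    def test_symmetry(self):
        a, b = tajima_chi2(31, 7), tajima_chi2(7, 31)
        assert a.chi_square == b.chi_square and a.p_value == b.p_value

    def test_published_p_values(self):
        assert round(tajima_chi2(22, 15).p_value, 2) == 0.25
        assert round(tajima_chi2(21, 19).p_value, 2) == 0.75
        assert tajima_chi2(52, 11).p_value < 0.01

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            tajima_chi2(-1, 3)

    def test_full_test_from_alignment(self):
        aln, _ = make_relative_rate_case(0.12, 0.04, 800, seed=3)
        r = relative_rate_test(aln, "lineage_a", "lineage_b", "outgroup")
        assert r.n_a > r.n_b
        assert r.chi_square == pytest.approx(
            (r.n_a - r.n_b) ** 2 / (r.n_a + r.n_b))


class TestDistances:
    def test_identical_rows(self):
        aln = ProteinAlignment(rows={"a": "MKVA" * 25, "b": "MKVA" * 25})
        assert p_distance(aln, "a", "b") == 0.0
        assert poisson_distance(aln, "a", "b") == 0.0

    def test_one_mismatch_in_hundred(self):
        a = "A" * 100
        b = "C" + "A" * 99
        aln = ProteinAlignment(rows={"a": a, "b": b})
        assert p_distance(aln, "a", "b") == pytest.approx(0.01)

    def test_poisson_exceeds_p_when_positive(self, rng):
        for _ in range(20):
            n = 200
            a = "".join(AA[i] for i in rng.integers(0, 20, n))
            b = "".join(
                AA[(i + int(rng.random() < 0.3) * int(rng.integers(1, 20)))
                   % 20]
                for i in (ord(c) % 20 for c in a))
            aln = ProteinAlignment(rows={"a": a, "b": b})
            p = p_distance(aln, "a", "b")
            d = poisson_distance(aln, "a", "b")
            assert d >= p
            if p > 0:
                assert d > p

    def test_saturated_distance_rejected(self):
        aln = ProteinAlignment(rows={"a": "AAAA", "b": "CCCC"})
        with pytest.raises(ValueError, match="saturated"):
            poisson_distance(aln, "a", "b")

    def test_no_comparable_columns_rejected(self):
        aln = ProteinAlignment(rows={"a": "A--", "b": "-CC"})
        with pytest.raises(ValueError, match="comparable"):
            p_distance(aln, "a", "b")


def _additive_matrix_from_tree(tree: dendropy.Tree) -> DistanceMatrix:
    """Path-length distances between tips (the independent route NJ must
    invert)."""
    pdm = tree.phylogenetic_distance_matrix()
    labels = sorted(t.label for t in tree.taxon_namespace)
    n = len(labels)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ti = tree.taxon_namespace.get_taxon(labels[i])
            tj = tree.taxon_namespace.get_taxon(labels[j])
            values[i, j] = values[j, i] = pdm.patristic_distance(ti, tj)
    return DistanceMatrix(labels=labels, values=values)


def _random_bl_tree(rng, n_tips):
    nodes = [f"T{i}:{rng.integers(1, 9)}" for i in range(n_tips)]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b}):{rng.integers(1, 9)}")
    return f"({nodes[0]},{nodes[1]});"


class TestNeighborJoining:
    def test_four_taxon_additive_recovery_exact(self):
        # ((A:1,B:2):1,(C:3,D:1)) -> dAB=3 dAC=5 dAD=3 dBC=6 dBD=4 dCD=4
        dm = DistanceMatrix(
            labels=["A", "B", "C", "D"],
            values=np.array([[0, 3, 5, 3], [3, 0, 6, 4],
                             [5, 6, 0, 4], [3, 4, 4, 0]], float))
        tree = nj(dm)
        assert bipartitions(tree) == {frozenset({"C", "D"})}
        lengths = {l.taxon.label: l.edge.length
                   for l in tree.leaf_node_iter()}
        assert lengths == {"A": 1.0, "B": 2.0, "C": 3.0, "D": 1.0}

    def test_three_taxa_star(self):
        dm = DistanceMatrix(labels=["A", "B", "C"],
                            values=np.array([[0, 2, 3], [2, 0, 3],
                                             [3, 3, 0]], float))
        tree = nj(dm)
        assert len(tree.seed_node.child_nodes()) == 3
        assert bipartitions(tree) == set()

    def test_label_permutation_invariance(self, rng):
        labels = ["A", "B", "C", "D", "E"]
        text = _random_bl_tree(rng, 5).replace("T0", "A").replace(
            "T1", "B").replace("T2", "C").replace("T3", "D").replace(
            "T4", "E")
        dm = _additive_matrix_from_tree(read_newick(text))
        base = bipartitions(nj(dm))
        for _ in range(5):
            perm = list(rng.permutation(len(labels)))
            pl = [dm.labels[i] for i in perm]
            pv = dm.values[np.ix_(perm, perm)]
            assert bipartitions(nj(DistanceMatrix(pl, pv))) == base

    def test_additive_recovery_random_trees(self, rng):
        """NJ is exact on additive matrices: the generating topology is
        recovered for random 4-8 taxon trees with integer branch lengths."""
        for _ in range(40):
            n = int(rng.integers(4, 9))
            source = read_newick(_random_bl_tree(rng, n))
            dm = _additive_matrix_from_tree(source)
            recovered = nj(dm)
            source.is_rooted = False
            assert bipartitions(recovered) == bipartitions(source)

    def test_agrees_with_skbio_on_random_additive_matrices(self, rng):
        skbio = pytest.importorskip("skbio")
        from skbio.tree import nj as skbio_nj

        for _ in range(10):
            n = int(rng.integers(4, 8))
            dm = _additive_matrix_from_tree(
                read_newick(_random_bl_tree(rng, n)))
            ours = bipartitions(nj(dm))
            sk_tree = skbio_nj(skbio.DistanceMatrix(dm.values, dm.labels))
            theirs = bipartitions(read_newick(str(sk_tree)))
            assert ours == theirs

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(labels=["A", "B"],
                           values=np.array([[0, 1], [2, 0]], float))


def _two_cluster_alignment(rng, n_cols=300, within=0.03):
    base1 = rng.integers(0, 20, n_cols)
    base2 = (base1 + rng.integers(1, 20, n_cols)) % 20

    def noisy(base):
        hit = rng.random(n_cols) < within
        return np.where(hit, (base + rng.integers(1, 20, n_cols)) % 20, base)

    rows = {}
    for name, base in (("a1", base1), ("a2", base1), ("a3", base1),
                       ("b1", base2), ("b2", base2), ("b3", base2)):
        rows[name] = "".join(AA[x] for x in noisy(base))
    return ProteinAlignment(rows=rows)


class TestBootstrap:
    def test_separated_clusters_strongly_supported(self, rng):
        aln = _two_cluster_alignment(rng)
        support = bootstrap_support(aln, p_distance, n_replicates=200,
                                    seed=42)
        cluster_split = frozenset({"b1", "b2", "b3"})
        assert support[cluster_split] >= 95.0

    def test_same_seed_reproducible(self, rng):
        aln = _two_cluster_alignment(rng)
        s1 = bootstrap_support(aln, p_distance, n_replicates=50, seed=9)
        s2 = bootstrap_support(aln, p_distance, n_replicates=50, seed=9)
        assert s1 == s2

    def test_row_order_invariance(self, rng):
        aln = _two_cluster_alignment(rng)
        reordered = ProteinAlignment(
            rows={k: aln.rows[k] for k in reversed(list(aln.rows))})
        s1 = bootstrap_support(aln, p_distance, n_replicates=50, seed=9)
        s2 = bootstrap_support(reordered, p_distance, n_replicates=50,
                               seed=9)
        assert s1 == s2

    def test_short_alignment_rejected(self):
        aln = ProteinAlignment(rows={"a": "M", "b": "M", "c": "M"})
        with pytest.raises(ValueError):
            bootstrap_support(aln, p_distance, n_replicates=10, seed=1)


class TestRootTree:
    def test_outgroup_attached_at_root(self):
        tree = read_newick("(((A:1,B:1):1,C:2):1,D:3);")
        tree.is_rooted = False
        rooted = root_tree(tree, "D")
        root_kids = rooted.seed_node.child_nodes()
        tip_sets = [{l.taxon.label for l in c.leaf_iter()}
                    for c in root_kids]
        assert {"D"} in tip_sets

    def test_rerooting_idempotent(self):
        tree = read_newick("(((A:1,B:1):1,C:2):1,D:3);")
        r1 = root_tree(tree, "D")
        r2 = root_tree(r1, "D")
        assert r1.as_string(schema="newick") == r2.as_string(
            schema="newick")

    def test_unknown_outgroup_rejected(self):
        tree = read_newick("((A,B),C);")
        with pytest.raises(KeyError):
            root_tree(tree, "Z")

    def test_marsupial_outgroup_splits_placentals(self, rng):
        # cluster alignment: 'out' far from two placental-like clusters
        aln = _two_cluster_alignment(rng)
        far = "".join(AA[i] for i in rng.integers(0, 20, aln.n_columns))
        rows = dict(aln.rows)
        rows["out"] = far
        tree = nj(DistanceMatrix.from_alignment(ProteinAlignment(rows=rows),
                                                p_distance))
        rooted = root_tree(tree, "out")
        kids = rooted.seed_node.child_nodes()
        tip_sets = [frozenset(l.taxon.label for l in c.leaf_iter())
                    for c in kids]
        assert frozenset({"out"}) in tip_sets
        others = [s for s in tip_sets if s != frozenset({"out"})]
        assert frozenset().union(*others) == frozenset(
            {"a1", "a2", "a3", "b1", "b2", "b3"})
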