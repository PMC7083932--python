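"""Distances, neighbor joining, bootstrap, whole-vs-bait reporting."""

import math

import numpy as np
import pytest

from prpscan import (
    DistanceMatrix,
    bipartitions,
    bootstrap_support,
    nj_tree,
    pairwise_distance,
    region_vs_whole_report,
)
from prpscan.phylo import InfiniteDistanceError, TreeNode

AA = "ACDEFGHIKLMNPQRSTVWY"


def random_additive_tree(rng, n_taxa):
    """A random unrooted binary tree with positive lengths, plus its
    path-length (additive) distance matrix."""
    labels = [f"t{i}" for i in range(n_taxa)]
    nodes = [TreeNode(name=lab) for lab in labels]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[j], nodes[i]
        a.length = float(rng.uniform(0.05, 1.0))
        b.length = float(rng.uniform(0.05, 1.0))
        parent = TreeNode(children=[b, a])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    for n in nodes:
        n.length = float(rng.uniform(0.05, 1.0))
    root = TreeNode(children=nodes)

    # path lengths between leaves
    def paths(node, acc, out):
        if node.is_leaf():
            out[node.name] = acc
        for c in node.children:
            paths(c, acc + c.length, out)

    dist = {}
    def collect(node):
        for c in node.children:
            collect(c)
        # distances through this node between leaves of different children
        sides = []
        for c in node.children:
            d = {}
            paths(c, c.length, d)
            sides.append(d)
        for x in range(len(sides)):
            for y in range(x + 1, len(sides)):
                for la, da in sides[x].items():
                    for lb, db in sides[y].items():
                        dist[frozenset((la, lb))] = da + db

    collect(root)
    m = np.zeros((n_taxa, n_taxa))
    for i, la in enumerate(labels):
        for j, lb in enumerate(labels):
            if i != j:
                m[i, j] = dist[frozenset((la, lb))]
    return root, DistanceMatrix(labels, m, "p-distance")


def leaf_distances(tree):
    out = {}
    def paths(node, acc, bag):
        if node.is_leaf():
            bag[node.name] = acc
        for c in node.children:
            paths(c, acc + c.length, bag)
    def collect(node):
        for c in node.children:
            collect(c)
        sides = []
        for c in node.children:
            d = {}
            paths(c, c.length, d)
            sides.append(d)
        for x in range(len(sides)):
            for y in range(x + 1, len(sides)):
                for la, da in sides[x].items():
                    for lb, db in sides[y].items():
                        out[frozenset((la, lb))] = da + db
    collect(tree)
    return out


class TestPairwiseDistance:
    def test_identical_pair_zero(self):
        for model in ("p-distance", "poisson"):
            dm = pairwise_distance(["a", "b"], ["ACDEF", "ACDEF"], model)
            assert dm.values[0, 1] == 0.0

    def test_completely_different_pair(self):
        dm = pairwise_distance(["a", "b"], ["AAAA", "CCCC"], "p-distance")
        assert dm.values[0, 1] == 1.0
        with pytest.raises(InfiniteDistanceError, match="'a' and 'b'"):
            pairwise_distance(["a", "b"], ["AAAA", "CCCC"], "poisson")

    def test_closed_form_poisson(self):
        a = "A" * 96 + "CCCC"
        b = "A" * 96 + "GGGG"
        assert pairwise_distance(["x", "y"], [a, b], "p-distance").values[0, 1] == pytest.approx(0.04)
        assert pairwise_distance(["x", "y"], [a, b], "poisson").values[0, 1] == pytest.approx(
            -math.log(0.96)
        )

    def test_pairwise_gap_deletion(self):
        dm = pairwise_distance(["a", "b"], ["AC-EF", "ACD-F"], "p-distance")
        # columns 3 and 4 dropped pairwise: 3 compared, 0 mismatches
        assert dm.values[0, 1] == 0.0

    def test_poisson_dominates_p_distance(self, rng):
        for _ in range(20):
            length = int(rng.integers(10, 60))
            a = "".join(rng.choice(list(AA), size=length))
            b = "".join(rng.choice(list(AA), size=length))
            p = pairwise_distance(["a", "b"], [a, b], "p-distance").values[0, 1]
            if p >= 1.0:
                continue
            d = pairwise_distance(["a", "b"], [a, b], "poisson").values[0, 1]
            assert d >= p
            assert (d == p) == (p == 0.0)


class TestNJ:
    def test_three_taxa_closed_form(self):
        m = np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], float)
        tree = nj_tree(DistanceMatrix(["a", "b", "c"], m, "p-distance"))
        d = leaf_distances(tree)
        assert d[frozenset(("a", "b"))] == pytest.approx(5)
        assert d[frozenset(("a", "c"))] == pytest.approx(9)
        assert d[frozenset(("b", "c"))] == pytest.approx(10)

    def test_duplicated_taxon_zero_cherry(self):
        m = np.array(
            [[0, 0, 4, 5], [0, 0, 4, 5], [4, 4, 0, 3], [5, 5, 3, 0]], float
        )
        tree = nj_tree(DistanceMatrix(["a", "a2", "c", "d"], m, "p-distance"))
        d = leaf_distances(tree)
        assert d[frozenset(("a", "a2"))] == pytest.approx(0.0)

    def test_additive_four_taxon_exact_recovery(self):
        # tree ((A:1,B:2):3,(C:4,D:5)) -> additive matrix by hand
        m = np.array(
            [
                [0, 3, 8, 9],
                [3, 0, 9, 10],
                [8, 9, 0, 9],
                [9, 10, 9, 0],
            ],
            float,
        )
        tree = nj_tree(DistanceMatrix(["A", "B", "C", "D"], m, "p-distance"))
        d = leaf_distances(tree)
        for i, la in enumerate("ABCD"):
            for j, lb in enumerate("ABCD"):
                if i < j:
                    assert d[frozenset((la, lb))] == pytest.approx(m[i, j])
        assert bipartitions(tree) == {frozenset({"A", "B"})}

    def test_recovers_random_additive_trees(self, rng):
        for _ in range(10):
            n = int(rng.integers(4, 11))
            true_tree, dm = random_additive_tree(rng, n)
            rec = nj_tree(dm)
            assert bipartitions(rec) == bipartitions(true_tree)
            true_d = leaf_distances(true_tree)
            rec_d = leaf_distances(rec)
            for k, v in true_d.items():
                assert rec_d[k] == pytest.approx(v, abs=1e-9)

    def test_matches_skbio_topology(self, rng):
        skbio = pytest.importorskip("skbio")
        n = 7
        labels = [f"t{i}" for i in range(n)]
        m = rng.uniform(0.2, 1.0, size=(n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0.0)
        ours = nj_tree(DistanceMatrix(labels, m, "p-distance"))
        ref = skbio.tree.nj(skbio.DistanceMatrix(m, ids=labels))
        ref_bips = set()
        all_leaves = frozenset(labels)
        for node in ref.non_tips():
            side = frozenset(t.name for t in node.tips())
            other = all_leaves - side
            if len(side) >= 2 and len(other) >= 2:
                ref_bips.add(min(side, other, key=lambda s: (len(s), sorted(s))))
        assert bipartitions(ours) == ref_bips

    def test_too_few_taxa(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(["a", "b"], np.array([[0, 1], [1, 0]], float), "p-distance"))

    def test_newick_round_trip(self, rng):
        skbio = pytest.importorskip("skbio")
        import io

        _, dm = random_additive_tree(rng, 6)
        tree = nj_tree(dm)
        parsed = skbio.TreeNode.read(io.StringIO(tree.to_newick()))
        assert {t.name for t in parsed.tips()} == set(dm.labels)
        ours = leaf_distances(tree)
        for a in dm.labels:
            for b in dm.labels:
                if a < b:
                    assert parsed.find(a).distance(parsed.find(b)) == pytest.approx(
                        ours[frozenset((a, b))], abs=1e-6
                    )


def two_clade_alignment(rng, n_per_clade=4, length=120, divergence=0.3):
    base = "".join(rng.choice(list(AA), size=length))
    other = list(base)
    for p in rng.choice(length, size=int(divergence * length), replace=False):
        other[p] = AA[(AA.index(other[p]) + 1) % 20]
    labels, seqs = [], []
    for i in range(n_per_clade):
        labels += [f"a{i}", f"b{i}"]
        seqs += [base, "".join(other)]
    return labels, seqs


class TestBootstrap:
    def test_clean_separation_full_support(self, rng):
        labels, seqs = two_clade_alignment(rng)
        tree = bootstrap_support(labels, seqs, n_reps=50, seed=7, model="p-distance")
        separating = frozenset(l for l in labels if l.startswith("a"))
        for node in tree.walk():
            if node.is_leaf() or node is tree or node.support is None:
                continue
            side = frozenset(node.leaf_names())
            if side in (separating, frozenset(labels) - separating):
                assert node.support == 100.0

    def test_single_replicate_supports_are_binary(self, rng):
        labels, seqs = two_clade_alignment(rng, n_per_clade=3)
        tree = bootstrap_support(labels, seqs, n_reps=1, seed=3, model="p-distance")
        supports = [n.support for n in tree.walk() if n.support is not None]
        assert supports and set(supports) <= {0.0, 100.0}

    def test_reproducible_and_order_invariant(self, rng):
        labels, seqs = two_clade_alignment(rng, n_per_clade=3, divergence=0.15)
        t1 = bootstrap_support(labels, seqs, n_reps=40, seed=11)
        t2 = bootstrap_support(labels, seqs, n_reps=40, seed=11)
        assert t1.to_newick() == t2.to_newick()
        order = list(reversed(range(len(labels))))
        t3 = bootstrap_support([labels[i] for i in order], [seqs[i] for i in order],
                               n_reps=40, seed=11)
        def support_map(t):
            every = frozenset(t.leaf_names())
            return {
                min(frozenset(n.leaf_names()), every - frozenset(n.leaf_names()),
                    key=lambda s: (len(s), sorted(s))): n.support
                for n in t.walk()
                if n.support is not None
            }
        assert support_map(t1) == support_map(t3)

    def test_supports_stable_across_seeds(self, rng):
        """On a structured 8-taxon alignment, 500-replicate supports agree
        within 5 points between independent resampling seeds."""
        # balanced 8-taxon tree: every internal edge carries 25 shared
        # derived substitutions, so all bipartitions are well supported
        base = "".join(rng.choice(list(AA), size=200))

        def mutate(seq, positions, step):
            s = list(seq)
            for p in positions:
                s[p] = AA[(AA.index(s[p]) + step) % 20]
            return "".join(s)

        taxa = {}
        for ci, clade in enumerate(("a", "b")):
            clade_seq = mutate(base, range(ci * 50, ci * 50 + 25), 3)
            for pi in range(2):  # two cherries per clade
                cherry_seq = mutate(clade_seq, range(100 + (ci * 2 + pi) * 25,
                                                     125 + (ci * 2 + pi) * 25), 5)
                for i in range(2):
                    tip = mutate(cherry_seq, rng.choice(200, size=4, replace=False), 1 + i)
                    taxa[f"{clade}{pi}{i}"] = tip
        labels, seqs = list(taxa), list(taxa.values())

        def support_map(tree):
            every = frozenset(tree.leaf_names())
            return {
                min(frozenset(n.leaf_names()), every - frozenset(n.leaf_names()),
                    key=lambda s: (len(s), sorted(s))): n.support
                for n in tree.walk() if n.support is not None
            }

        m1 = support_map(bootstrap_support(labels, seqs, n_reps=500, seed=101))
        m2 = support_map(bootstrap_support(labels, seqs, n_reps=500, seed=202))
        for bp, s in m1.items():
            assert abs(s - m2[bp]) <= 5.0

    def test_short_alignment_errors(self):
        with pytest.raises(ValueError):
            bootstrap_support(["a", "b", "c"], ["A", "A", "C"], n_reps=5, seed=0)


class TestRegionVsWhole:
    def test_identical_sequences_guarded(self):
        rep = region_vs_whole_report(["a", "b"], ["ACDEFG", "ACDEFG"], (2, 4))
        assert rep.loc[0, "whole"] == 0.0
        assert np.isnan(rep.loc[0, "ratio_bait_whole"])

    def test_fast_bait_gives_ratio_above_one(self, rng):
        from prpscan import HomologPairConfig, gen_homolog_pair

        hits = 0
        for seed in range(10):
            pair = gen_homolog_pair(
                HomologPairConfig(length=400, bait_start=181, bait_end=220,
                                  r_out=0.02, r_bait=0.10, seed=seed)
            )
            rep = region_vs_whole_report(
                ["anc", "desc"],
                [pair["protein_ancestor"], pair["protein_descendant"]],
                (181, 220),
                model="p-distance",
            )
            if rep.loc[0, "ratio_bait_whole"] > 1:
                hits += 1
        assert hits >= 9
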