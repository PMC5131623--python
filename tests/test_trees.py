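"""Newick I/O, neighbor joining, bootstrap and Robinson-Foulds."""

import itertools

import numpy as np
import pytest

from plastsurvey.errors import TreeError
from plastsurvey.model import MarkerAlignment
from plastsurvey.simulate import evolve_marker, simulate_tree
from plastsurvey.trees import (
    PhyloTree,
    bootstrap_support,
    mean_support,
    nj_tree,
    parse_newick,
    pruned,
    rf_distance,
)


def path_distances(tree: PhyloTree) -> tuple[list[str], np.ndarray]:
    """Leaf-to-leaf path-length matrix (independent of NJ internals)."""
    import networkx as nx

    G = nx.Graph()
    counter = itertools.count()

    def walk(node):
        my_id = next(counter)
        G.add_node(my_id, name=node.name if node.is_leaf else None)
        for child in node.children:
            cid = walk(child)
            G.add_edge(my_id, cid, weight=child.length or 0.0)
        return my_id

    walk(tree.root)
    leaves = {d["name"]: n for n, d in G.nodes(data=True) if d.get("name")}
    labels = sorted(leaves)
    dist = dict(nx.all_pairs_dijkstra_path_length(G))
    n = len(labels)
    d = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            d[i, j] = dist[leaves[a]][leaves[b]]
    return labels, d


class TestNewick:
    def test_round_trip_topology_lengths_supports(self):
        text = "((a:0.1,b:0.2)95:0.05,(c:0.3,d:0.1)80:0.07,e:0.4);"
        tree = parse_newick(text)
        back = parse_newick(tree.newick())
        assert back.taxa == {"a", "b", "c", "d", "e"}
        assert back.bipartitions() == tree.bipartitions()
        supports = sorted(n.support for n, _ in back.internal_edges())
        assert supports == [80.0, 95.0]

    def test_trifurcating_root_accepted(self):
        tree = parse_newick("(a,b,(c,d));")
        assert len(tree.root.children) == 3

    @pytest.mark.parametrize("seed", range(3))
    def test_round_trip_on_random_trees(self, seed):
        tree = simulate_tree(n_taxa=10, seed=seed)
        back = parse_newick(tree.newick())
        assert back.bipartitions() == tree.bipartitions()
        d0, d1 = path_distances(tree)[1], path_distances(back)[1]
        np.testing.assert_allclose(d0, d1, rtol=1e-9)

    @pytest.mark.parametrize("bad", ["(a,b", "(a,b);x", "a;", "(a,:0.1);"])
    def test_malformed_newick_rejected(self, bad):
        with pytest.raises(TreeError):
            parse_newick(bad)


class TestNeighborJoining:
    def test_recovers_generating_topology_from_additive_distances(self):
        tree = simulate_tree(n_taxa=5, seed=2)
        labels, d = path_distances(tree)
        nj = nj_tree(labels, d)
        assert rf_distance(nj, tree) == 0

    def test_four_point_condition_split(self):
        # d favors AB|CD: within-pair distances small, across large
        labels = ["a", "b", "c", "d"]
        d = np.array(
            [[0, 2, 8, 8], [2, 0, 8, 8], [8, 8, 0, 2], [8, 8, 2, 0]], dtype=float
        )
        nj = nj_tree(labels, d)
        assert frozenset({"c", "d"}) in nj.bipartitions() or frozenset({"a", "b"}) in nj.bipartitions()

    def test_three_taxa_rejected(self):
        with pytest.raises(TreeError):
            nj_tree(["a", "b", "c"], np.zeros((3, 3)))

    def test_asymmetric_matrix_rejected(self):
        d = np.zeros((4, 4))
        d[0, 1] = 1.0
        with pytest.raises(TreeError):
            nj_tree(list("abcd"), d)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_scikit_bio_on_random_distances(self, seed):
        """Independent cross-check against skbio's NJ implementation."""
        import skbio

        rng = np.random.default_rng(seed)
        n = 7
        coords = rng.random((n, 3))
        d = np.sqrt(((coords[:, None] - coords[None]) ** 2).sum(-1))  # metric
        labels = [f"t{i}" for i in range(n)]
        ours = nj_tree(labels, d)
        theirs = skbio.tree.nj(skbio.DistanceMatrix(d, ids=labels))
        their_bips = set()
        for node in theirs.non_tips(include_self=False):
            clade = frozenset(t.name for t in node.tips())
            if 1 < len(clade) < n - 1:
                anchor = min(labels)
                their_bips.add(frozenset(labels) - clade if anchor in clade else clade)
        assert ours.bipartitions() == their_bips


class TestBootstrap:
    @pytest.fixture(scope="class")
    def strong_signal(self):
        tree = parse_newick(
            "(((a:.01,b:.01):.01,(c:.01,d:.01):.01):.2,((e:.01,f:.01):.01,(g:.01,h:.01):.01):.2);"
        )
        return evolve_marker(tree, 5000, seed=4, name="strong")

    def test_high_support_under_strong_signal(self, strong_signal):
        tree = bootstrap_support(strong_signal, replicates=50, seed=1)
        assert all(n.support >= 95 for n, _ in tree.internal_edges())

    def test_noise_supports_below_signal_supports(self, strong_signal):
        # i.i.d. rows: every taxon independently mutates a shared column
        # base with probability 0.1, so there is no tree signal at all
        rng = np.random.default_rng(9)
        base = rng.integers(0, 4, 500)
        rows = []
        for _ in range(8):
            row = base.copy()
            hit = rng.random(500) < 0.1
            row[hit] = rng.integers(0, 4, int(hit.sum()))
            rows.append("".join("ACGT"[i] for i in row))
        noise = MarkerAlignment("noise", list("abcdefgh"), rows)
        s_sig = mean_support(bootstrap_support(strong_signal, replicates=30, seed=2))
        s_noise = mean_support(bootstrap_support(noise, replicates=30, seed=2))
        assert s_noise < s_sig - 20

    def test_same_seed_reproduces_supports(self, strong_signal):
        t1 = bootstrap_support(strong_signal, replicates=20, seed=5)
        t2 = bootstrap_support(strong_signal, replicates=20, seed=5)
        assert [n.support for n, _ in t1.internal_edges()] == [
            n.support for n, _ in t2.internal_edges()
        ]

    def test_supports_within_bounds(self, strong_signal):
        tree = bootstrap_support(strong_signal, replicates=20, seed=6)
        assert all(0.0 <= n.support <= 100.0 for n, _ in tree.internal_edges())


class TestMeanSupport:
    def test_known_mean(self):
        tree = parse_newick("((a,b)50,(c,d)100,e);")
        assert mean_support(tree) == 75.0

    def test_no_supports_is_error(self):
        with pytest.raises(TreeError):
            mean_support(parse_newick("(a,b,(c,d));"))


class TestRobinsonFoulds:
    def test_identical_trees(self):
        t = simulate_tree(n_taxa=16, seed=3)
        assert rf_distance(t, parse_newick(t.newick())) == 0

    def test_conflicting_quartets_distance_two(self):
        t1 = parse_newick("((a,b),(c,d));")
        t2 = parse_newick("((a,c),(b,d));")
        assert rf_distance(t1, t2) == 2

    def test_taxon_mismatch_rejected(self):
        with pytest.raises(TreeError):
            rf_distance(parse_newick("((a,b),(c,d));"), parse_newick("((a,b),(c,e));"))

    def test_upper_bound_for_binary_trees(self):
        t1, t2 = simulate_tree(10, seed=4), simulate_tree(10, seed=5)
        t2 = _relabel_like(t2, t1)
        assert rf_distance(t1, t2) <= 2 * (10 - 3)

    @pytest.mark.parametrize("seeds", [(0, 1, 2), (3, 4, 5)])
    def test_metric_axioms_on_random_triples(self, seeds):
        trees = [simulate_tree(8, seed=s) for s in seeds]
        trees = [trees[0]] + [_relabel_like(t, trees[0]) for t in trees[1:]]
        for a, b in itertools.combinations(trees, 2):
            assert rf_distance(a, b) == rf_distance(b, a) >= 0
        a, b, c = trees
        assert rf_distance(a, c) <= rf_distance(a, b) + rf_distance(b, c)
        for t in trees:
            assert rf_distance(t, t) == 0

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_dendropy(self, seed):
        """Independent cross-check against dendropy's RF computation."""
        import dendropy

        t1 = simulate_tree(9, seed=seed)
        t2 = _relabel_like(simulate_tree(9, seed=seed + 50), t1)
        ours = rf_distance(t1, t2)
        ns = dendropy.TaxonNamespace()
        d1 = dendropy.Tree.get(data=t1.newick(), schema="newick", taxon_namespace=ns)
        d2 = dendropy.Tree.get(data=t2.newick(), schema="newick", taxon_namespace=ns)
        d1.encode_bipartitions(); d2.encode_bipartitions()
        assert ours == dendropy.calculate.treecompare.symmetric_difference(d1, d2)


class TestPruning:
    def test_pruned_bipartitions_are_restrictions(self):
        tree = simulate_tree(10, seed=6)
        keep = set(sorted(tree.taxa)[:6])
        sub = pruned(tree, keep)
        assert sub.taxa == frozenset(keep)
        full_restricted = set()
        for bp in tree.bipartitions():
            r = frozenset(bp & keep)
            if 1 < len(r) < len(keep) - 1:
                anchor = min(keep)
                full_restricted.add(frozenset(keep) - r if anchor in r else r)
        assert sub.bipartitions() <= full_restricted


def _relabel_like(tree: PhyloTree, template: PhyloTree) -> PhyloTree:
    """Map one simulated tree's labels onto another's taxon set."""
    mapping = dict(zip(sorted(tree.taxa), sorted(template.taxa)))
    for leaf in tree.leaves():
        leaf.name = mapping[leaf.name]
    return PhyloTree(tree.root)
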