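import itertools

import numpy as np
import pytest

from mipscan.io_core import ProteinSequence
from mipscan.phylo import (
    DistanceMatrix,
    PhyloError,
    PseudoAlignment,
    Tree,
    assign_clades,
    bootstrap_support,
    majority_rule_collapse,
    neighbor_joining,
    p_distance_matrix,
)

# ---------------------------------------------------------------------------
# helpers: random additive trees + exhaustive topology enumeration oracle


def random_unrooted_tree(n, rng):
    """Edge-list representation; nodes 0..n-1 are leaves."""
    # start from the 3-leaf star, insert remaining leaves on random edges
    next_node = n
    edges = {}

    def add_edge(u, v):
        edges[(u, v)] = rng.uniform(0.1, 1.0)

    center = next_node
    next_node += 1
    for leaf in range(3):
        add_edge(center, leaf)
    for leaf in range(3, n):
        u, v = list(edges)[rng.integers(len(edges))]
        length = edges.pop((u, v))
        mid = next_node
        next_node += 1
        edges[(u, mid)] = length * 0.5
        edges[(mid, v)] = length * 0.5
        add_edge(mid, leaf)
    return edges


def path_distances(edges, n):
    nodes = set()
    for u, v in edges:
        nodes.update((u, v))
    adj = {x: [] for x in nodes}
    for (u, v), w in edges.items():
        adj[u].append((v, w))
        adj[v].append((u, w))
    d = np.zeros((n, n))
    for src in range(n):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            x = stack.pop()
            for y, w in adj[x]:
                if y not in dist:
                    dist[y] = dist[x] + w
                    stack.append(y)
        for dst in range(n):
            d[src, dst] = dist[dst]
    return d


def tree_bipartitions(edges, n):
    nodes = set()
    for u, v in edges:
        nodes.update((u, v))
    adj = {x: set() for x in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    bips = set()
    for u, v in edges:
        # leaves on the v side of edge (u, v)
        seen = {u, v}
        stack = [v]
        side = set()
        while stack:
            x = stack.pop()
            if x < n:
                side.add(x)
            for y in adj[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        if 1 < len(side) < n - 1:
            bips.add(frozenset(side))
    return bips


def enumerate_topologies(n):
    """All unrooted binary topologies on leaves 0..n-1 as edge sets."""
    trees = [[(n, 0), (n, 1), (n, 2)]]
    next_internal = n + 1
    for leaf in range(3, n):
        new_trees = []
        for edges in trees:
            for i, (u, v) in enumerate(edges):
                mid = next_internal
                rest = edges[:i] + edges[i + 1 :]
                new_trees.append(rest + [(u, mid), (mid, v), (mid, leaf)])
        trees = new_trees
        next_internal += 1
    return trees


def lstsq_residual(edge_list, n, d):
    """Least-squares branch-length fit of distance matrix d on a topology."""
    nodes = set()
    for u, v in edge_list:
        nodes.update((u, v))
    adj = {x: [] for x in nodes}
    for idx, (u, v) in enumerate(edge_list):
        adj[u].append((v, idx))
        adj[v].append((u, idx))
    pairs = list(itertools.combinations(range(n), 2))
    A = np.zeros((len(pairs), len(edge_list)))
    for row, (a, b) in enumerate(pairs):
        # path from a to b
        parent = {a: (None, None)}
        stack = [a]
        while stack:
            x = stack.pop()
            for y, idx in adj[x]:
                if y not in parent:
                    parent[y] = (x, idx)
                    stack.append(y)
        x = b
        while parent[x][0] is not None:
            A[row, parent[x][1]] = 1.0
            x = parent[x][0]
    y = np.array([d[a, b] for a, b in pairs])
    sol, *_ = np.linalg.lstsq(A, y, rcond=None)
    return float(np.linalg.norm(A @ sol - y))


# ---------------------------------------------------------------------------
# p-distance


class TestPDistance:
    def test_examples(self):
        seqs = [
            ProteinSequence(id="a", residues="AAAAAAAA"),
            ProteinSequence(id="b", residues="AAAAAAAA"),
            ProteinSequence(id="c", residues="WWWWWWWW"),
            ProteinSequence(id="d", residues="AAAAWWWW"),
        ]
        dm = p_distance_matrix(seqs)
        idx = {lab: i for i, lab in enumerate(dm.labels)}
        assert dm.d[idx["a"], idx["b"]] == 0.0
        assert dm.d[idx["a"], idx["c"]] == 1.0
        assert dm.d[idx["a"], idx["d"]] == pytest.approx(0.5)

    def test_requires_three(self):
        seqs = [ProteinSequence(id=i, residues="ACDE") for i in "ab"]
        with pytest.raises(PhyloError):
            p_distance_matrix(seqs)

    def test_matrix_validation(self):
        with pytest.raises(PhyloError):
            DistanceMatrix(labels=["a", "b"], d=np.array([[0.0, 1.0], [0.5, 0.0]]))
        with pytest.raises(PhyloError):
            DistanceMatrix(labels=["a", "b"], d=np.array([[0.0, -1.0], [-1.0, 0.0]]))


# ---------------------------------------------------------------------------
# neighbor joining


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        d = np.array(
            [
                [0.0, 0.4, 0.6],
                [0.4, 0.0, 0.8],
                [0.6, 0.8, 0.0],
            ]
        )
        tree = neighbor_joining(DistanceMatrix(labels=["a", "b", "c"], d=d))
        lengths = {c.name: c.length for c in tree.root.children}
        assert lengths["a"] == pytest.approx(0.1)
        assert lengths["b"] == pytest.approx(0.3)
        assert lengths["c"] == pytest.approx(0.5)

    def test_four_taxon_additive_topology(self):
        # tree ((a:1,b:2):1,(c:3,d:4)) -> additive distances
        d = np.array(
            [
                [0.0, 3.0, 5.0, 6.0],
                [3.0, 0.0, 6.0, 7.0],
                [5.0, 6.0, 0.0, 7.0],
                [6.0, 7.0, 7.0, 0.0],
            ]
        )
        tree = neighbor_joining(DistanceMatrix(labels=list("abcd"), d=d))
        bips = {frozenset(b) for b in tree.bipartitions()}
        assert frozenset({"a", "b"}) in bips or frozenset({"c", "d"}) in bips
        labels, paths = tree.path_length_matrix()
        order = [labels.index(x) for x in "abcd"]
        assert np.allclose(paths[np.ix_(order, order)], d, atol=1e-9)

    def test_closest_pair_joined_first(self):
        d = np.array(
            [
                [0.0, 0.1, 0.9, 0.9, 0.9],
                [0.1, 0.0, 0.9, 0.9, 0.9],
                [0.9, 0.9, 0.0, 0.5, 0.6],
                [0.9, 0.9, 0.5, 0.0, 0.6],
                [0.9, 0.9, 0.6, 0.6, 0.0],
            ]
        )
        tree = neighbor_joining(DistanceMatrix(labels=list("abcde"), d=d))
        assert frozenset({"a", "b"}) in {frozenset(b) for b in tree.bipartitions()}

    def test_additive_recovery_small(self):
        rng = np.random.default_rng(13)
        for n in (4, 5, 6):
            for _ in range(5):
                edges = random_unrooted_tree(n, rng)
                d = path_distances(edges, n)
                labels = [str(i) for i in range(n)]
                tree = neighbor_joining(DistanceMatrix(labels=labels, d=d))
                full = frozenset(range(n))
                got = {frozenset(int(x) for x in b) for b in tree.bipartitions()}
                got = {b if 0 in b else full - b for b in got}
                want = {b if 0 in b else full - b for b in tree_bipartitions(edges, n)}
                assert got == want
                labs, paths = tree.path_length_matrix()
                order = [labs.index(str(i)) for i in range(n)]
                assert np.allclose(paths[np.ix_(order, order)], d, atol=1e-8)

    def test_rejects_small_or_invalid(self):
        with pytest.raises(PhyloError):
            neighbor_joining(DistanceMatrix(labels=["a"], d=np.zeros((1, 1))))


# ---------------------------------------------------------------------------
# bootstrap


def _alignment(rows):
    return PseudoAlignment.from_strings([f"t{i}" for i in range(len(rows))], rows)


class TestBootstrap:
    def test_unanimous_split_is_100(self):
        aln = _alignment(["AAAA", "AAAA", "CCCC", "CCCC"])
        tree = bootstrap_support(aln, n_reps=50, seed=1)
        bips = tree.bipartitions()
        assert len(bips) == 1
        assert list(bips.values())[0] == 100.0

    def test_seed_determinism(self):
        rows = ["AACCA", "AACCC", "CCAAA", "CCAAC"]
        t1 = bootstrap_support(_alignment(rows), n_reps=100, seed=42)
        t2 = bootstrap_support(_alignment(rows), n_reps=100, seed=42)
        assert t1.to_newick() == t2.to_newick()

    def test_leaf_permutation_invariance(self):
        rng = np.random.default_rng(3)
        rows = ["".join(rng.choice(list("ACDE"), 30)) for _ in range(6)]
        labels = [f"t{i}" for i in range(6)]
        a1 = PseudoAlignment.from_strings(labels, rows)
        perm = [3, 1, 5, 0, 4, 2]
        a2 = PseudoAlignment.from_strings([labels[i] for i in perm], [rows[i] for i in perm])
        b1 = bootstrap_support(a1, n_reps=200, seed=7).bipartitions()
        b2 = bootstrap_support(a2, n_reps=200, seed=7).bipartitions()
        shared = set(b1) & set(b2)
        assert shared
        for b in shared:
            assert b1[b] == pytest.approx(b2[b], abs=12.0)

    def test_rejects_bad_args(self):
        aln = _alignment(["AAAA", "AAAA", "CCCC", "CCCC"])
        with pytest.raises(PhyloError):
            bootstrap_support(aln, n_reps=0)
        with pytest.raises(PhyloError):
            bootstrap_support(_alignment(["AA", "AC", "CC"]), n_reps=10)


# ---------------------------------------------------------------------------
# collapse and clade assignment


class TestMajorityRuleCollapse:
    def test_all_supported_unchanged(self):
        tree = Tree.from_newick("((A:1,B:1)100:1,(C:1,D:1)100:1,E:1);")
        out = majority_rule_collapse(tree, 50.0)
        assert set(out.bipartitions()) == set(tree.bipartitions())

    def test_weak_edge_contracted(self):
        tree = Tree.from_newick("((A:1,B:1)40:1,(C:1,D:1)90:1,E:1);")
        out = majority_rule_collapse(tree, 50.0)
        assert frozenset({"A", "B"}) not in set(out.bipartitions())
        assert frozenset({"C", "D"}) in set(out.bipartitions())
        assert sorted(out.leaf_names()) == list("ABCDE")

    def test_star_tree(self):
        tree = Tree.from_newick("((A:1,B:1)10:1,(C:1,D:1)20:1,E:1);")
        out = majority_rule_collapse(tree, 50.0)
        assert out.bipartitions() == {}

    def test_collapsed_subset_of_original(self):
        tree = Tree.from_newick("(((A:1,B:1)70:1,C:1)30:1,(D:1,E:1)90:1,F:1);")
        out = majority_rule_collapse(tree, 50.0)
        assert set(out.bipartitions()) <= set(tree.bipartitions())


class TestAssignClades:
    def test_sister_references(self):
        tree = Tree.from_newick("((q:1,(r1:1,r2:1)80:1)90:1,(x1:1,x2:1)95:1,y:1);")
        calls = assign_clades(tree, {"r1": "delta", "r2": "delta", "x1": "alpha", "x2": "alpha"})
        assert calls["q"] == "delta"

    def test_outsider_query_unclassified(self):
        # query on its own branch outside the labeled clades: its smallest
        # containing clades disagree, so no label is assigned
        tree = Tree.from_newick("((r1:1,r2:1)90:1,(x1:1,x2:1)90:1,(q:5,u:1)90:1);")
        calls = assign_clades(tree, {"r1": "delta", "r2": "delta", "x1": "alpha", "x2": "alpha"})
        assert calls["q"] == "unclassified"
        assert calls["u"] == "unclassified"

    def test_mixed_clade_unclassified(self):
        tree = Tree.from_newick("((q:1,(r1:1,r2:1)80:1)90:1,(x1:1,x2:1)95:1,y:1);")
        calls = assign_clades(tree, {"r1": "alpha", "r2": "beta"})
        assert calls["q"] == "unclassified"

    def test_low_support_ignored(self):
        tree = Tree.from_newick("((q:1,(r1:1,r2:1)80:1)30:1,(x1:1,x2:1)95:1,y:1);")
        calls = assign_clades(tree, {"r1": "delta", "r2": "delta", "x1": "alpha", "x2": "alpha"})
        # the clade grouping q with the delta refs is unsupported, so q
        # cannot be placed
        assert calls["q"] == "unclassified"

    def test_no_labeled_leaves(self):
        tree = Tree.from_newick("((A:1,B:1)90:1,(C:1,D:1)90:1,E:1);")
        with pytest.raises(PhyloError):
            assign_clades(tree, {"nope": "alpha"})


def test_newick_round_trip():
    text = "((A:0.1,B:0.2)88:0.05,(C:0.3,D:0.4)67:0.06,E:0.5);"
    tree = Tree.from_newick(text)
    back = Tree.from_newick(tree.to_newick())
    assert back.bipartitions() == tree.bipartitions()
    assert sorted(back.leaf_names()) == list("ABCDE")
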