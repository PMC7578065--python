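"""Neighbor joining, bootstrap support, bipartition queries.

The NJ oracle is twofold: exact recovery of the generating tree on random
additive matrices, and (for small n) exhaustive topology search with
least-squares branch fitting.
"""

import itertools

import dendropy
import numpy as np
import pytest
from dendropy.calculate import treecompare

from minibarkit import (
    DistanceMatrix,
    SimConfig,
    bootstrap_support,
    evolve_alignment,
    neighbor_joining,
    nontrivial_bipartitions,
    read_newick,
    shared_clade_proportion,
    simulate_species_tree,
    species_monophyly,
    write_newick,
)

# ---------------------------------------------------------------------------
# additive-matrix machinery (test-side oracle, independent of the package)
# ---------------------------------------------------------------------------


def _subdivide(adj, u, v, mid, leaf, cut_frac, pend):
    """Insert ``leaf`` on edge (u, v) via new internal node ``mid``."""
    w = adj[u].pop(v)
    adj[v].pop(u)
    cut = cut_frac * w
    adj[mid] = {}
    adj[u][mid] = adj[mid].setdefault(u, cut)
    adj[mid][u] = cut
    adj[v][mid] = w - cut
    adj[mid][v] = w - cut
    adj[leaf] = {mid: pend}
    adj[mid][leaf] = pend


def _splits_from_adj(adj, ids):
    """Canonical nontrivial bipartitions of a leaf-labelled tree graph."""
    n = len(ids)
    ref = min(ids)
    splits = set()
    for u in adj:
        for v in adj[u]:
            if u < v and u >= n and v >= n:  # internal edge
                side, stack, seen = set(), [u], {v}
                while stack:
                    x = stack.pop()
                    if x in seen:
                        continue
                    seen.add(x)
                    if x < n:
                        side.add(ids[x])
                    stack.extend(adj[x])
                if 2 <= len(side) <= n - 2:
                    canon = (
                        frozenset(side)
                        if ref not in side
                        else frozenset(set(ids) - side)
                    )
                    splits.add(canon)
    return frozenset(splits)


def random_additive(rng, n):
    """Random unrooted binary tree -> (ids, path-distance matrix, splits)."""
    center = n
    adj = {center: {}}
    for leaf in range(3):
        w = rng.uniform(0.1, 1.0)
        adj[leaf] = {center: w}
        adj[center][leaf] = w
    nxt = n + 1
    for leaf in range(3, n):
        edges = [(u, v) for u in adj for v in adj[u] if u < v]
        u, v = edges[rng.integers(0, len(edges))]
        _subdivide(
            adj, u, v, nxt, leaf,
            float(rng.uniform(0.2, 0.8)), float(rng.uniform(0.1, 1.0)),
        )
        nxt += 1

    def paths_from(src):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            x = stack.pop()
            for y, w in adj[x].items():
                if y not in dist:
                    dist[y] = dist[x] + w
                    stack.append(y)
        return dist

    ids = [f"t{i:02d}" for i in range(n)]
    mat = np.zeros((n, n))
    for i in range(n):
        d = paths_from(i)
        for j in range(n):
            mat[i, j] = d[j]
    return ids, mat, _splits_from_adj(adj, ids)


def enumerate_topologies(ids):
    """All unrooted binary topologies as frozensets of nontrivial splits.

    Sequential leaf insertion on every existing edge enumerates each
    topology exactly once: 15 for n=5, 105 for n=6.
    """
    n = len(ids)
    center = n

    def copy(adj):
        return {u: dict(nb) for u, nb in adj.items()}

    def rec(adj, nxt, k):
        if k == n:
            yield _splits_from_adj(adj, ids)
            return
        edges = [(u, v) for u in adj for v in adj[u] if u < v]
        for u, v in edges:
            branch = copy(adj)
            _subdivide(branch, u, v, nxt, k, 0.5, 1.0)
            yield from rec(branch, nxt + 1, k + 1)

    adj = {center: {}}
    for leaf in range(3):
        adj[leaf] = {center: 1.0}
        adj[center][leaf] = 1.0
    yield from rec(adj, n + 1, 3)


def least_squares_rss(ids, mat, splits):
    """RSS of the best branch-length fit for a topology given as splits."""
    n = len(ids)
    index = {t: i for i, t in enumerate(ids)}
    # edge set: pendant edges + internal splits
    edges = [frozenset([t]) for t in ids] + [set(s) for s in splits]
    pairs = list(itertools.combinations(ids, 2))
    A = np.zeros((len(pairs), len(edges)))
    y = np.zeros(len(pairs))
    for r, (a, b) in enumerate(pairs):
        y[r] = mat[index[a], index[b]]
        for c, side in enumerate(edges):
            if (a in side) != (b in side):
                A[r, c] = 1.0
    sol, *_ = np.linalg.lstsq(A, y, rcond=None)
    return float(((A @ sol - y) ** 2).sum())


def _dm(ids, mat):
    return DistanceMatrix(ids, mat, "k2p")


# ---------------------------------------------------------------------------


class TestNeighborJoining:
    def test_four_taxon_additive_exact(self):
        # tree ((A:1,B:2):1,(C:3,D:4)) -> path distances
        ids = ["A", "B", "C", "D"]
        mat = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], dtype=float
        )
        tree = neighbor_joining(_dm(ids, mat))
        assert nontrivial_bipartitions(tree) == {frozenset({"C", "D"})}
        leaf_len = {
            leaf.taxon.label: leaf.edge.length for leaf in tree.leaf_node_iter()
        }
        assert leaf_len == pytest.approx({"A": 1, "B": 2, "C": 3, "D": 4})
        total = sum(
            e.length for e in tree.preorder_edge_iter() if e.length is not None
        )
        assert total == pytest.approx(11.0)

    def test_three_taxa_closed_form(self):
        ids = ["a", "b", "c"]
        mat = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        tree = neighbor_joining(_dm(ids, mat))
        leaf_len = {
            leaf.taxon.label: leaf.edge.length for leaf in tree.leaf_node_iter()
        }
        assert leaf_len == pytest.approx({"a": 1.0, "b": 2.0, "c": 3.0})

    def test_too_few_taxa(self):
        with pytest.raises(ValueError):
            neighbor_joining(_dm(["a", "b"], np.array([[0.0, 1.0], [1.0, 0.0]])))

    def test_equidistant_matrix_deterministic(self):
        ids = [f"x{i}" for i in range(5)]
        mat = np.ones((5, 5)) - np.eye(5)
        t1 = neighbor_joining(_dm(ids, mat))
        t2 = neighbor_joining(_dm(ids, mat))
        assert write_newick(t1) == write_newick(t2)

    def test_additive_recovery(self, rng):
        """NJ reconstructs the generating tree exactly on additive input."""
        for n in (5, 7, 9, 12):
            for _ in range(3):
                ids, mat, true_splits = random_additive(rng, n)
                tree = neighbor_joining(_dm(ids, mat))
                assert nontrivial_bipartitions(tree) == true_splits

    def test_matches_exhaustive_topology_search(self, rng):
        """NJ picks the topology with zero least-squares residual (n=5, 6)."""
        for n in (5, 6):
            ids, mat, _ = random_additive(rng, n)
            tree = neighbor_joining(_dm(ids, mat))
            nj_splits = frozenset(nontrivial_bipartitions(tree))
            best = min(
                enumerate_topologies(ids),
                key=lambda topo: least_squares_rss(ids, mat, topo),
            )
            assert nj_splits == best
            assert least_squares_rss(ids, mat, best) == pytest.approx(0.0, abs=1e-18)

    def test_tree_length_invariant_under_leaf_permutation(self, rng):
        ids, mat, _ = random_additive(rng, 8)
        perm = rng.permutation(8)
        tree1 = neighbor_joining(_dm(ids, mat))
        tree2 = neighbor_joining(
            _dm([ids[i] for i in perm], mat[np.ix_(perm, perm)])
        )
        length = lambda t: sum(
            e.length for e in t.preorder_edge_iter() if e.length is not None
        )
        assert length(tree1) == pytest.approx(length(tree2))
        assert nontrivial_bipartitions(tree1) == nontrivial_bipartitions(tree2)

    def test_undefined_cells_imputed(self):
        ids = ["a", "b", "c", "d"]
        mat = np.array(
            [[0, 0.1, 0.5, np.nan], [0.1, 0, 0.5, 0.5],
             [0.5, 0.5, 0, 0.1], [np.nan, 0.5, 0.1, 0]]
        )
        tree = neighbor_joining(_dm(ids, mat))  # should not raise
        assert len(tree.leaf_nodes()) == 4


class TestCladeComparison:
    def test_identical_trees(self, rng):
        ids, mat, _ = random_additive(rng, 8)
        tree = neighbor_joining(_dm(ids, mat))
        assert shared_clade_proportion(tree, tree) == 1.0

    def test_conflicting_four_taxon(self):
        ids = ["A", "B", "C", "D"]
        m1 = np.array([[0, 1, 5, 5], [1, 0, 5, 5], [5, 5, 0, 1], [5, 5, 1, 0]], float)
        m2 = np.array([[0, 5, 1, 5], [5, 0, 5, 1], [1, 5, 0, 5], [5, 1, 5, 0]], float)
        t1 = neighbor_joining(_dm(ids, m1))
        t2 = neighbor_joining(_dm(ids, m2))
        assert shared_clade_proportion(t1, t2) == 0.0

    def test_leaf_set_mismatch(self, rng):
        ids1, mat1, _ = random_additive(rng, 5)
        ids2 = [f"z{i}" for i in range(5)]
        t1 = neighbor_joining(_dm(ids1, mat1))
        t2 = neighbor_joining(_dm(ids2, mat1))
        with pytest.raises(ValueError):
            shared_clade_proportion(t1, t2)

    def test_against_dendropy_bipartition_oracle(self, rng):
        """Shared-clade fraction agrees with dendropy's bipartition compare."""
        for _ in range(5):
            ids, mat1, _ = random_additive(rng, 8)
            _, mat2, _ = random_additive(rng, 8)
            ta = neighbor_joining(_dm(ids, mat1))
            tb = neighbor_joining(_dm(ids, mat2))
            got = shared_clade_proportion(ta, tb)

            tns = dendropy.TaxonNamespace()
            da = dendropy.Tree.get(
                data=write_newick(ta), schema="newick", taxon_namespace=tns
            )
            db = dendropy.Tree.get(
                data=write_newick(tb), schema="newick", taxon_namespace=tns
            )
            da.is_rooted = db.is_rooted = False
            da.encode_bipartitions()
            db.encode_bipartitions()
            n_a = len(da.internal_edges(exclude_seed_edge=True))
            _, fn = treecompare.false_positives_and_negatives(da, db)
            assert got == pytest.approx((n_a - fn) / n_a)


class TestSpeciesMonophyly:
    def test_separated_species_true(self):
        ids = ["a1", "a2", "b1", "b2"]
        mat = np.array([[0, 1, 9, 9], [1, 0, 9, 9], [9, 9, 0, 1], [9, 9, 1, 0]], float)
        tree = neighbor_joining(_dm(ids, mat))
        result = species_monophyly(tree, {"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        assert result == {"A": True, "B": True}

    def test_interleaved_counterexample(self):
        # topology groups a1 with b1 and a2 with b2: neither species monophyletic
        ids = ["a1", "b1", "a2", "b2"]
        mat = np.array([[0, 1, 9, 9], [1, 0, 9, 9], [9, 9, 0, 1], [9, 9, 1, 0]], float)
        tree = neighbor_joining(_dm(ids, mat))
        result = species_monophyly(tree, {"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        assert result["A"] is False and result["B"] is False

    def test_singleton_true_by_convention(self):
        ids = ["a1", "a2", "b1", "c1"]
        mat = np.array(
            [[0, 1, 9, 9], [1, 0, 9, 9], [9, 9, 0, 8], [9, 9, 8, 0]], float
        )
        tree = neighbor_joining(_dm(ids, mat))
        result = species_monophyly(
            tree, {"a1": "A", "a2": "A", "b1": "B", "c1": "C"}
        )
        assert result["B"] is True and result["C"] is True


@pytest.fixture(scope="module")
def two_species_aln():
    cfg = SimConfig(
        seed=5, n_species=2, n_singletons=0, total_specimens=6,
        specimens_range=(3, 3), seq_length=500, indels_per_specimen=0.0,
    )
    aln, _ = evolve_alignment(simulate_species_tree(cfg), cfg)
    return aln


class TestBootstrap:
    def test_species_split_strongly_supported(self, two_species_aln):
        tree = bootstrap_support(two_species_aln, replicates=100, seed=1)
        species = {}
        for rec in two_species_aln:
            species.setdefault(rec.species, set()).add(rec.id)
        sides = list(species.values())
        ref = min(min(s) for s in sides)
        canon = frozenset(sides[0] if ref not in sides[0] else sides[1])
        assert tree.bipartition_support[canon] >= 95.0

    def test_single_replicate_support_binary(self, two_species_aln):
        tree = bootstrap_support(two_species_aln, replicates=1, seed=2)
        assert set(tree.bipartition_support.values()) <= {0.0, 100.0}

    def test_seed_determinism(self, two_species_aln):
        t1 = bootstrap_support(two_species_aln, replicates=25, seed=9)
        t2 = bootstrap_support(two_species_aln, replicates=25, seed=9)
        assert t1.bipartition_support == t2.bipartition_support

    def test_newick_round_trip_and_threshold(self, two_species_aln, tmp_path):
        tree = bootstrap_support(two_species_aln, replicates=25, seed=3)
        path = tmp_path / "tree.nwk"
        write_newick(tree, path, support_threshold=80.0)
        back = read_newick(str(path))
        assert {l.taxon.label for l in back.leaf_node_iter()} == set(
            two_species_aln.ids
        )
        assert nontrivial_bipartitions(back) == nontrivial_bipartitions(tree)
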