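"""Neighbor-joining trees, bootstrap support, and bipartition queries.

Trees are :class:`dendropy.Tree` objects (unrooted; the seed node is a
trifurcation). Neighbor joining follows the Saitou–Nei agglomeration with
two determinism rules:

* ties in the Q-criterion are broken by the lowest (row, column) index pair
  in the current matrix order (original input order, merged nodes appended);
* a negative branch length is clamped to zero and its deficit moved to the
  sister branch (which is itself floored at zero), preserving the path
  length through the new node where possible.

Bipartitions are represented as frozensets of leaf labels, canonicalised to
the side *not* containing the lexicographically smallest leaf; only
nontrivial splits (both sides >= 2 leaves) are enumerated.
"""

from __future__ import annotations

import dendropy
import numpy as np

from .distances import DistanceMatrix, Model, encode_alignment, matrix_from_codes
from .seq_io import AlignedSeqSet

__all__ = [
    "neighbor_joining",
    "bootstrap_support",
    "nontrivial_bipartitions",
    "shared_clade_proportion",
    "species_monophyly",
    "write_newick",
    "read_newick",
]


def _impute_undefined(values: np.ndarray) -> np.ndarray:
    """Replace NaN (saturated) cells with the maximum defined distance."""
    out = values.astype(float, copy=True)
    nan = np.isnan(out)
    if nan.any():
        defined = out[~nan]
        out[nan] = float(defined.max()) if defined.size else 0.0
    return out


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    if li < 0.0:
        lj = max(0.0, lj + li)
        li = 0.0
    elif lj < 0.0:
        li = max(0.0, li + lj)
        lj = 0.0
    return li, lj


def neighbor_joining(D: DistanceMatrix) -> dendropy.Tree:
    """Saitou–Nei neighbor joining; deterministic; >= 3 taxa required."""
    n = len(D)
    if n < 3:
        raise ValueError(f"neighbor joining needs >= 3 taxa, got {n}")

    taxon_ns = dendropy.TaxonNamespace(D.ids)
    tree = dendropy.Tree(taxon_namespace=taxon_ns)
    tree.is_rooted = False
    nodes: list[dendropy.Node] = []
    for taxon in taxon_ns:
        node = dendropy.Node(taxon=taxon)
        nodes.append(node)

    mat = _impute_undefined(D.values)
    active = list(range(n))  # indices into `nodes`
    dist = mat.copy()

    while len(active) > 2:
        m = len(active)
        sub = dist[np.ix_(active, active)]
        row_sums = sub.sum(axis=1)
        q = (m - 2) * sub - row_sums[:, None] - row_sums[None, :]
        np.fill_diagonal(q, np.inf)
        iu = np.triu_indices(m, k=1)
        q_upper = q[iu]
        # np.argmin scans row-major: first minimum is the lowest (i, j) pair
        k = int(np.argmin(q_upper))
        i, j = int(iu[0][k]), int(iu[1][k])
        d_ij = sub[i, j]
        if m > 2:
            li = 0.5 * d_ij + (row_sums[i] - row_sums[j]) / (2.0 * (m - 2))
        else:  # pragma: no cover - loop exits before m == 2
            li = 0.5 * d_ij
        lj = d_ij - li
        li, lj = _clamp_pair(li, lj)

        parent = dendropy.Node()
        ni, nj = nodes[active[i]], nodes[active[j]]
        parent.add_child(ni)
        parent.add_child(nj)
        ni.edge.length = li
        nj.edge.length = lj

        # distances from the new node to every other active node
        grown = np.pad(dist, ((0, 1), (0, 1)), constant_values=0.0)
        new_index = grown.shape[0] - 1
        for t, a in enumerate(active):
            if t in (i, j):
                continue
            d_uk = 0.5 * (sub[i, t] + sub[j, t] - d_ij)
            grown[new_index, a] = grown[a, new_index] = max(0.0, d_uk)
        dist = grown
        nodes.append(parent)
        active = [a for t, a in enumerate(active) if t not in (i, j)] + [new_index]

    # join the final two lineages through the seed node (yields the
    # standard unrooted tree: a trifurcation when n >= 3)
    a, b = active
    d_ab = max(0.0, dist[a, b])
    na, nb = nodes[a], nodes[b]
    if na.is_leaf() and not nb.is_leaf():
        na, nb = nb, na  # graft the leaf onto the internal node
    if na.is_leaf() and nb.is_leaf():  # pragma: no cover - n == 2 rejected above
        root = dendropy.Node()
        root.add_child(na)
        root.add_child(nb)
        na.edge.length = d_ab / 2.0
        nb.edge.length = d_ab / 2.0
        tree.seed_node = root
    else:
        na.add_child(nb)
        nb.edge.length = d_ab
        tree.seed_node = na
    tree.update_taxon_namespace()
    return tree


def _leaf_labels(tree: dendropy.Tree) -> frozenset[str]:
    return frozenset(leaf.taxon.label for leaf in tree.leaf_node_iter())


def nontrivial_bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Canonical nontrivial splits (both sides >= 2) as leaf-label sets."""
    all_leaves = _leaf_labels(tree)
    ref = min(all_leaves)
    splits: set[frozenset[str]] = set()
    for node in tree.postorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        side = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        other = all_leaves - side
        if len(side) < 2 or len(other) < 2:
            continue
        splits.add(other if ref in side else side)
    return splits


def shared_clade_proportion(
    tree_a: dendropy.Tree,
    tree_b: dendropy.Tree,
    *,
    denominator: str = "first",
) -> float:
    """Fraction of ``tree_a``'s nontrivial splits also present in ``tree_b``.

    Call with the window/query tree first and the reference tree second.
    ``denominator="second"`` divides by ``tree_b``'s split count instead.
    Trees with no nontrivial splits (< 4 leaves) score 1.0 vacuously.
    """
    la, lb = _leaf_labels(tree_a), _leaf_labels(tree_b)
    if la != lb:
        raise ValueError("trees have different leaf sets")
    sa, sb = nontrivial_bipartitions(tree_a), nontrivial_bipartitions(tree_b)
    denom = len(sa) if denominator == "first" else len(sb)
    if denom == 0:
        return 1.0
    return len(sa & sb) / denom


def species_monophyly(
    tree: dendropy.Tree, species_map: dict[str, str]
) -> dict[str, bool]:
    """Per-species monophyly on an unrooted tree.

    A species with >= 2 specimens is monophyletic iff some edge isolates
    exactly its specimen set; singletons are monophyletic by convention.
    """
    all_leaves = _leaf_labels(tree)
    sides: set[frozenset[str]] = set()
    for node in tree.postorder_node_iter():
        if node is tree.seed_node:
            continue
        side = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        sides.add(side)
        sides.add(all_leaves - side)
    species_members: dict[str, set[str]] = {}
    for leaf, sp in species_map.items():
        if leaf in all_leaves:
            species_members.setdefault(sp, set()).add(leaf)
    return {
        sp: (len(members) == 1 or frozenset(members) in sides)
        for sp, members in species_members.items()
    }


def bootstrap_support(
    aln: AlignedSeqSet,
    model: Model = "k2p",
    replicates: int = 1000,
    seed: int | None = None,
    *,
    display_threshold: float = 80.0,
) -> dendropy.Tree:
    """NJ tree from the full data with bootstrap support on internal edges.

    Alignment columns are resampled with replacement per replicate; support
    for each original bipartition is the percentage of replicate NJ trees
    containing it. Supports are stored on internal nodes (``node.label``)
    and in ``tree.bipartition_support``; :func:`write_newick` hides values
    below ``display_threshold`` (kept internally).
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    codes = encode_alignment(aln)
    tree = neighbor_joining(matrix_from_codes(codes, aln.ids, model))
    original = nontrivial_bipartitions(tree)
    counts = {split: 0 for split in original}
    n_cols = codes.shape[1]
    for _ in range(replicates):
        cols = rng.integers(0, n_cols, size=n_cols)
        rep_tree = neighbor_joining(matrix_from_codes(codes[:, cols], aln.ids, model))
        for split in nontrivial_bipartitions(rep_tree):
            if split in counts:
                counts[split] += 1
    support = {s: 100.0 * c / replicates for s, c in counts.items()}

    all_leaves = _leaf_labels(tree)
    ref = min(all_leaves)
    for node in tree.postorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        side = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        canon = (all_leaves - side) if ref in side else side
        if canon in support:
            node.label = f"{support[canon]:g}"
    tree.bipartition_support = support
    tree.support_display_threshold = display_threshold
    return tree


def write_newick(tree: dendropy.Tree, path=None, *, support_threshold: float | None = None):
    """Serialise to Newick; supports below the threshold are not rendered."""
    if support_threshold is None:
        support_threshold = getattr(tree, "support_display_threshold", None)
    out = tree.clone(depth=1)
    if support_threshold is not None:
        for node in out.postorder_node_iter():
            if node.is_leaf() or node.label is None:
                continue
            try:
                if float(node.label) < support_threshold:
                    node.label = None
            except ValueError:
                pass
    text = out.as_string(schema="newick", suppress_rooting=True)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def read_newick(source: str) -> dendropy.Tree:
    """Parse a Newick string or file path into an unrooted tree."""
    import os

    if os.path.exists(source):
        tree = dendropy.Tree.get(path=source, schema="newick")
    else:
        tree = dendropy.Tree.get(data=source, schema="newick")
    tree.is_rooted = False
    return tree
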