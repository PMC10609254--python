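"""Distance trees: neighbor-joining, bootstrap support, Robinson-Foulds.

Trees are dendropy objects, unrooted by convention; rooted drawings are
presentation only. Neighbor-joining is implemented directly so that two
contracts hold exactly:

* determinism — when two pairs minimise the Q-criterion equally, the
  pair whose (smallest-leaf-label) names sort first is joined;
* negative branch lengths are clamped to 0 with the deficit transferred
  to the sibling branch, preserving the joined pair's distance.

On additive distance matrices NJ recovers the generating topology and
branch lengths exactly; the test-suite checks this against matrices
built from random trees, and checks Robinson-Foulds against dendropy's
independent implementation.
"""

from __future__ import annotations

import numpy as np
import dendropy

from .pairwise import DistanceMatrix, SaturationError, k2p_matrix_from_array
from .seqio import SequenceRecord


def nj_tree(dist: DistanceMatrix) -> dendropy.Tree:
    """Canonical neighbor-joining tree from a distance matrix."""
    labels = list(dist.labels)
    n = len(labels)
    if n < 3:
        raise ValueError("neighbor-joining needs at least 3 taxa")
    if np.isnan(dist.values).any():
        raise ValueError("distance matrix contains missing (saturated) cells")

    ns = dendropy.TaxonNamespace(labels)
    nodes: list[dendropy.Node] = []
    names: list[str] = []  # smallest leaf label under each active node
    for lab in labels:
        node = dendropy.Node(taxon=ns.get_taxon(lab))
        nodes.append(node)
        names.append(lab)
    D = dist.values.copy()
    active = list(range(n))

    def join(i: int, j: int, li: float, lj: float) -> dendropy.Node:
        parent = dendropy.Node()
        # clamp negative lengths; deficit moves to the sibling branch
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        parent.add_child(nodes[i])
        nodes[i].edge.length = li
        parent.add_child(nodes[j])
        nodes[j].edge.length = lj
        return parent

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        ties = np.argwhere(np.isclose(q, qmin, rtol=0, atol=1e-12))
        # tie-break: lexicographically smallest (sorted) label pair
        best = min(
            ((a, b) for a, b in ties if a < b),
            key=lambda ab: tuple(sorted((names[active[ab[0]]],
                                         names[active[ab[1]]]))),
        )
        ai, aj = best
        gi, gj = active[ai], active[aj]
        dij = D[gi, gj]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = dij - li
        parent = join(gi, gj, li, lj)
        # new node reuses slot gi
        for k in active:
            if k in (gi, gj):
                continue
            dnew = 0.5 * (D[gi, k] + D[gj, k] - dij)
            D[gi, k] = D[k, gi] = dnew
        nodes[gi] = parent
        names[gi] = min(names[gi], names[gj])
        active.remove(gj)

    a, b, c = active
    # three-point formulas
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    root = dendropy.Node()
    for idx, ln in ((a, la), (b, lb), (c, lc)):
        root.add_child(nodes[idx])
        nodes[idx].edge.length = max(0.0, ln)
    tree = dendropy.Tree(taxon_namespace=ns, seed_node=root)
    tree.is_rooted = False
    return tree


def tree_splits(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial bipartitions, each written as the side that excludes
    the lexicographically smallest leaf label."""
    leaves = sorted(
        lf.taxon.label for lf in tree.leaf_node_iter() if lf.taxon
    )
    all_set = frozenset(leaves)
    anchor = leaves[0]
    splits: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        below = frozenset(
            lf.taxon.label for lf in node.leaf_iter() if lf.taxon
        )
        side = all_set - below if anchor in below else below
        if 1 < len(side) < len(leaves) - 1:
            splits.add(side)
    return splits


def rf_distance(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Unnormalised Robinson-Foulds distance between two trees.

    Counts internal bipartitions present in exactly one tree; 0 iff the
    unrooted topologies are identical, at most 2(n-3) for binary trees.
    """
    l1 = {lf.taxon.label for lf in t1.leaf_node_iter() if lf.taxon}
    l2 = {lf.taxon.label for lf in t2.leaf_node_iter() if lf.taxon}
    if l1 != l2:
        raise ValueError(
            "leaf sets differ: "
            f"only in first={sorted(l1 - l2)}, only in second={sorted(l2 - l1)}"
        )
    return len(tree_splits(t1) ^ tree_splits(t2))


def bootstrap_support(
    records: list[SequenceRecord], n_reps: int = 1000, seed: int = 0
) -> dendropy.Tree:
    """NJ point-estimate tree with bootstrap supports on internal nodes.

    Alignment columns are resampled with replacement per replicate (one
    RNG stream from ``seed``), K2P + NJ recomputed, and each internal
    bipartition of the point tree is scored by the percentage of
    successful replicates containing it. Replicates where a distance
    saturates are dropped and counted on the returned tree as
    ``bootstrap_dropped``.

    Sequences must be equal length (an aligned, homologous set).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    ids = [r.id for r in records]
    arr = np.frombuffer(
        "".join(r.residues for r in records).encode(), dtype="S1"
    ).reshape(len(records), -1)
    point = nj_tree(k2p_matrix_from_array(ids, arr))
    target_splits = tree_splits(point)
    counts = {s: 0 for s in target_splits}

    rng = np.random.default_rng(seed)
    n_sites = arr.shape[1]
    dropped = 0
    done = 0
    for _ in range(n_reps):
        cols = rng.integers(0, n_sites, size=n_sites)
        try:
            rep_tree = nj_tree(k2p_matrix_from_array(ids, arr[:, cols]))
        except (SaturationError, ValueError):
            dropped += 1
            continue
        done += 1
        rep_splits = tree_splits(rep_tree)
        for s in target_splits:
            if s in rep_splits:
                counts[s] += 1

    denom = max(done, 1)
    leaves = sorted(ids)
    all_set = frozenset(leaves)
    anchor = leaves[0]
    for node in point.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        below = frozenset(
            lf.taxon.label for lf in node.leaf_iter() if lf.taxon
        )
        side = all_set - below if anchor in below else below
        if side in counts:
            node.label = str(round(100.0 * counts[side] / denom))
    point.bootstrap_dropped = dropped
    point.bootstrap_replicates = done
    return point
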