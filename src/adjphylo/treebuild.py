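"""Distance-based tree reconstruction: neighbor joining, UPGMA and balanced
minimum evolution (BME) by NNI hill-climbing from the NJ topology.

All builders are deterministic: criterion ties are broken by the
lexicographic order of the cluster labels (the smallest leaf name in each
cluster), so the same matrix always yields the same tree.

Negative NJ branch lengths are clamped to zero with the deficit moved to the
sister branch, the usual practical convention.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .distances import DistanceMatrix
from .tree import Node, PhyloTree

__all__ = [
    "nj_tree",
    "upgma_tree",
    "me_tree",
    "bme_length",
    "tree_distance_matrix",
]


def _check(dm: DistanceMatrix, min_taxa: int) -> None:
    if len(dm) < min_taxa:
        raise ValueError(f"need at least {min_taxa} taxa")
    if not np.all(np.isfinite(dm.values)):
        raise ValueError("non-finite distances")


def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Saitou–Nei neighbor joining; returns an unrooted tree represented with
    a trifurcating root."""
    _check(dm, 3)
    d = dm.values.astype(float).copy()
    nodes = [Node(name=t) for t in dm.taxa]
    labels = list(dm.taxa)  # smallest leaf name per cluster, for tie-breaks
    active = list(range(len(nodes)))

    while len(active) > 3:
        r = len(active)
        sums = {i: sum(d[i, k] for k in active if k != i) for i in active}
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                q = (r - 2) * d[i, j] - sums[i] - sums[j]
                key = (q, *sorted((labels[i], labels[j])))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        li = 0.5 * d[i, j] + (sums[i] - sums[j]) / (2 * (r - 2))
        lj = d[i, j] - li
        li, lj = _clamp_pair(li, lj)
        parent = Node()
        ni, nj_ = nodes[i], nodes[j]
        ni.length, nj_.length = li, lj
        parent.add_child(ni)
        parent.add_child(nj_)
        # distances to the new node
        for k in active:
            if k in (i, j):
                continue
            d[i, k] = d[k, i] = 0.5 * (d[i, k] + d[j, k] - d[i, j])
        nodes[i] = parent
        labels[i] = min(labels[i], labels[j])
        active.remove(j)

    i, j, k = active
    root = Node()
    for a, b, c in ((i, j, k), (j, i, k), (k, i, j)):
        nodes[a].length = max(0.0, 0.5 * (d[a, b] + d[a, c] - d[b, c]))
        root.add_child(nodes[a])
    return PhyloTree(root)


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    if li < 0:
        lj += li
        li = 0.0
    if lj < 0:
        li += lj
        lj = 0.0
    return max(li, 0.0), max(lj, 0.0)


def upgma_tree(dm: DistanceMatrix) -> PhyloTree:
    """Average-linkage clustering; returns a rooted ultrametric tree."""
    _check(dm, 3)
    d = dm.values.astype(float).copy()
    nodes = [Node(name=t) for t in dm.taxa]
    labels = list(dm.taxa)
    sizes = [1] * len(nodes)
    heights = [0.0] * len(nodes)
    active = list(range(len(nodes)))

    while len(active) > 1:
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                key = (d[i, j], *sorted((labels[i], labels[j])))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        height = 0.5 * d[i, j]
        parent = Node()
        for child_idx in (i, j):
            child = nodes[child_idx]
            child.length = height - heights[child_idx]
            parent.add_child(child)
        for k in active:
            if k in (i, j):
                continue
            d[i, k] = d[k, i] = (sizes[i] * d[i, k] + sizes[j] * d[j, k]) / (
                sizes[i] + sizes[j]
            )
        nodes[i] = parent
        sizes[i] += sizes[j]
        heights[i] = height
        labels[i] = min(labels[i], labels[j])
        active.remove(j)
    return PhyloTree(nodes[active[0]])


# --------------------------------------------------------------------------
# balanced minimum evolution
#
# Trees are manipulated as undirected graphs over integer node ids; a
# degree-2 root is suppressed so topological leaf-to-leaf path lengths match
# the unrooted tree.  The BME length of a topology is Pauplin's formula
#   L(T) = sum_{i<j} d_ij * 2^(1 - p_ij)
# with p_ij the number of edges between leaves i and j.


def _tree_to_graph(tree: PhyloTree):
    adj: dict[int, set[int]] = {}
    names: dict[int, str] = {}
    counter = [0]

    def walk(node: Node) -> int:
        nid = counter[0]
        counter[0] += 1
        adj[nid] = set()
        if node.is_leaf:
            names[nid] = node.name
        for child in node.children:
            cid = walk(child)
            adj[nid].add(cid)
            adj[cid].add(nid)
        return nid

    root_id = walk(tree.root)
    if len(adj[root_id]) == 2:  # suppress rooted representation
        a, b = sorted(adj[root_id])
        adj[a].discard(root_id)
        adj[b].discard(root_id)
        adj[a].add(b)
        adj[b].add(a)
        del adj[root_id]
    return adj, names


def _graph_to_tree(adj, names) -> PhyloTree:
    internal = [n for n in adj if n not in names]
    start = min(internal) if internal else min(adj)

    def build(nid: int, parent: Optional[int]) -> Node:
        node = Node(name=names.get(nid))
        for nb in sorted(adj[nid]):
            if nb != parent:
                node.add_child(build(nb, nid))
        return node

    return PhyloTree(build(start, None))


def _leaf_path_lengths(adj, names) -> dict[tuple[int, int], int]:
    lengths = {}
    for leaf in names:
        dist = {leaf: 0}
        frontier = [leaf]
        while frontier:
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if v not in dist:
                        dist[v] = dist[u] + 1
                        nxt.append(v)
            frontier = nxt
        for other in names:
            if other > leaf:
                lengths[(leaf, other)] = dist[other]
    return lengths


def _bme_length_graph(adj, names, dm: DistanceMatrix) -> float:
    idx = {t: i for i, t in enumerate(dm.taxa)}
    total = 0.0
    for (a, b), p in _leaf_path_lengths(adj, names).items():
        total += dm.values[idx[names[a]], idx[names[b]]] * 2.0 ** (1 - p)
    return total


def bme_length(tree: PhyloTree, dm: DistanceMatrix) -> float:
    """Pauplin (balanced) tree length of a topology under a distance matrix."""
    adj, names = _tree_to_graph(tree)
    return _bme_length_graph(adj, names, dm)


def _nni_neighbourhood(adj, names):
    """Yield (edge, alternative_index, new_adj) for every NNI rearrangement,
    in a deterministic order."""
    internal_edges = sorted(
        (u, v)
        for u in adj
        for v in adj[u]
        if u < v and u not in names and v not in names
    )
    for u, v in internal_edges:
        u_side = sorted(adj[u] - {v})
        v_side = sorted(adj[v] - {u})
        b = v_side[1]
        for alt, c in enumerate(u_side):
            new_adj = {k: set(s) for k, s in adj.items()}
            new_adj[v].discard(b)
            new_adj[b].discard(v)
            new_adj[u].discard(c)
            new_adj[c].discard(u)
            new_adj[v].add(c)
            new_adj[c].add(v)
            new_adj[u].add(b)
            new_adj[b].add(u)
            yield (u, v), alt, new_adj


def me_tree(dm: DistanceMatrix, return_trace: bool = False):
    """Balanced minimum evolution: NNI hill-climb from the NJ topology.

    Each accepted rearrangement strictly decreases the Pauplin tree length;
    the search stops at a local optimum.  Branch lengths of the final
    topology are ordinary least-squares estimates (clamped at zero).
    """
    _check(dm, 4)
    adj, names = _tree_to_graph(nj_tree(dm))
    current = _bme_length_graph(adj, names, dm)
    trace = [current]
    improved = True
    while improved:
        improved = False
        best = None
        for edge, alt, cand in _nni_neighbourhood(adj, names):
            length = _bme_length_graph(cand, names, dm)
            if length < current - 1e-12 and (best is None or length < best[0] - 1e-15):
                best = (length, cand)
        if best is not None:
            current, adj = best[0], best[1]
            trace.append(current)
            improved = True
    tree = _graph_to_tree(adj, names)
    _fit_ols_branch_lengths(tree, dm)
    if return_trace:
        return tree, trace
    return tree


def _fit_ols_branch_lengths(tree: PhyloTree, dm: DistanceMatrix) -> None:
    """Least-squares branch lengths on a fixed topology (clamped >= 0)."""
    edges = [n for n in tree.postorder() if n is not tree.root]
    edge_idx = {id(n): k for k, n in enumerate(edges)}
    leaves = tree.leaves()
    idx = {t: i for i, t in enumerate(dm.taxa)}

    # leaf sets below each edge
    below: dict[int, frozenset] = {}
    for node in tree.postorder():
        if node.is_leaf:
            below[id(node)] = frozenset([node.name])
        else:
            below[id(node)] = frozenset().union(*(below[id(c)] for c in node.children))

    rows, rhs = [], []
    for a in range(len(leaves)):
        for b in range(a + 1, len(leaves)):
            la, lb = leaves[a].name, leaves[b].name
            row = np.zeros(len(edges))
            for n in edges:
                side = below[id(n)]
                if (la in side) != (lb in side):
                    row[edge_idx[id(n)]] = 1.0
            rows.append(row)
            rhs.append(dm.values[idx[la], idx[lb]])
    sol, *_ = np.linalg.lstsq(np.array(rows), np.array(rhs), rcond=None)
    for n in edges:
        n.length = max(0.0, float(sol[edge_idx[id(n)]]))


def tree_distance_matrix(tree: PhyloTree) -> DistanceMatrix:
    """Additive (path-length) distances between the leaves of a tree with
    branch lengths."""
    leaves = tree.leaves()
    names = [l.name for l in leaves]
    # accumulate root-to-leaf paths
    paths: dict[str, list[Node]] = {}

    def walk(node: Node, acc: list[Node]):
        acc = acc + [node]
        if node.is_leaf:
            paths[node.name] = acc
        for c in node.children:
            walk(c, acc)

    walk(tree.root, [])
    n = len(names)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pa, pb = paths[names[i]], paths[names[j]]
            shared = 0
            for x, y in zip(pa, pb):
                if x is y:
                    shared += 1
                else:
                    break
            d = sum((x.length or 0.0) for x in pa[shared:]) + sum(
                (y.length or 0.0) for y in pb[shared:]
            )
            values[i, j] = values[j, i] = d
    values[values < 0] = 0.0
    return DistanceMatrix(taxa=names, values=values)
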