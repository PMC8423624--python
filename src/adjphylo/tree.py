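"""Lightweight phylogenetic tree structure shared by all analysis stages.

Trees are stored as rooted node hierarchies; operations that are logically
unrooted (bipartitions, Robinson--Foulds comparison) normalise splits so the
placement of the root is irrelevant.  Newick parsing and serialisation are
delegated to dendropy.
"""

from __future__ import annotations

import io
from typing import Iterable, Iterator, Optional

import dendropy

__all__ = ["Node", "PhyloTree", "TreeError"]


class TreeError(ValueError):
    """Raised for malformed Newick input or invalid tree operations."""


class Node:
    __slots__ = ("name", "length", "support", "children", "parent")

    def __init__(self, name: Optional[str] = None, length: Optional[float] = None):
        self.name = name
        self.length = length
        self.support: Optional[float] = None
        self.children: list[Node] = []
        self.parent: Optional[Node] = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def postorder(self) -> Iterator["Node"]:
        for c in self.children:
            yield from c.postorder()
        yield self

    def preorder(self) -> Iterator["Node"]:
        yield self
        for c in self.children:
            yield from c.preorder()

    def leaves(self) -> list["Node"]:
        return [n for n in self.postorder() if n.is_leaf]

    def copy(self) -> "Node":
        dup = Node(self.name, self.length)
        dup.support = self.support
        for c in self.children:
            dup.add_child(c.copy())
        return dup

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<Node {self.name or '*'} len={self.length}>"


class PhyloTree:
    """A (possibly rooted) tree with named leaves and optional branch lengths."""

    def __init__(self, root: Node):
        self.root = root
        names = [l.name for l in root.leaves()]
        if len(names) != len(set(names)):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise TreeError(f"duplicate leaf labels: {', '.join(map(str, dup))}")
        if any(n is None for n in names):
            raise TreeError("every leaf must be labelled")

    # ------------------------------------------------------------------ IO
    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        try:
            dtree = dendropy.Tree.get(
                data=text,
                schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except Exception as exc:  # dendropy raises assorted parse errors
            raise TreeError(f"invalid Newick: {exc}") from exc

        def convert(dnode) -> Node:
            name = dnode.taxon.label if dnode.taxon is not None else dnode.label
            node = Node(name=name, length=dnode.edge.length)
            for child in dnode.child_nodes():
                node.add_child(convert(child))
            return node

        return cls(convert(dtree.seed_node))

    def to_newick(self, include_supports: bool = False) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf:
                body = node.name
            else:
                inner = ",".join(fmt(c) for c in node.children)
                label = ""
                if include_supports and node.support is not None:
                    label = format(node.support, "g")
                elif node.name:
                    label = node.name
                body = f"({inner}){label}"
            if node.length is not None:
                body += f":{node.length:.10g}"
            return body

        return fmt(self.root) + ";"

    # ----------------------------------------------------------- traversal
    def postorder(self) -> Iterator[Node]:
        return self.root.postorder()

    def preorder(self) -> Iterator[Node]:
        return self.root.preorder()

    def leaves(self) -> list[Node]:
        return self.root.leaves()

    @property
    def leaf_names(self) -> list[str]:
        return [l.name for l in self.leaves()]

    def find_leaf(self, name: str) -> Node:
        for leaf in self.leaves():
            if leaf.name == name:
                return leaf
        raise TreeError(f"leaf {name!r} not in tree")

    def copy(self) -> "PhyloTree":
        return PhyloTree(self.root.copy())

    # --------------------------------------------------------------- splits
    def bipartitions(self) -> set[frozenset]:
        """Non-trivial unrooted splits, each given as the side that excludes
        the lexicographically smallest leaf."""
        all_leaves = frozenset(self.leaf_names)
        anchor = min(all_leaves)
        splits: set[frozenset] = set()
        below: dict[int, frozenset] = {}
        for node in self.postorder():
            if node.is_leaf:
                below[id(node)] = frozenset([node.name])
            else:
                below[id(node)] = frozenset().union(
                    *(below[id(c)] for c in node.children)
                )
            side = below[id(node)]
            if anchor in side:
                side = all_leaves - side
            if 2 <= len(side) <= len(all_leaves) - 2:
                splits.add(side)
        return splits

    def rf_distance(self, other: "PhyloTree") -> int:
        if set(self.leaf_names) != set(other.leaf_names):
            raise TreeError("trees have different leaf sets")
        a, b = self.bipartitions(), other.bipartitions()
        return len(a ^ b)

    def mrca(self, names: Iterable[str]) -> Node:
        target = set(names)
        missing = target - set(self.leaf_names)
        if missing:
            raise TreeError(f"leaves not in tree: {sorted(missing)}")
        for node in self.postorder():
            if target <= {l.name for l in node.leaves()}:
                return node
        raise TreeError("mrca not found")  # pragma: no cover

    # -------------------------------------------------------------- rooting
    def rooted_on(self, outgroup: Iterable[str]) -> "PhyloTree":
        """Return a copy rooted so the given taxa form one child clade of the
        root.  The tree must contain an edge separating exactly these taxa
        from the rest."""
        out = frozenset(outgroup)
        all_leaves = frozenset(self.leaf_names)
        if not out or not out < all_leaves:
            raise TreeError("outgroup must be a proper non-empty subset of the leaves")
        work = self.root.copy()
        target = None
        for node in work.postorder():
            if node is work:
                continue
            side = frozenset(l.name for l in node.leaves())
            if side == out or side == all_leaves - out:
                target = node
                break
        if target is None:
            raise TreeError(
                "no edge separates the outgroup from the ingroup; "
                "the outgroup is not monophyletic on this tree"
            )
        rerooted = _reroot_above(target)
        # orient so the outgroup clade is the first child
        kids = rerooted.children
        if frozenset(l.name for l in kids[0].leaves()) != out:
            kids.reverse()
        return PhyloTree(rerooted)

    def terminal_branch_length(self, name: str) -> float:
        leaf = self.find_leaf(name)
        return leaf.length if leaf.length is not None else 0.0


def _reroot_above(node: Node) -> Node:
    """Reroot the tree on the edge above `node`, splitting its length 50/50."""
    old_len = node.length
    half = old_len / 2.0 if old_len is not None else None
    parent = node.parent
    if parent is None:
        raise TreeError("cannot reroot on the root node")
    new_root = Node()
    # detach node from parent
    parent.children.remove(node)
    node.parent = None
    node.length = half
    new_root.add_child(node)
    flipped = _flip_upwards(parent)
    flipped.length = half
    new_root.add_child(flipped)
    _suppress_unifurcations(new_root)
    return new_root


def _suppress_unifurcations(node: Node) -> None:
    new_children = []
    for c in node.children:
        while not c.is_leaf and len(c.children) == 1:
            only = c.children[0]
            if c.length is not None or only.length is not None:
                only.length = (c.length or 0.0) + (only.length or 0.0)
            c = only
        c.parent = node
        new_children.append(c)
    node.children = new_children


def _flip_upwards(node: Node) -> Node:
    """Reverse parent pointers from `node` up to the old root; returns `node`
    as the root of the re-hung subtree.  Unifurcations left by the old root
    are suppressed (their branch lengths merged)."""
    parent = node.parent
    node.parent = None
    if parent is not None:
        parent.children.remove(node)
        rehung = _flip_upwards(parent)
        rehung.length = node.length
        node.children.append(rehung)
        rehung.parent = node
    node.length = None
    # suppress unifurcating children (old root with a single remaining child)
    new_children = []
    for c in node.children:
        if not c.is_leaf and len(c.children) == 1:
            only = c.children[0]
            if c.length is not None or only.length is not None:
                only.length = (c.length or 0.0) + (only.length or 0.0)
            only.parent = node
            new_children.append(only)
        else:
            new_children.append(c)
    node.children = new_children
    return node
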