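"""Lightweight rooted trees with newick I/O.

All stages of the pipeline (simulation, neighbor joining, reconciliation,
codon-model likelihoods) share this one tree representation: a mutable
node-linked rooted tree.  Newick parsing and serialization are delegated
to dendropy so the dialect (quoting, comments, support labels) matches
what other tools emit.
"""

from __future__ import annotations

import itertools
from typing import Callable, Iterator, Optional

import dendropy

__all__ = ["Node", "parse_newick", "to_newick", "bipartitions", "same_unrooted_topology"]

_counter = itertools.count()


class Node:
    """A node of a rooted tree.

    Attributes
    ----------
    name : str or None
        Leaf name (or an optional internal label).
    length : float
        Length of the branch above this node; 0.0 at the root.
    children : list of Node
    parent : Node or None
    support : float or None
        Bootstrap support of the branch above, on a 0-100 scale.
    meta : dict
        Free-form per-node annotations (event labels, branch classes, ...).
    """

    __slots__ = ("name", "length", "children", "parent", "support", "meta", "_uid")

    def __init__(self, name: Optional[str] = None, length: float = 0.0,
                 children: Optional[list["Node"]] = None):
        self.name = name
        self.length = float(length)
        self.children: list[Node] = []
        self.parent: Optional[Node] = None
        self.support: Optional[float] = None
        self.meta: dict = {}
        self._uid = next(_counter)
        for c in children or []:
            self.add_child(c)

    # -- structure -----------------------------------------------------
    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def remove_child(self, child: "Node") -> None:
        self.children.remove(child)
        child.parent = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self) -> Iterator["Node"]:
        stack, out = [self], []
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return reversed(out)

    def preorder(self) -> Iterator["Node"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list["Node"]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def find(self, name: str) -> Optional["Node"]:
        for n in self.postorder():
            if n.name == name:
                return n
        return None

    def copy(self) -> "Node":
        new = Node(self.name, self.length)
        new.support = self.support
        new.meta = dict(self.meta)
        for c in self.children:
            new.add_child(c.copy())
        return new

    def depth(self) -> float:
        """Sum of branch lengths from the root down to this node."""
        d, n = 0.0, self
        while n.parent is not None:
            d += n.length
            n = n.parent
        return d

    # -- editing -------------------------------------------------------
    def suppress_unifurcations(self) -> "Node":
        """Collapse nodes with a single child (merging branch lengths).

        Returns the (possibly new) root.
        """
        root = self
        changed = True
        while changed:
            changed = False
            for node in list(root.postorder()):
                if len(node.children) == 1:
                    child = node.children[0]
                    if node.parent is None:
                        child.parent = None
                        child.length = 0.0
                        root = child
                    else:
                        parent = node.parent
                        idx = parent.children.index(node)
                        child.length += node.length
                        child.parent = parent
                        parent.children[idx] = child
                    changed = True
        return root

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<Node {self.name or '*'} len={self.length:g} nchild={len(self.children)}>"


# ---------------------------------------------------------------------------
# newick I/O via dendropy


def _from_dendropy(dnode: dendropy.Node) -> Node:
    name = None
    if dnode.taxon is not None:
        name = dnode.taxon.label
    elif dnode.label is not None:
        name = dnode.label
    node = Node(name=name, length=dnode.edge.length or 0.0)
    for child in dnode.child_nodes():
        node.add_child(_from_dendropy(child))
    if not node.is_leaf and name is not None:
        # internal labels written by bootstrap_support are numeric supports
        try:
            node.support = float(name)
            node.name = None
        except ValueError:
            pass
    return node


def parse_newick(text: str) -> Node:
    dtree = dendropy.Tree.get(data=text, schema="newick",
                              preserve_underscores=True,
                              suppress_internal_node_taxa=True)
    return _from_dendropy(dtree.seed_node)


def _to_dendropy(node: Node, dtree: dendropy.Tree, dnode: dendropy.Node,
                 support_as_label: bool) -> None:
    for child in node.children:
        dchild = dendropy.Node()
        dchild.edge.length = child.length
        if child.is_leaf:
            dchild.taxon = dtree.taxon_namespace.require_taxon(label=child.name)
        else:
            if support_as_label and child.support is not None:
                dchild.label = f"{child.support:g}"
            elif child.name:
                dchild.label = child.name
        dnode.add_child(dchild)
        _to_dendropy(child, dtree, dchild, support_as_label)


def to_newick(root: Node, support_as_label: bool = False) -> str:
    dtree = dendropy.Tree()
    if root.name and root.is_leaf:
        dtree.seed_node.taxon = dtree.taxon_namespace.require_taxon(label=root.name)
    elif root.name:
        dtree.seed_node.label = root.name
    _to_dendropy(root, dtree, dtree.seed_node, support_as_label)
    return dtree.as_string(schema="newick", suppress_rooting=True,
                           unquoted_underscores=True).strip()


# ---------------------------------------------------------------------------
# topology utilities


def bipartitions(root: Node) -> set[frozenset[str]]:
    """Non-trivial unrooted bipartitions, each as the leaf set of one side.

    Each internal edge splits the leaves in two; the side not containing
    the lexicographically smallest leaf is used as the canonical key.
    """
    all_leaves = frozenset(root.leaf_names())
    anchor = min(all_leaves)
    splits: set[frozenset[str]] = set()
    for node in root.postorder():
        if node.parent is None or node.is_leaf:
            continue
        below = frozenset(n.name for n in node.leaves())
        side = below if anchor not in below else all_leaves - below
        if 1 < len(side) < len(all_leaves) - 1:
            splits.add(side)
    return splits


def same_unrooted_topology(a: Node, b: Node) -> bool:
    if set(a.leaf_names()) != set(b.leaf_names()):
        return False
    return bipartitions(a) == bipartitions(b)


def mrca(root: Node, names: set[str]) -> Node:
    """Smallest clade of `root` containing every name in `names`."""
    want = set(names)
    best = root
    for node in root.postorder():
        below = set(n.name for n in node.leaves())
        if want <= below and len(below) < len(set(n.name for n in best.leaves())):
            best = node
    return best


def reroot_above(node: Node, fraction: float = 0.5) -> Node:
    """Reroot the tree on the branch above `node`.

    A new root is created `fraction` of the way up the branch from `node`
    towards its current parent.  Returns the new root; the old root is
    suppressed if it becomes a unifurcation.
    """
    if node.parent is None:
        return node
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    # Invert parent pointers from node's parent up to the old root.
    path: list[Node] = []
    cur: Optional[Node] = node.parent
    while cur is not None:
        path.append(cur)
        cur = cur.parent
    old_parent = node.parent
    old_parent.remove_child(node)

    new_root = Node()
    below_len = node.length * fraction
    above_len = node.length - below_len
    new_root.add_child(node)
    node.length = below_len

    # walk up the old path, flipping each edge
    prev = new_root
    carry_len = above_len
    for i, cur in enumerate(path):
        nxt = path[i + 1] if i + 1 < len(path) else None
        if nxt is not None:
            nxt.remove_child(cur)
        edge_len = cur.length
        cur.length = carry_len
        prev.add_child(cur)
        prev = cur
        carry_len = edge_len
    return _tidy_root(new_root)


def _tidy_root(root: Node) -> Node:
    # collapse any unifurcation left behind by rerooting
    for node in list(root.postorder()):
        if node is not root and len(node.children) == 1:
            child = node.children[0]
            parent = node.parent
            idx = parent.children.index(node)
            child.length += node.length
            child.parent = parent
            parent.children[idx] = child
    if len(root.children) == 1:
        child = root.children[0]
        child.parent = None
        child.length = 0.0
        return child
    return root
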