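"""Rooted phylogenetic tree model and traversal/manipulation primitives.

The tree is stored as a flat ``id -> TreeNode`` table with explicit parent and
child links.  Child order is a first-class property: it does not affect the
topology (the set of clades) but determines leaf order in layouts and hence
tanglegram crossings, so every operation except :func:`ladderize` and the
tanglegram optimizer preserves it.

Branches are identified with their child node: every non-root node has exactly
one subtending branch, and per-branch state (category tags, lengths) lives on
that node.  The root has no branch.

Two independent display flags exist per node: ``hidden`` removes a subtree
from layout and traversal entirely, while ``collapsed`` keeps the subtree in
the model but lets layouts replace it with a single leaf slot and a boundary
glyph.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Iterator, Optional


class TreeError(Exception):
    """Structural or contract violation on a tree operation."""


@dataclass
class TreeNode:
    id: int
    label: str = ""
    length: Optional[float] = None
    tags: set = field(default_factory=set)
    children: list = field(default_factory=list)   # child node ids, ordered
    parent: Optional[int] = None
    collapsed: bool = False
    hidden: bool = False
    payload: dict = field(default_factory=dict)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def copy(self) -> "TreeNode":
        return TreeNode(
            id=self.id,
            label=self.label,
            length=self.length,
            tags=set(self.tags),
            children=list(self.children),
            parent=self.parent,
            collapsed=self.collapsed,
            hidden=self.hidden,
            payload=dict(self.payload),
        )


class Tree:
    """A rooted tree: a node table plus the root id.

    Parameters
    ----------
    name:
        Optional tree name (e.g. from a NeXML ``tree`` element).
    """

    def __init__(self, name: str = ""):
        self.name = name
        self.nodes: dict[int, TreeNode] = {}
        self.root: Optional[int] = None
        self._next_id = itertools.count()

    # -- construction -----------------------------------------------------
    def add_node(self, label: str = "", length: Optional[float] = None,
                 parent: Optional[int] = None) -> TreeNode:
        node = TreeNode(id=next(self._next_id), label=label, length=length,
                        parent=parent)
        self.nodes[node.id] = node
        if parent is None:
            if self.root is not None:
                raise TreeError("tree already has a root")
            self.root = node.id
        else:
            self.nodes[parent].children.append(node.id)
        return node

    def __getitem__(self, node_id: int) -> TreeNode:
        try:
            return self.nodes[node_id]
        except KeyError:
            raise TreeError(f"unknown node id {node_id!r}") from None

    def __len__(self) -> int:
        return len(self.nodes)

    def __contains__(self, node_id: int) -> bool:
        return node_id in self.nodes

    @property
    def root_node(self) -> TreeNode:
        if self.root is None:
            raise TreeError("empty tree")
        return self.nodes[self.root]

    # -- iteration --------------------------------------------------------
    def preorder(self, start: Optional[int] = None,
                 skip_hidden: bool = False) -> Iterator[TreeNode]:
        """Yield nodes parent-first, children in stored order."""
        if self.root is None:
            return
        stack = [start if start is not None else self.root]
        while stack:
            node = self[stack.pop()]
            if skip_hidden and node.hidden:
                continue
            yield node
            stack.extend(reversed(node.children))

    def postorder(self, start: Optional[int] = None,
                  skip_hidden: bool = False) -> Iterator[TreeNode]:
        """Yield nodes children-first (each child block in stored order)."""
        if self.root is None:
            return
        stack: list[tuple[int, bool]] = [(start if start is not None else self.root, False)]
        while stack:
            node_id, expanded = stack.pop()
            node = self[node_id]
            if skip_hidden and node.hidden:
                continue
            if expanded:
                yield node
            else:
                stack.append((node_id, True))
                stack.extend((c, False) for c in reversed(node.children))

    def leaves(self, start: Optional[int] = None) -> list[TreeNode]:
        return [n for n in self.preorder(start) if n.is_leaf]

    def path_to_root(self, node_id: int) -> list[TreeNode]:
        """Nodes from ``node_id`` up to and including the root."""
        out = [self[node_id]]
        while out[-1].parent is not None:
            out.append(self[out[-1].parent])
        return out

    def find(self, label: str) -> Optional[TreeNode]:
        for node in self.preorder():
            if node.label == label:
                return node
        return None

    def mrca(self, node_ids) -> TreeNode:
        """Most recent common ancestor of a set of nodes."""
        ids = list(node_ids)
        if not ids:
            raise TreeError("mrca of empty set")
        paths = [[n.id for n in self.path_to_root(i)] for i in ids]
        common = set(paths[0]).intersection(*map(set, paths[1:]))
        for nid in paths[0]:           # deepest first
            if nid in common:
                return self[nid]
        raise TreeError("nodes share no ancestor")  # pragma: no cover

    # -- copying / comparison ---------------------------------------------
    def copy(self) -> "Tree":
        dup = Tree(name=self.name)
        dup.nodes = {i: n.copy() for i, n in self.nodes.items()}
        dup.root = self.root
        dup._next_id = itertools.count(max(self.nodes, default=-1) + 1)
        return dup

    def clades(self) -> list[frozenset]:
        """Leaf-label set of every internal node (topology fingerprint)."""
        out = []
        for node in self.preorder():
            if not node.is_leaf:
                out.append(frozenset(l.label for l in self.leaves(node.id)))
        return out

    def topology_signature(self) -> tuple:
        return tuple(sorted((n.id, n.parent, tuple(n.children))
                            for n in self.nodes.values()))

    def validate(self) -> None:
        """Raise TreeError on any broken structural invariant."""
        if self.root is None:
            raise TreeError("empty tree")
        roots = [n for n in self.nodes.values() if n.parent is None]
        if len(roots) != 1 or roots[0].id != self.root:
            raise TreeError("tree must have exactly one parentless root node")
        seen = set()
        for node in self.preorder():
            if node.id in seen:
                raise TreeError("cycle detected")
            seen.add(node.id)
            for cid in node.children:
                if cid not in self.nodes:
                    raise TreeError(f"dangling child id {cid}")
                if self.nodes[cid].parent != node.id:
                    raise TreeError(f"parent link of {cid} inconsistent")
            if node.is_leaf and node.collapsed:
                raise TreeError("collapsed flag on a leaf")
            if node.length is not None and node.length < 0:
                raise TreeError("negative branch length")
        if seen != set(self.nodes):
            raise TreeError("tree is not connected")


# ---------------------------------------------------------------------------
# traversal / manipulation operations
# ---------------------------------------------------------------------------

def traverse_and_compute(tree: Tree, order: str,
                         visitor: Callable[[TreeNode, Tree], None]) -> Tree:
    """Apply ``visitor(node, tree)`` to every non-hidden node.

    ``order`` is ``"preorder"`` (parent before children) or ``"postorder"``
    (children, in stored order, before parent).  The visitor may read and
    write ``node.payload`` but must not alter the topology; a change to any
    parent/child link aborts the traversal with ``traversal-mutation``.
    Returns the tree itself so calls can be chained.
    """
    if order not in ("preorder", "postorder"):
        raise ValueError(f"order must be 'preorder' or 'postorder', got {order!r}")
    signature = {n.id: (n.parent, tuple(n.children)) for n in tree.nodes.values()}
    if order == "preorder":
        sequence = list(tree.preorder(skip_hidden=True))
    else:
        sequence = list(tree.postorder(skip_hidden=True))
    for node in sequence:
        visitor(node, tree)
        if (node.parent, tuple(node.children)) != signature[node.id]:
            raise TreeError("traversal-mutation")
    current = {n.id: (n.parent, tuple(n.children)) for n in tree.nodes.values()}
    if current != signature:
        raise TreeError("traversal-mutation")
    return tree


def count_leaves(tree: Tree, node_id: Optional[int] = None) -> int:
    """Number of leaf descendants of a node (a leaf counts itself as 1)."""
    node = tree[node_id if node_id is not None else tree.root]
    return sum(1 for n in tree.preorder(node.id) if n.is_leaf)


def ladderize(tree: Tree, direction: str = "ascending") -> Tree:
    """Stably reorder every node's children by subtree leaf count.

    ``ascending`` puts small subtrees first, ``descending`` large ones first.
    The clade set is unchanged; only child order moves.  Modifies the tree in
    place and returns it.
    """
    if direction not in ("ascending", "descending"):
        raise ValueError(f"direction must be 'ascending' or 'descending', got {direction!r}")
    sizes: dict[int, int] = {}
    for node in tree.postorder():
        sizes[node.id] = 1 if node.is_leaf else sum(sizes[c] for c in node.children)
    reverse = direction == "descending"
    for node in tree.nodes.values():
        if node.children:
            node.children.sort(key=lambda c: sizes[c], reverse=reverse)
    return tree


def set_collapsed(tree: Tree, node_id: int, state: bool) -> Tree:
    """Mark an internal node's subtree as collapsed (or restore it).

    Collapsing never deletes topology; layouts replace an outermost collapsed
    subtree with a single leaf slot and a boundary polygon.
    """
    node = tree[node_id]
    if node.is_leaf:
        raise TreeError("collapse-leaf")
    node.collapsed = bool(state)
    return tree


def set_hidden(tree: Tree, node_id: int, state: bool) -> Tree:
    """Remove a subtree from layout and traversal entirely (or restore it)."""
    node = tree[node_id]
    node.hidden = bool(state)
    return tree
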