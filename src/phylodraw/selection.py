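"""Multi-category branch selection with callback notification.

A selection assigns named categories (e.g. ``test`` / ``reference`` for a
selection-relaxation analysis) to branches.  Branches are identified with
their child node, so the root — which has no subtending branch — is never
selectable.  Every mutation through :meth:`SelectionState.apply` notifies the
registered callbacks exactly once, in registration order, which is the hook
other application components use to react to the current selection.

The assignment serializes to the ``hyphy_tags`` Newick dialect, the
interchange surface consumed by downstream evolutionary-analysis tools.
"""

from __future__ import annotations

import math
from typing import Callable, Optional

from . import io
from .layout import LayoutResult, branch_midpoint
from .tree import Tree

__all__ = ["SelectionState", "SelectionError", "apply_selection",
           "register_callback", "serialize_selection"]

MODES = ("branch", "clade", "path_to_root", "all_external", "all_internal",
         "near_point")
ACTIONS = ("add", "remove", "toggle")


class SelectionError(ValueError):
    pass


class SelectionState:
    """Branch -> categories assignment bound to one tree."""

    def __init__(self, tree: Tree, categories=("selected",)):
        self.tree = tree
        self.categories: list[str] = list(categories)
        self.assignment: dict[int, set] = {}
        self.callbacks: list[Callable] = []

    # -- queries ----------------------------------------------------------
    def branches(self, category: Optional[str] = None) -> set:
        """Ids of selected branches, optionally restricted to one category."""
        if category is None:
            return {i for i, cats in self.assignment.items() if cats}
        return {i for i, cats in self.assignment.items() if category in cats}

    def categories_of(self, node_id: int) -> set:
        return set(self.assignment.get(node_id, ()))

    # -- mutation ---------------------------------------------------------
    def apply(self, mode: str, anchor=None, category: Optional[str] = None,
              action: str = "add", layout: Optional[LayoutResult] = None,
              radius: Optional[float] = None) -> "SelectionState":
        """Select a set of branches and update the assignment.

        ``mode`` picks the branch set: the anchor's own subtending branch,
        its whole clade (subtree branches plus the clade's own branch), the
        path from the anchor to the root, all leaf branches, all internal
        non-root branches, or every branch whose drawn midpoint lies within
        ``radius`` of the Cartesian point ``anchor`` in ``layout`` space.
        ``action`` adds, removes or toggles ``category`` on that set; all
        callbacks fire once afterwards.
        """
        if mode not in MODES:
            raise SelectionError(f"unknown mode {mode!r}")
        if action not in ACTIONS:
            raise SelectionError(f"unknown action {action!r}")
        if category is None:
            category = self.categories[0]
        if category not in self.categories:
            raise SelectionError(f"unknown category {category!r}")

        targets = self._resolve(mode, anchor, layout, radius)
        for node_id in targets:
            cats = self.assignment.setdefault(node_id, set())
            if action == "add":
                cats.add(category)
            elif action == "remove":
                cats.discard(category)
            else:
                cats.symmetric_difference_update({category})
        self._notify()
        return self

    def _resolve(self, mode, anchor, layout, radius) -> set:
        tree = self.tree
        root = tree.root
        if mode == "branch":
            node = tree[anchor]
            if node.id == root:
                raise SelectionError("the root has no subtending branch")
            return {node.id}
        if mode == "clade":
            node = tree[anchor]
            ids = {n.id for n in tree.preorder(node.id)}
            ids.discard(root)
            return ids
        if mode == "path_to_root":
            ids = {n.id for n in tree.path_to_root(anchor)}
            ids.discard(root)
            return ids
        if mode == "all_external":
            return {n.id for n in tree.leaves() if n.id != root}
        if mode == "all_internal":
            return {n.id for n in tree.preorder()
                    if not n.is_leaf and n.id != root}
        # near_point
        if layout is None:
            raise SelectionError("near_point selection requires a layout")
        if radius is None:
            raise SelectionError("near_point selection requires a radius")
        px, py = anchor
        hits = set()
        for node_id in layout.edge_paths:
            mx, my = branch_midpoint(layout, node_id)
            if math.dist((px, py), (mx, my)) <= radius:
                hits.add(node_id)
        return hits

    def register_callback(self, fn: Callable) -> "SelectionState":
        """Append ``fn(tree, state)``; it fires once per subsequent update."""
        if not callable(fn):
            raise SelectionError("callback must be callable")
        self.callbacks.append(fn)
        return self

    def _notify(self) -> None:
        for fn in self.callbacks:
            fn(self.tree, self)

    # -- serialization ----------------------------------------------------
    def serialize(self, category_order=None, precision: int = 6) -> str:
        """Annotated-Newick string with one ``{category}`` per selected branch.

        A branch assigned several categories needs ``category_order`` (highest
        priority first) to pick its tag; without one, such a branch raises
        ``ambiguous-tag``.  Parsing the output with the ``hyphy_tags`` dialect
        reconstructs the (resolved) assignment.
        """
        annotated = self.tree.copy()
        for node in annotated.nodes.values():
            node.tags = set()
        for node_id, cats in self.assignment.items():
            if not cats:
                continue
            if len(cats) == 1:
                tag = next(iter(cats))
            else:
                if category_order is None:
                    raise SelectionError("ambiguous-tag")
                ranked = [c for c in category_order if c in cats]
                if not ranked:
                    raise SelectionError("ambiguous-tag")
                tag = ranked[0]
            annotated[node_id].tags = {tag}
        return io.write_newick(annotated, io.HYPHY_TAGS, precision=precision)

    @classmethod
    def from_tree_tags(cls, tree: Tree, categories=None) -> "SelectionState":
        """Rebuild an assignment from per-branch tags (e.g. after parsing an
        annotated Newick string)."""
        found: list[str] = []
        for node in tree.preorder():
            for tag in sorted(node.tags):
                if tag not in found:
                    found.append(tag)
        state = cls(tree, categories if categories is not None else (found or ["selected"]))
        for node in tree.preorder():
            if node.tags and node.id != tree.root:
                state.assignment[node.id] = set(node.tags)
        return state


# -- functional wrappers (thin aliases over the state methods) -------------

def apply_selection(tree: Tree, state: SelectionState, mode: str, anchor=None,
                    category: Optional[str] = None, action: str = "add",
                    layout: Optional[LayoutResult] = None,
                    radius: Optional[float] = None) -> SelectionState:
    if state.tree is not tree:
        raise SelectionError("selection state is bound to a different tree")
    return state.apply(mode, anchor, category, action, layout, radius)


def register_callback(state: SelectionState, fn: Callable) -> SelectionState:
    return state.register_callback(fn)


def serialize_selection(tree: Tree, state: SelectionState,
                        category_order=None, precision: int = 6) -> str:
    if state.tree is not tree:
        raise SelectionError("selection state is bound to a different tree")
    return state.serialize(category_order, precision=precision)
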