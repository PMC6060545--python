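"""Deterministic random-tree and tanglegram-instance generators.

Everything here is seeded, so any corpus used in tests or demonstrations is
reproducible without shipping data files.  A Yule (pure-birth) process is the
only topology model: lineages split at rate proportional to their number and
exponential waiting times accumulate into branch lengths.  That is enough for
layout/crossing correctness work, where topological and branch-length realism
beyond "a plausible binary tree" is irrelevant.
"""

from __future__ import annotations

import random

from .tanglegram import Tanglegram, match_by_label
from .tree import Tree

__all__ = ["generate_yule_tree", "scramble_orientation", "generate_tangled_pair"]


def generate_yule_tree(n_leaves: int, seed: int = 0, rate: float = 1.0) -> Tree:
    """Grow a binary tree under a pure-birth process.

    Starting from two lineages, a uniformly chosen extant lineage splits at
    each event; inter-event times are exponential with total rate
    ``rate * n_extant`` and accrue onto every extant pendant branch.  Leaves
    are labelled ``L1..Ln`` in final depth-first order.  The same seed always
    yields the same tree.
    """
    if n_leaves < 2:
        raise ValueError("a Yule tree needs at least 2 leaves")
    if rate <= 0:
        raise ValueError("rate must be positive")
    rng = random.Random(seed)
    tree = Tree(name=f"yule-{n_leaves}-{seed}")
    root = tree.add_node()
    extant = [tree.add_node(parent=root.id, length=0.0),
              tree.add_node(parent=root.id, length=0.0)]

    def advance():
        dt = rng.expovariate(rate * len(extant))
        for node in extant:
            node.length += dt

    while len(extant) < n_leaves:
        advance()
        parent = extant.pop(rng.randrange(len(extant)))
        extant.append(tree.add_node(parent=parent.id, length=0.0))
        extant.append(tree.add_node(parent=parent.id, length=0.0))
    advance()                           # pendant time after the last split

    for k, leaf in enumerate(tree.leaves(), start=1):
        leaf.label = f"L{k}"
    tree.validate()
    return tree


def scramble_orientation(tree: Tree, seed: int = 0) -> Tree:
    """Return a copy in which each internal node's child order is reversed
    independently with probability 1/2.  The clade set is unchanged."""
    rng = random.Random(seed)
    dup = tree.copy()
    for node in dup.preorder():
        if node.children and rng.random() < 0.5:
            node.children.reverse()
    return dup


def generate_tangled_pair(n_leaves: int, seed: int = 0,
                          n_leaf_swaps: int = 0) -> Tanglegram:
    """A two-tree instance for crossing-minimization work.

    The left tree is a Yule tree; the right tree is a copy whose leaf labels
    are perturbed by ``n_leaf_swaps`` random pairwise swaps and whose child
    orders are scrambled.  The matching is the identity on leaf labels, so
    with zero swaps the trees are identical up to orientation and the optimal
    crossing count is 0.
    """
    if n_leaves < 3:
        raise ValueError("a tangled pair needs at least 3 leaves")
    rng = random.Random(seed)
    left = generate_yule_tree(n_leaves, seed=rng.randrange(1 << 30))
    right = left.copy()
    right.name = left.name + "-tangled"
    leaves = right.leaves()
    for _ in range(n_leaf_swaps):
        a, b = rng.sample(range(len(leaves)), 2)
        leaves[a].label, leaves[b].label = leaves[b].label, leaves[a].label
    right = scramble_orientation(right, seed=rng.randrange(1 << 30))
    return Tanglegram(left=left, right=right,
                      matching=match_by_label(left, right))
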