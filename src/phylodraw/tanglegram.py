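"""Tanglegrams: two trees side by side with leaf-to-leaf links.

The crossing number of the links measures discordance between the trees, but
it depends on each internal node's child order — which is free, since
reordering children does not change the topology.  This module counts
crossings under a given orientation and minimizes them over child orders.

Orientation is kept separate from the trees: a per-side map
``node id -> child-order permutation`` overrides the stored order, so the
underlying trees are never mutated.

Minimization with one side fixed is solved exactly by a bottom-up dynamic
program.  The key fact: for two links attached to different child blocks of a
free node, whether they cross depends only on which block each link's leaf is
in and on the fixed-side ranks — not on any ordering decision made deeper in
either block.  Inter-block crossing costs are therefore additive over nodes,
and choosing the cheapest child order independently at every free node is
globally optimal.  A brute-force enumerator over the full orientation space
serves as the independent oracle in tests.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional

from .tree import Tree, TreeError

__all__ = ["Tanglegram", "count_crossings", "minimize_crossings",
           "brute_force_min_crossings", "read_matching", "match_by_label"]

DEGREE_CAP = 8            # max children of a free node the DP will permute
BRUTE_FORCE_LIMIT = 1 << 20
EXACT_BOTH_LIMIT = 1 << 12  # two-sided instances this small are solved exactly


@dataclass
class Tanglegram:
    left: Tree
    right: Tree
    matching: list = field(default_factory=list)        # [(left id, right id)]
    orientation: dict = field(default_factory=lambda: {"left": {}, "right": {}})

    def validate(self) -> None:
        self.left.validate()
        self.right.validate()
        left_leaves = {n.id for n in self.left.leaves()}
        right_leaves = {n.id for n in self.right.leaves()}
        for a, b in self.matching:
            if a not in left_leaves or b not in right_leaves:
                raise TreeError(f"matching pair ({a}, {b}) is not a leaf pair")
        for side, tree in (("left", self.left), ("right", self.right)):
            for node_id, order in self.orientation.get(side, {}).items():
                if sorted(order) != sorted(tree[node_id].children):
                    raise TreeError(
                        f"orientation at {side} node {node_id} is not a "
                        "permutation of its children")

    def copy(self) -> "Tanglegram":
        return Tanglegram(
            left=self.left, right=self.right, matching=list(self.matching),
            orientation={"left": dict(self.orientation.get("left", {})),
                         "right": dict(self.orientation.get("right", {}))})

    def leaf_ranks(self, side: str) -> dict:
        """Leaf id -> 0-based rank in depth-first order under the current
        orientation of that side."""
        tree = self.left if side == "left" else self.right
        overrides = self.orientation.get(side, {})
        ranks: dict[int, int] = {}
        stack = [tree.root]
        while stack:
            node = tree[stack.pop()]
            if node.is_leaf:
                ranks[node.id] = len(ranks)
            else:
                order = overrides.get(node.id, node.children)
                stack.extend(reversed(list(order)))
        return ranks


def read_matching(text: str, left: Tree, right: Tree) -> list:
    """Parse a two-column tab-separated leaf-label matching file.

    Blank lines and ``#`` comments are skipped; unmatched leaves are allowed.
    """
    by_label_l = {n.label: n.id for n in left.leaves()}
    by_label_r = {n.label: n.id for n in right.leaves()}
    matching = []
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) != 2:
            raise ValueError(f"matching line {lineno}: expected two columns")
        a, b = parts
        if a not in by_label_l:
            raise ValueError(f"matching line {lineno}: unknown left leaf {a!r}")
        if b not in by_label_r:
            raise ValueError(f"matching line {lineno}: unknown right leaf {b!r}")
        matching.append((by_label_l[a], by_label_r[b]))
    return matching


def match_by_label(left: Tree, right: Tree) -> list:
    """Identity matching on leaf labels (shared labels only)."""
    by_label_r = {n.label: n.id for n in right.leaves()}
    return [(n.id, by_label_r[n.label]) for n in left.leaves()
            if n.label in by_label_r]


def count_crossings(tg: Tanglegram) -> int:
    """Number of crossing link pairs under the current orientations.

    Links are rank pairs; two links cross iff their left ranks and right
    ranks are oppositely ordered.  Links sharing an endpoint never cross.
    """
    left_rank = tg.leaf_ranks("left")
    right_rank = tg.leaf_ranks("right")
    links = [(left_rank[a], right_rank[b]) for a, b in tg.matching]
    crossings = 0
    for (a, b), (c, d) in itertools.combinations(links, 2):
        if (a - c) * (b - d) < 0:
            crossings += 1
    return crossings


def _inter_block_cost(block_links: list) -> tuple:
    """Crossings between links of consecutive child blocks, for the block
    order as given vs fully reversed.

    ``block_links`` is a list per child block of the fixed-side ranks of the
    links attached to leaves inside that block.  Returns (cost_forward,
    cost_reversed) summed over all block pairs; equal ranks (shared fixed
    endpoint) cross in neither order.
    """
    forward = 0
    backward = 0
    for i, j in itertools.combinations(range(len(block_links)), 2):
        up = sum(1 for x in block_links[i] for y in block_links[j] if x > y)
        down = sum(1 for x in block_links[i] for y in block_links[j] if x < y)
        forward += up      # block i drawn before block j: inverted pairs cross
        backward += down
    return forward, backward


def _optimize_side(tg: Tanglegram, free: str) -> Tanglegram:
    """Exact one-sided pass: choose every free node's child order bottom-up."""
    fixed = "left" if free == "right" else "right"
    fixed_rank = tg.leaf_ranks(fixed)
    free_tree = tg.left if free == "left" else tg.right

    links_from = {}                      # free leaf id -> fixed-side ranks
    if free == "right":
        for a, b in tg.matching:
            links_from.setdefault(b, []).append(fixed_rank[a])
    else:
        for a, b in tg.matching:
            links_from.setdefault(a, []).append(fixed_rank[b])

    result = tg.copy()
    overrides = result.orientation[free]
    subtree_ranks: dict[int, list] = {}
    for node in free_tree.postorder():
        if node.is_leaf:
            subtree_ranks[node.id] = sorted(links_from.get(node.id, []))
            continue
        order = list(overrides.get(node.id, node.children))
        blocks = [subtree_ranks[c] for c in order]
        if len(order) == 2:
            fwd, bwd = _inter_block_cost(blocks)
            if bwd < fwd:                # ties keep the input orientation
                order = order[::-1]
        elif len(order) > 2:
            if len(order) > DEGREE_CAP:
                raise TreeError("degree-cap")
            best = None
            for perm in itertools.permutations(range(len(order))):
                cost, _ = _inter_block_cost([blocks[i] for i in perm])
                key = (cost, perm)       # deterministic, input order wins ties
                if best is None or key < best[0]:
                    best = (key, perm)
            order = [order[i] for i in best[1]]
        overrides[node.id] = list(order)
        merged: list = []
        for child in order:
            merged.extend(subtree_ranks[child])
        subtree_ranks[node.id] = sorted(merged)
    return result


def minimize_crossings(tg: Tanglegram, free_side: str = "right"):
    """Minimize link crossings over child orders of the free side(s).

    ``free_side="right"`` holds the left tree fixed and returns the exact
    optimum over all child-order permutations of the right tree.  With
    ``"both"``, one-sided passes alternate until the crossing count stops
    improving — a heuristic for the (harder) two-sided problem, which can
    stall on per-node ties; instances whose full orientation space is small
    are therefore finished off by exhaustive enumeration.  Returns
    ``(tanglegram with optimized orientations, crossing count)``.
    """
    if free_side not in ("right", "both"):
        raise ValueError(f"free_side must be 'right' or 'both', got {free_side!r}")
    tg.validate()
    if free_side == "right":
        best = _optimize_side(tg, "right")
        return best, count_crossings(best)
    current, score = tg.copy(), count_crossings(tg)
    for _ in range(16):                  # alternate until a fixed point
        improved = False
        for side in ("right", "left"):
            candidate = _optimize_side(current, side)
            candidate_score = count_crossings(candidate)
            if candidate_score < score:
                current, score = candidate, candidate_score
                improved = True
        if not improved:
            break
    if score > 0 and _search_space(tg, "both") <= EXACT_BOTH_LIMIT:
        exact, exact_score = _enumerate_best(tg, "both")
        if exact_score < score:
            current, score = exact, exact_score
    return current, score


def _free_internal_nodes(tg: Tanglegram, free_side: str) -> list:
    sides = ("right",) if free_side == "right" else ("left", "right")
    out = []
    for side in sides:
        tree = tg.left if side == "left" else tg.right
        for node in tree.preorder():
            if not node.is_leaf:
                out.append((side, node.id, len(node.children)))
    return out


def _search_space(tg: Tanglegram, free_side: str) -> int:
    space = 1
    for _, _, degree in _free_internal_nodes(tg, free_side):
        for k in range(2, degree + 1):
            space *= k
        if space > BRUTE_FORCE_LIMIT:
            return space
    return space


def _enumerate_best(tg: Tanglegram, free_side: str):
    """Exhaustive search over every orientation assignment of the free side(s);
    returns (best tanglegram, minimum crossings)."""
    free_nodes = _free_internal_nodes(tg, free_side)
    per_node_orders = []
    for side, node_id, _ in free_nodes:
        tree = tg.left if side == "left" else tg.right
        per_node_orders.append([list(p) for p in
                                itertools.permutations(tree[node_id].children)])
    best = (tg.copy(), count_crossings(tg))
    for combo in itertools.product(*per_node_orders):
        candidate = tg.copy()
        for (side, node_id, _), order in zip(free_nodes, combo):
            candidate.orientation[side][node_id] = order
        crossings = count_crossings(candidate)
        if crossings < best[1]:
            best = (candidate, crossings)
    return best


def brute_force_min_crossings(tg: Tanglegram, free_side: str = "right") -> int:
    """Exact minimum by enumerating every orientation assignment.

    Test oracle: refuses more than 16 free internal nodes or a search space
    beyond 2**20 assignments.
    """
    tg.validate()
    if len(_free_internal_nodes(tg, free_side)) > 16 or \
            _search_space(tg, free_side) > BRUTE_FORCE_LIMIT:
        raise TreeError("brute-force search space too large")
    return _enumerate_best(tg, free_side)[1]
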