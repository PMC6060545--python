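"""Rectangular and radial tree layouts.

Conventions (fixed and relied on by the renderer and tests):

* rectangular coordinates are ``(x, y)`` with the root at ``x = 0`` and ``y``
  growing downward; visible leaves sit at ``y = 0, s, 2s, ...`` in depth-first
  child order and every internal node at the arithmetic mean of its children's
  ``y``;
* radial coordinates are ``(radius, angle)`` with angles in radians growing
  counter-clockwise from the positive x-axis; ``n`` visible leaves get the
  uniform angles ``2*pi*k/n``;
* ``phylogram`` scaling maps cumulative branch length from the root onto
  ``[0, width]`` (a missing length counts as 0, with a warning);
  ``cladogram`` scaling places internal nodes by node depth and pins every
  leaf to the full width/radius;
* a subtree whose root is collapsed (outermost such node only) occupies
  exactly one leaf slot; a hidden subtree occupies none.

Edge paths are axis-parallel elbows in rectangular mode (vertical drop at the
parent's x, then horizontal to the child) and an arc at the parent's radius
followed by an outward radial segment in radial mode.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

from .tree import Tree, TreeError

__all__ = ["LayoutResult", "layout_rectangular", "layout_radial",
           "collapsed_boundary", "branch_midpoint"]


@dataclass
class LayoutResult:
    mode: str                      # rectangular | radial
    scale_mode: str                # phylogram | cladogram
    coordinates: dict = field(default_factory=dict)   # id -> (x, y) | (r, theta)
    edge_paths: dict = field(default_factory=dict)    # child id -> path dict
    collapsed_boundaries: dict = field(default_factory=dict)  # id -> [(x, y), ...]
    extents: tuple = ((0.0, 0.0), (0.0, 0.0))         # ((xmin, ymin), (xmax, ymax))

    def cartesian(self, node_id: int) -> tuple:
        """Coordinates of a node in Cartesian space (radial ones converted)."""
        if self.mode == "radial":
            r, theta = self.coordinates[node_id]
            return (r * math.cos(theta), r * math.sin(theta))
        return self.coordinates[node_id]


def _visible_nodes(tree: Tree):
    """Walk the layout-visible part of the tree.

    Yields ``(node, is_slot)`` in depth-first order, where ``is_slot`` marks
    nodes that occupy a leaf slot: true leaves and outermost collapsed nodes.
    Hidden subtrees are skipped entirely; the interior of a collapsed subtree
    is not descended into.
    """
    if tree.root is None:
        return
    stack = [tree.root]
    while stack:
        node = tree[stack.pop()]
        if node.hidden:
            continue
        visible_children = [c for c in node.children if not tree[c].hidden]
        if node.collapsed or not visible_children:
            yield node, True
        else:
            yield node, False
            stack.extend(reversed(visible_children))


def _depths_and_distances(tree: Tree, visible: list):
    depth = {}
    dist = {}
    missing = False
    for node, _ in visible:
        if node.parent is None or node.parent not in depth:
            depth[node.id] = 0
            dist[node.id] = 0.0
        else:
            depth[node.id] = depth[node.parent] + 1
            length = node.length
            if length is None:
                missing = True
                length = 0.0
            dist[node.id] = dist[node.parent] + length
    return depth, dist, missing


def _axis_positions(tree: Tree, scale_mode: str, span: float):
    """Shared core: leaf slot index + radial/x axis position per visible node.

    Returns (slots, axis, parents) where ``slots`` maps node id -> leaf slot
    ordinate (0, 1, 2, ... for slots; children's mean for internal nodes) and
    ``axis`` maps node id -> root-distance coordinate scaled to ``span``.
    """
    visible = list(_visible_nodes(tree))
    if not visible:
        raise TreeError("no visible nodes to lay out")
    depth, dist, missing = _depths_and_distances(tree, visible)
    if scale_mode == "phylogram" and missing:
        warnings.warn("phylogram layout: missing branch lengths treated as 0",
                      stacklevel=3)

    slots: dict[int, float] = {}
    next_slot = 0
    for node, is_slot in visible:
        if is_slot:
            slots[node.id] = float(next_slot)
            next_slot += 1
    # internal slot ordinate = mean of visible children's, bottom-up
    for node, is_slot in reversed(visible):
        if not is_slot:
            vals = [slots[c] for c in node.children if c in slots]
            slots[node.id] = sum(vals) / len(vals)

    axis: dict[int, float] = {}
    if scale_mode == "phylogram":
        max_dist = max(dist.values()) or 1.0
        for node, _ in visible:
            axis[node.id] = dist[node.id] / max_dist * span
    else:
        max_depth = max(depth.values()) or 1
        for node, is_slot in visible:
            axis[node.id] = span if is_slot else depth[node.id] / max_depth * span
    return visible, slots, axis, next_slot


def layout_rectangular(tree: Tree, scale_mode: str = "phylogram",
                       leaf_spacing: float = 20.0,
                       width: float = 400.0) -> LayoutResult:
    """Left-to-right rectangular layout (phylogram or cladogram)."""
    if scale_mode not in ("phylogram", "cladogram"):
        raise ValueError(f"unknown scale_mode {scale_mode!r}")
    if width <= 0 or leaf_spacing <= 0:
        raise ValueError("width and leaf_spacing must be positive")
    tree.validate()
    visible, slots, axis, _ = _axis_positions(tree, scale_mode, width)

    result = LayoutResult(mode="rectangular", scale_mode=scale_mode)
    for node, _ in visible:
        result.coordinates[node.id] = (axis[node.id], slots[node.id] * leaf_spacing)
    for node, _ in visible:
        if node.parent is None or node.parent not in result.coordinates:
            continue
        px, py = result.coordinates[node.parent]
        cx, cy = result.coordinates[node.id]
        result.edge_paths[node.id] = {
            "type": "elbow",
            "points": [(px, py), (px, cy), (cx, cy)],
        }
    for node, is_slot in visible:
        if node.collapsed and is_slot:
            result.collapsed_boundaries[node.id] = collapsed_boundary_points(
                tree, result, node.id)
    xs = [p[0] for p in result.coordinates.values()]
    ys = [p[1] for p in result.coordinates.values()]
    result.extents = ((min(xs), min(ys)), (max(xs), max(ys)))
    return result


def layout_radial(tree: Tree, scale_mode: str = "phylogram",
                  radius: float = 200.0) -> LayoutResult:
    """Radial layout: uniform leaf angles, radius per the scale mode."""
    if scale_mode not in ("phylogram", "cladogram"):
        raise ValueError(f"unknown scale_mode {scale_mode!r}")
    if radius <= 0:
        raise ValueError("radius must be positive")
    tree.validate()
    visible, slots, axis, n_slots = _axis_positions(tree, scale_mode, radius)

    result = LayoutResult(mode="radial", scale_mode=scale_mode)
    step = 2.0 * math.pi / n_slots
    for node, _ in visible:
        result.coordinates[node.id] = (axis[node.id], slots[node.id] * step)
    for node, _ in visible:
        if node.parent is None or node.parent not in result.coordinates:
            continue
        pr, pa = result.coordinates[node.parent]
        cr, ca = result.coordinates[node.id]
        result.edge_paths[node.id] = {
            "type": "arc_radial",
            "arc_radius": pr,
            "angle_from": pa,
            "angle_to": ca,
            "outer_radius": cr,
        }
    for node, is_slot in visible:
        if node.collapsed and is_slot:
            result.collapsed_boundaries[node.id] = collapsed_boundary_points(
                tree, result, node.id)
    pts = [result.cartesian(i) for i in result.coordinates]
    xs = [p[0] for p in pts]
    ys = [p[1] for p in pts]
    result.extents = ((min(xs), min(ys)), (max(xs), max(ys)))
    return result


def branch_midpoint(layout: LayoutResult, node_id: int) -> tuple:
    """Cartesian midpoint of a branch's drawn path (used by near-point
    selection): the middle of the horizontal run for rectangular elbows, the
    middle of the outward radial segment for radial edges."""
    path = layout.edge_paths[node_id]
    if path["type"] == "elbow":
        (_, _), (x1, y1), (x2, y2) = path["points"]
        return ((x1 + x2) / 2.0, (y1 + y2) / 2.0)
    theta = path["angle_to"]
    r = (path["arc_radius"] + path["outer_radius"]) / 2.0
    return (r * math.cos(theta), r * math.sin(theta))


# ---------------------------------------------------------------------------
# collapsed-clade boundaries
# ---------------------------------------------------------------------------

def _convex_hull(points: list) -> list:
    """Andrew's monotone chain; returns hull vertices counter-clockwise."""
    pts = sorted(set(points))
    if len(pts) <= 2:
        return pts

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    lower: list = []
    for p in pts:
        while len(lower) >= 2 and cross(lower[-2], lower[-1], p) <= 0:
            lower.pop()
        lower.append(p)
    upper: list = []
    for p in reversed(pts):
        while len(upper) >= 2 and cross(upper[-2], upper[-1], p) <= 0:
            upper.pop()
        upper.append(p)
    return lower[:-1] + upper[:-1]


def _catmull_rom(control: list, samples_per_segment: int) -> list:
    """Closed centripetal Catmull-Rom curve through the control points."""
    n = len(control)
    if n < 3 or samples_per_segment < 1:
        return list(control)
    out = []
    for i in range(n):
        p0, p1, p2, p3 = (control[(i - 1) % n], control[i],
                          control[(i + 1) % n], control[(i + 2) % n])

        def t_next(t, a, b):
            d = math.dist(a, b) ** 0.5      # centripetal: sqrt of chord length
            return t + (d if d > 0 else 1e-9)
        t0 = 0.0
        t1 = t_next(t0, p0, p1)
        t2 = t_next(t1, p1, p2)
        t3 = t_next(t2, p2, p3)
        for k in range(samples_per_segment):
            t = t1 + (t2 - t1) * k / samples_per_segment
            def lerp(pa, pb, ta, tb):
                if tb == ta:
                    return pa
                w = (t - ta) / (tb - ta)
                return (pa[0] + (pb[0] - pa[0]) * w, pa[1] + (pb[1] - pa[1]) * w)
            a1 = lerp(p0, p1, t0, t1)
            a2 = lerp(p1, p2, t1, t2)
            a3 = lerp(p2, p3, t2, t3)
            b1 = lerp(a1, a2, t0, t2)
            b2 = lerp(a2, a3, t1, t3)
            out.append(lerp(b1, b2, t1, t2))
    return out


def _phantom_subtree_points(tree: Tree, layout: LayoutResult, node_id: int) -> list:
    """Cartesian positions the collapsed subtree's leaves would occupy.

    The subtree is laid out as if expanded, anchored at the collapsed node's
    own position, reusing the surrounding layout's scale (leaf spacing /
    angular step and axis units) so the glyph is proportionate.
    """
    sub_leaves = [n for n in tree.preorder(node_id) if n.is_leaf and not n.hidden]
    anchor = layout.cartesian(node_id)
    if not sub_leaves:
        return [anchor]

    # depth of each subtree leaf below the collapsed node: cumulative branch
    # length in phylogram mode, node depth otherwise (or if lengths are absent)
    dist = {node_id: 0.0}
    for node in tree.preorder(node_id):
        if node.id == node_id:
            continue
        dist[node.id] = dist[node.parent] + (node.length or 0.0)
    if layout.scale_mode != "phylogram" or not any(dist.values()):
        dist = {node_id: 0.0}
        for node in tree.preorder(node_id):
            if node.id != node_id:
                dist[node.id] = dist[node.parent] + 1.0
    max_dist = max(dist[l.id] for l in sub_leaves) or 1.0

    if layout.mode == "rectangular":
        ys = sorted(layout.coordinates[i][1] for i in layout.coordinates)
        spacing = min((b - a for a, b in zip(ys, ys[1:]) if b > a), default=20.0)
        depth_scale = spacing * 2.0
        ax, ay = anchor
        pts = [anchor]
        for k, leaf in enumerate(sub_leaves):
            offset = (k - (len(sub_leaves) - 1) / 2.0) * spacing
            pts.append((ax + dist[leaf.id] / max_dist * depth_scale, ay + offset))
        return pts
    # radial: fan the leaves within one angular step around the anchor angle
    r0, theta0 = layout.coordinates[node_id]
    n_slots = max(len([1 for i in layout.coordinates]), 2)
    step = 2.0 * math.pi / n_slots
    pts = [anchor]
    for k, leaf in enumerate(sub_leaves):
        dtheta = (k / max(len(sub_leaves) - 1, 1) - 0.5) * step
        r = r0 + dist[leaf.id] / max_dist * r0 * 0.25 if r0 else dist[leaf.id]
        pts.append((r * math.cos(theta0 + dtheta), r * math.sin(theta0 + dtheta)))
    return pts


def collapsed_boundary_points(tree: Tree, layout: LayoutResult,
                              node_id: int, samples: int = 8) -> list:
    """Closed boundary polygon of a collapsed clade (list of (x, y)).

    Control points are the clade's attachment point plus the hull of the
    positions its leaves would occupy if expanded; a closed centripetal
    Catmull-Rom curve through them is sampled, and the returned polygon is the
    convex closure of samples and control points, which guarantees every
    subtree leaf position lies inside or on the polygon.
    """
    node = tree[node_id]
    if not node.collapsed:
        raise TreeError(f"node {node_id} is not collapsed")
    pts = _phantom_subtree_points(tree, layout, node_id)
    hull = _convex_hull(pts)
    if len(hull) < 3:                   # degenerate: pad to a sliver triangle
        (x0, y0) = hull[0]
        (x1, y1) = hull[-1]
        dx, dy = x1 - x0, y1 - y0
        norm = math.hypot(dx, dy)
        if norm == 0:
            dx, dy, norm = 1.0, 0.0, 1.0
        eps = 1e-6 + 0.01 * norm
        # offset perpendicular to the segment so the triangle has area
        hull = [(x0, y0), (x1, y1),
                ((x0 + x1) / 2 - dy / norm * eps, (y0 + y1) / 2 + dx / norm * eps)]
    # densify with edge midpoints: the interpolating spline then hugs the
    # hull instead of ballooning past sharp corners
    control = []
    for i, p in enumerate(hull):
        q = hull[(i + 1) % len(hull)]
        control.append(p)
        control.append(((p[0] + q[0]) / 2, (p[1] + q[1]) / 2))
    curve = _catmull_rom(control, max(samples, 1))
    return _convex_hull(hull + curve)


def collapsed_boundary(tree: Tree, layout: LayoutResult, node_id: int,
                       samples: int = 8) -> list:
    """Public alias of :func:`collapsed_boundary_points`."""
    return collapsed_boundary_points(tree, layout, node_id, samples)
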