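"""Rectangular/radial layout conventions and collapsed-clade boundaries.

Geometric assertions (containment, areas) are cross-checked against shapely,
which the layout code itself does not use.
"""

import math
import statistics

import pytest
from shapely.geometry import Point, Polygon

from phylodraw import (collapsed_boundary, generate_yule_tree, ladderize,
                       layout_radial, layout_rectangular, parse_newick,
                       set_collapsed, set_hidden)


class TestRectangular:
    def test_two_leaf_phylogram_conventions(self):
        tree = parse_newick("(A:1,B:1);")
        lay = layout_rectangular(tree, "phylogram", leaf_spacing=1.0, width=1.0)
        coords = {tree[i].label: xy for i, xy in lay.coordinates.items()}
        assert coords["A"] == (1.0, 0.0)
        assert coords["B"] == (1.0, 1.0)
        assert coords[""] == (0.0, 0.5)

    def test_cladogram_pins_leaves_to_width(self, three_leaf):
        lay = layout_rectangular(three_leaf, "cladogram", 1.0, 1.0)
        xs = [lay.coordinates[l.id][0] for l in three_leaf.leaves()]
        assert xs == [1.0, 1.0, 1.0]
        assert statistics.pvariance(xs) == 0.0

    def test_internal_y_is_mean_and_within_range(self, yule_corpus):
        for tree in yule_corpus[:8]:
            lay = layout_rectangular(tree)
            for node in tree.nodes.values():
                if node.is_leaf:
                    continue
                ys = [lay.coordinates[c][1] for c in node.children]
                y = lay.coordinates[node.id][1]
                assert y == pytest.approx(sum(ys) / len(ys))
                assert min(ys) <= y <= max(ys)

    def test_phylogram_x_monotone_root_to_leaf(self, yule_corpus):
        for tree in yule_corpus[:8]:
            lay = layout_rectangular(tree, "phylogram")
            for node in tree.nodes.values():
                if node.parent is not None:
                    assert (lay.coordinates[node.id][0]
                            >= lay.coordinates[node.parent][0])

    def test_leaf_ys_distinct_and_uniform(self):
        tree = generate_yule_tree(17, seed=4)
        lay = layout_rectangular(tree, leaf_spacing=20.0)
        ys = sorted(lay.coordinates[l.id][1] for l in tree.leaves())
        assert len(set(ys)) == 17
        assert ys == [20.0 * k for k in range(17)]

    def test_ladderize_permutes_leaf_rows_only(self):
        tree = generate_yule_tree(20, seed=9)
        before = layout_rectangular(tree)
        ladderize(tree, "ascending")
        after = layout_rectangular(tree)
        ys = lambda lay: sorted(lay.coordinates[l.id][1] for l in tree.leaves())
        assert ys(before) == ys(after)
        assert before.extents == after.extents

    def test_missing_length_warns_in_phylogram(self, three_leaf):
        with pytest.warns(UserWarning, match="missing branch lengths"):
            layout_rectangular(three_leaf, "phylogram")

    def test_bad_parameters(self, three_leaf):
        with pytest.raises(ValueError):
            layout_rectangular(three_leaf, "cladogram", width=-1.0)
        with pytest.raises(ValueError):
            layout_rectangular(three_leaf, "cladogram", leaf_spacing=0.0)
        with pytest.raises(ValueError):
            layout_rectangular(three_leaf, "freeform")


class TestRadial:
    def test_uniform_leaf_angles(self, balanced_four):
        lay = layout_radial(balanced_four, "cladogram")
        angles = sorted(lay.coordinates[l.id][1]
                        for l in balanced_four.leaves())
        assert angles == pytest.approx([0.0, math.pi / 2, math.pi,
                                        3 * math.pi / 2])

    def test_two_leaf_phylogram_radius(self):
        tree = parse_newick("(A:1,B:1);")
        lay = layout_radial(tree, "phylogram", radius=1.0)
        for leaf in tree.leaves():
            assert lay.coordinates[leaf.id][0] == pytest.approx(1.0)

    def test_root_angle_is_mean_of_children(self, balanced_four):
        lay = layout_radial(balanced_four, "cladogram")
        child_angles = [lay.coordinates[c][1]
                        for c in balanced_four.root_node.children]
        assert lay.coordinates[balanced_four.root][1] == pytest.approx(
            sum(child_angles) / 2)

    def test_angle_gaps_sum_to_two_pi(self, yule_corpus):
        for tree in yule_corpus[:6]:
            lay = layout_radial(tree, "cladogram")
            angles = sorted(lay.coordinates[l.id][1] for l in tree.leaves())
            assert all(0 <= a < 2 * math.pi for a in angles)
            assert len(set(angles)) == len(angles)
            gaps = [b - a for a, b in zip(angles, angles[1:])]
            gaps.append(2 * math.pi - angles[-1] + angles[0])
            assert sum(gaps) == pytest.approx(2 * math.pi)

    def test_cladogram_leaf_radius_variance_zero(self, yule_corpus):
        tree = yule_corpus[0]
        lay = layout_radial(tree, "cladogram")
        radii = [lay.coordinates[l.id][0] for l in tree.leaves()]
        assert statistics.pvariance(radii) == pytest.approx(0.0)


class TestCollapsedAndHidden:
    def test_collapsed_clade_uses_one_slot(self, three_leaf):
        clade = three_leaf.find("A").parent
        set_collapsed(three_leaf, clade, True)
        lay = layout_rectangular(three_leaf, "cladogram", 10.0, 100.0)
        # visible slots: the collapsed placeholder and C
        slot_ys = sorted(lay.coordinates[i][1]
                         for i in (clade, three_leaf.find("C").id))
        assert slot_ys == [0.0, 10.0]
        assert three_leaf.find("A").id not in lay.coordinates

    def test_hidden_subtree_contributes_nothing(self, three_leaf):
        clade = three_leaf.find("A").parent
        set_hidden(three_leaf, clade, True)
        lay = layout_rectangular(three_leaf, "cladogram", 10.0, 100.0)
        assert clade not in lay.coordinates
        assert len(lay.coordinates) == 2       # root + C

    def test_nested_collapse_honors_outermost(self):
        tree = parse_newick("(((A,B)X,C)Y,D);")
        set_collapsed(tree, tree.find("X").id, True)
        set_collapsed(tree, tree.find("Y").id, True)
        lay = layout_rectangular(tree, "cladogram", 10.0, 100.0)
        assert tree.find("Y").id in lay.coordinates
        assert tree.find("X").id not in lay.coordinates
        assert tree.find("Y").id in lay.collapsed_boundaries
        assert tree.find("X").id not in lay.collapsed_boundaries

    def test_two_leaf_boundary_is_polygonal(self, three_leaf):
        clade = three_leaf.find("A").parent
        set_collapsed(three_leaf, clade, True)
        lay = layout_rectangular(three_leaf, "cladogram", 10.0, 100.0)
        polygon = collapsed_boundary(three_leaf, lay, clade, samples=4)
        assert len(polygon) >= 3
        assert Polygon(polygon).area > 0

    def test_boundary_contains_all_subtree_leaves(self):
        """Hull-oracle containment: every phantom leaf position of a 10-leaf
        collapsed clade lies in the reported polygon."""
        from phylodraw.layout import _phantom_subtree_points
        tree = generate_yule_tree(14, seed=11)
        clade = max((n for n in tree.nodes.values() if not n.is_leaf
                     and n.id != tree.root),
                    key=lambda n: len(tree.leaves(n.id)))
        set_collapsed(tree, clade.id, True)
        for make in (layout_rectangular, lambda t: layout_radial(t)):
            lay = make(tree)
            polygon = Polygon(collapsed_boundary(tree, lay, clade.id, samples=12))
            pts = _phantom_subtree_points(tree, lay, clade.id)
            for pt in pts:
                assert polygon.buffer(1e-6).contains(Point(pt))

    def test_boundary_area_approaches_hull(self):
        tree = generate_yule_tree(10, seed=2)
        clade = tree[tree.find("L1").parent]
        while clade.parent is not None and clade.parent != tree.root:
            clade = tree[clade.parent]
        set_collapsed(tree, clade.id, True)
        lay = layout_rectangular(tree)
        coarse = Polygon(collapsed_boundary(tree, lay, clade.id, samples=3))
        fine = Polygon(collapsed_boundary(tree, lay, clade.id, samples=50))
        from phylodraw.layout import _convex_hull, _phantom_subtree_points
        hull = Polygon(_convex_hull(_phantom_subtree_points(tree, lay, clade.id)))
        assert fine.area >= coarse.area - 1e-9
        assert fine.area >= hull.area - 1e-9
        assert fine.area <= hull.area * 1.25   # spline overshoot stays modest

    def test_boundary_requires_collapsed_node(self, three_leaf):
        lay = layout_rectangular(three_leaf, "cladogram", 10.0, 100.0)
        from phylodraw import TreeError
        with pytest.raises(TreeError):
            collapsed_boundary(three_leaf, lay, three_leaf.find("A").parent)
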