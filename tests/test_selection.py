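"""Branch-selection mechanics, callbacks and annotated-Newick round-trips."""

import random

import pytest

from phylodraw import (HYPHY_TAGS, SelectionError, SelectionState,
                       apply_selection, generate_yule_tree, layout_rectangular,
                       parse_newick, register_callback, serialize_selection)


@pytest.fixture
def state(three_leaf):
    return SelectionState(three_leaf, categories=["test", "reference"])


class TestModes:
    def test_clade_includes_own_branch(self, three_leaf, state):
        clade = three_leaf.find("A").parent
        state.apply("clade", anchor=clade, category="test")
        expected = {clade, three_leaf.find("A").id, three_leaf.find("B").id}
        assert state.branches("test") == expected

    def test_branch_and_path_to_root(self, three_leaf, state):
        a = three_leaf.find("A").id
        state.apply("branch", anchor=a, category="test")
        assert state.branches() == {a}
        state.apply("path_to_root", anchor=a, category="reference")
        # A and its parent; the root has no subtending branch
        assert state.branches("reference") == {a, three_leaf.find("A").parent}

    def test_root_branch_is_unselectable(self, three_leaf, state):
        with pytest.raises(SelectionError):
            state.apply("branch", anchor=three_leaf.root)
        state.apply("clade", anchor=three_leaf.root, category="test")
        assert three_leaf.root not in state.branches()
        assert len(state.branches()) == len(three_leaf) - 1

    def test_external_internal_partition(self):
        tree = generate_yule_tree(10, seed=1)
        state = SelectionState(tree, ["test"])
        state.apply("all_external", category="test")
        assert len(state.branches()) == 10
        state = SelectionState(tree, ["test"])
        state.apply("all_internal", category="test")
        # 19 nodes: 10 leaves, 9 internal, minus the root
        assert len(state.branches()) == 8

    def test_clade_selection_size_matches_subtree(self):
        tree = generate_yule_tree(12, seed=7)
        state = SelectionState(tree, ["test"])
        internal = next(n for n in tree.preorder()
                        if not n.is_leaf and n.id != tree.root)
        state.apply("clade", anchor=internal.id, category="test")
        assert len(state.branches()) == sum(
            1 for _ in tree.preorder(internal.id))

    def test_near_point(self, three_leaf, state):
        layout = layout_rectangular(three_leaf, "cladogram", 10.0, 100.0)
        from phylodraw import branch_midpoint
        a = three_leaf.find("A").id
        point = branch_midpoint(layout, a)
        state.apply("near_point", anchor=point, category="test",
                    layout=layout, radius=1e-6)
        assert state.branches("test") == {a}
        state.apply("near_point", anchor=(0.0, 0.0), category="test",
                    layout=layout, radius=1e9)
        assert state.branches("test") == set(layout.edge_paths)

    def test_near_point_requires_layout(self, state):
        with pytest.raises(SelectionError):
            state.apply("near_point", anchor=(0, 0), radius=1.0)

    def test_unknown_category_rejected(self, three_leaf, state):
        with pytest.raises(SelectionError):
            state.apply("all_external", category="nope")

    def test_toggle_twice_is_identity(self, three_leaf, state):
        before = {k: set(v) for k, v in state.assignment.items()}
        for _ in range(2):
            state.apply("clade", anchor=three_leaf.find("A").parent,
                        category="test", action="toggle")
        after = {k: set(v) for k, v in state.assignment.items() if v}
        assert after == {k: v for k, v in before.items() if v}


class TestCallbacks:
    def test_fire_once_per_update_in_order(self, three_leaf, state):
        calls = []
        register_callback(state, lambda t, s: calls.append("first"))
        register_callback(state, lambda t, s: calls.append("second"))
        for _ in range(3):
            apply_selection(three_leaf, state, "all_external", category="test")
        assert calls == ["first", "second"] * 3

    def test_callback_sees_post_update_state(self, balanced_four):
        state = SelectionState(balanced_four, ["test"])
        seen = []
        state.register_callback(lambda t, s: seen.append(len(s.branches())))
        state.apply("all_external", category="test")
        assert seen == [4]

    def test_non_callable_rejected(self, state):
        with pytest.raises(SelectionError):
            state.register_callback("not a function")


class TestSerialization:
    def test_fig1_style_test_reference_split(self, three_leaf, state):
        state.apply("clade", anchor=three_leaf.find("A").parent, category="test")
        state.apply("branch", anchor=three_leaf.find("C").id,
                    category="reference")
        text = serialize_selection(three_leaf, state)
        assert text == "((A{test},B{test}){test},C{reference});"
        again = parse_newick(text, HYPHY_TAGS)
        rebuilt = SelectionState.from_tree_tags(again)
        assert sorted(rebuilt.categories) == ["reference", "test"]
        assert len(rebuilt.branches("test")) == 3
        assert len(rebuilt.branches("reference")) == 1

    def test_empty_selection_is_plain_newick(self, three_leaf, state):
        assert serialize_selection(three_leaf, state) == "((A,B),C);"

    def test_priority_resolves_multicategory(self, three_leaf, state):
        a = three_leaf.find("A").id
        state.apply("branch", anchor=a, category="test")
        state.apply("branch", anchor=a, category="reference")
        with pytest.raises(SelectionError, match="ambiguous-tag"):
            state.serialize()
        text = state.serialize(category_order=["test", "reference"])
        assert "A{test}" in text

    def test_random_selection_roundtrip(self):
        """Any single-category assignment survives serialize -> parse."""
        for seed in range(25):
            rng = random.Random(seed)
            tree = generate_yule_tree(rng.randint(4, 20), seed=seed)
            state = SelectionState(tree, ["test", "reference"])
            expected = {}
            for node in tree.nodes.values():
                if node.parent is None or rng.random() < 0.5:
                    continue
                cat = rng.choice(["test", "reference"])
                state.apply("branch", anchor=node.id, category=cat)
                expected[node.label or node.id] = {cat}
            again = parse_newick(state.serialize(), HYPHY_TAGS)
            got = {}
            for node in again.preorder():
                if node.tags:
                    got.setdefault(node.label or node.id, set()).update(node.tags)
            got_by_leafset = {
                frozenset(l.label for l in again.leaves(n.id)): n.tags
                for n in again.nodes.values() if n.tags}
            exp_by_leafset = {
                frozenset(l.label for l in tree.leaves(n.id)): state.assignment[n.id]
                for n in tree.nodes.values()
                if state.assignment.get(n.id)}
            assert got_by_leafset == exp_by_leafset
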