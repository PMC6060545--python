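import pytest

from phylodraw import generate_yule_tree, parse_newick


@pytest.fixture
def three_leaf():
    """((A,B),C); — the smallest tree with a non-trivial clade."""
    return parse_newick("((A,B),C);")


@pytest.fixture
def balanced_four():
    return parse_newick("((A,B),(C,D));")


@pytest.fixture
def yule_corpus():
    """Seeded random binary trees spanning 4-64 leaves."""
    return [generate_yule_tree(n, seed=seed)
            for seed in range(10) for n in (4, 9, 20, 64)]
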