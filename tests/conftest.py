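import numpy as np
import pytest

from kallima import ctmc, synthdata
from kallima.treeio import CharacterMatrix, TreeSample


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_tree():
    """((A:1,B:1):1,C:2); — the canonical 3-leaf example."""
    from kallima.treeio import parse_newick

    return parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def five_leaf_tree():
    from kallima.treeio import parse_newick

    return parse_newick("(((A:0.5,B:0.7):0.4,(C:0.6,D:0.2):0.9):0.3,E:1.5);")


def random_tipdata(tree, n_states, rng, poly_fraction=0.2):
    """Random tip data, some cells ambiguous over all states."""
    partials = {}
    for name in tree.taxon_set:
        if rng.random() < poly_fraction:
            vec = np.ones(n_states)
        else:
            vec = np.zeros(n_states)
            vec[rng.integers(n_states)] = 1.0
        partials[name] = vec
    return ctmc.TipData(partials, n_states)


def matrix_from_tips(tree, tip_dicts, characters):
    taxa = sorted(tree.taxon_set)
    codes = np.array(
        [[tip_dicts[c][t] for c in range(len(characters))] for t in taxa],
        dtype=np.int8,
    )
    return CharacterMatrix(taxa, characters, codes)


@pytest.fixture
def single_tree_sample(five_leaf_tree):
    return TreeSample([five_leaf_tree])
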