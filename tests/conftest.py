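import numpy as np
import pytest

from bioregions.community import Grid, build_community
from bioregions.phylobeta import Phylogeny


@pytest.fixture
def grid4() -> Grid:
    return Grid(4, 4, 100.0)


@pytest.fixture
def toy_tree() -> Phylogeny:
    """((A:1,B:1):1,C:2); — the hand-enumerable three-tip tree."""
    return Phylogeny.from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def toy_community(grid4):
    presences = [(0, "A"), (1, "B"), (2, "C"), (3, "A"), (3, "B"), (3, "C")]
    return build_community(presences, grid4, ["A", "B", "C"])


def random_community(rng, grid, species, p=0.4):
    """Random binary community; guarantees every cell non-empty."""
    presences = []
    for cell in range(grid.n_cells):
        present = [s for s in species if rng.random() < p]
        if not present:
            present = [species[rng.integers(len(species))]]
        presences.extend((cell, s) for s in present)
    return build_community(presences, grid, species)


def random_tree(rng, labels):
    """Random binary tree with exponential branch lengths (not ultrametric)."""
    from bioregions.synth import generate_phylogeny

    t = generate_phylogeny(len(labels), int(rng.integers(2**31)))
    # jitter lengths so the tree is non-ultrametric and relabel tips
    lengths = t.lengths.copy()
    non_root = np.arange(t.n_nodes) != t.root
    lengths[non_root] = rng.exponential(1.0, non_root.sum()) + 1e-3
    return Phylogeny(t.parent, lengths, list(labels), t.tip_nodes)
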