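import numpy as np
import pytest

from famevol.species import SpeciesTree, build_default_species_tree
from famevol.tree import Node, parse_newick


@pytest.fixture(scope="session")
def species_tree() -> SpeciesTree:
    return build_default_species_tree()


@pytest.fixture
def congruent_gene_tree(species_tree) -> Node:
    """A gene tree exactly mirroring the species tree, one gene each."""
    root = species_tree.root.copy()
    for leaf in root.leaves():
        leaf.name = f"{leaf.name}_fam1_1"
    return root


@pytest.fixture(scope="session")
def small_species_tree() -> SpeciesTree:
    """4-taxon species tree (2 dicots, 2 grasses) for exhaustive oracles."""
    root = parse_newick("((Ath:1,Bra:1):1,(Osa:1,Zma:1):1);")
    return SpeciesTree(root)


def random_gene_tree(rng: np.random.Generator, species: list[str],
                     n_leaves: int) -> Node:
    """Random rooted binary gene tree with species-tagged leaf names."""
    counters: dict[str, int] = {}
    leaves = []
    for _ in range(n_leaves):
        sp = species[rng.integers(len(species))]
        counters[sp] = counters.get(sp, 0) + 1
        leaves.append(Node(name=f"{sp}_f_{counters[sp]}", length=1.0))
    nodes = leaves[:]
    while len(nodes) > 1:
        i = int(rng.integers(len(nodes)))
        a = nodes.pop(i)
        j = int(rng.integers(len(nodes)))
        b = nodes.pop(j)
        nodes.append(Node(length=1.0, children=[a, b]))
    root = nodes[0]
    root.length = 0.0
    return root
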