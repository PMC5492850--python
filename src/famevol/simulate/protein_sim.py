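"""Amino-acid alignment simulation under the JTT model.

Used to exercise the distance/NJ/bootstrap stack with known trees:
sequences evolve site-independently down a tree whose branch lengths
are expected replacements per site.
"""

from __future__ import annotations

import numpy as np

from ..phylo.alignment import AA_ALPHABET, ProteinAlignment
from ..phylo.jtt import JttModel
from ..tree import Node

__all__ = ["simulate_protein_alignment"]


def simulate_protein_alignment(tree: Node, n_sites: int,
                               rng: np.random.Generator) -> ProteinAlignment:
    model = JttModel()
    states: dict[int, np.ndarray] = {}
    states[tree._uid] = rng.choice(20, size=n_sites, p=model.pi)
    for node in tree.preorder():
        if node.parent is None:
            continue
        p = model.probability_matrix(node.length)
        p_cum = np.cumsum(p, axis=1)
        p_cum[:, -1] = 1.0
        parent = states[node.parent._uid]
        u = rng.random(n_sites)
        states[node._uid] = (p_cum[parent] < u[:, None]).sum(axis=1)
    seqs = {}
    for leaf in tree.leaves():
        seqs[leaf.name] = "".join(AA_ALPHABET[s] for s in states[leaf._uid])
    return ProteinAlignment.from_strings(seqs)
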