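"""Bootstrap support for NJ/JTT trees.

Columns are resampled with replacement; the JTT distance matrix and NJ
tree are rebuilt per replicate; support of each internal edge of the
full-data tree is the percentage of replicates whose tree contains the
same bipartition.  Fully deterministic given the seed.
"""

from __future__ import annotations

import warnings

import numpy as np

from ..tree import Node, bipartitions
from .alignment import ProteinAlignment
from .nj import jtt_distance_matrix, nj_tree

__all__ = ["bootstrap_support"]


def bootstrap_support(aln: ProteinAlignment, n_reps: int = 1000,
                      seed: int = 0) -> Node:
    """NJ/JTT tree with bootstrap supports on internal edges.

    Replicates in which some sequence pair has no shared ungapped
    columns are skipped (a warning is raised if more than 1% are)."""
    rng = np.random.default_rng(seed)
    d, _ = jtt_distance_matrix(aln)
    tree = nj_tree(d, aln.ids)

    target = {split: 0 for split in bipartitions(tree)}
    n_used = 0
    n_skipped = 0
    for _ in range(n_reps):
        cols = rng.integers(0, aln.n_columns, size=aln.n_columns)
        rep_aln = aln.take_columns(cols)
        try:
            rd, _ = jtt_distance_matrix(rep_aln)
        except ValueError:
            n_skipped += 1
            continue
        rep_tree = nj_tree(rd, rep_aln.ids)
        rep_splits = bipartitions(rep_tree)
        for split in target:
            if split in rep_splits:
                target[split] += 1
        n_used += 1
    if n_reps and n_skipped > 0.01 * n_reps:
        warnings.warn(f"{n_skipped}/{n_reps} bootstrap replicates skipped "
                      "(pairs with no shared ungapped sites)")

    all_leaves = frozenset(aln.ids)
    anchor = min(all_leaves)
    for node in tree.postorder():
        if node.parent is None or node.is_leaf:
            continue
        below = frozenset(n.name for n in node.leaves())
        side = below if anchor not in below else all_leaves - below
        if side in target and n_used:
            node.support = 100.0 * target[side] / n_used
    return tree
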