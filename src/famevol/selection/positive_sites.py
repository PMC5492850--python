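"""Clade-specific positive-site partitioning from a switching-model fit.

For every site the mean posterior of the highest-omega class is taken
over the dicot-subtree branches and over the grass-subtree branches of
the fitted tree; a site is dicot-specific when only the dicot mean
clears the threshold, grass-specific symmetrically, and shared when
both do.  Site indices are translated back to original-alignment
coordinates through the kept-column map when one is supplied.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .models import CodonModelResults, label_branches_by_partition

__all__ = ["partition_positive_sites"]


def partition_positive_sites(fit: CodonModelResults, partition: dict[str, str],
                             threshold: float = 0.5,
                             kept_column_map: np.ndarray | None = None,
                             ) -> dict[str, pd.DataFrame]:
    """Dicot-specific / grass-specific / shared positive-site lists.

    `fit` must be a switching-model result (per-branch class posteriors
    present).  When the fitted highest omega is <= 1 all lists are empty.
    """
    if fit.branch_class_posteriors is None:
        raise ValueError("fit has no per-branch class posteriors "
                         "(need a switching-model result)")
    omegas = np.asarray(fit.params["omegas"])
    top = int(np.argmax(omegas))
    empty = pd.DataFrame(columns=["site", "dicot_posterior", "grass_posterior"])
    if omegas[top] <= 1.0:
        return {"dicot": empty.copy(), "grass": empty.copy(), "shared": empty.copy()}

    tree = fit.model.tree
    labels = label_branches_by_partition(tree, partition)
    sides = {"dicot": [], "grass": []}
    for node in tree.postorder():
        if node.parent is None:
            continue
        lab = labels[node._uid]
        if lab in sides:
            sides[lab].append(fit.branch_class_posteriors[node._uid][:, top])
    means = {}
    for side, stacks in sides.items():
        if not stacks:
            raise ValueError(f"tree has no pure {side} branches")
        means[side] = np.mean(np.stack(stacks, axis=0), axis=0)

    n_sites = means["dicot"].shape[0]
    if kept_column_map is not None:
        site_index = np.asarray(kept_column_map, dtype=int)
        if site_index.shape[0] != n_sites:
            raise ValueError("kept-column map length does not match sites")
    else:
        warnings.warn("no kept-column map supplied; site indices are in "
                      "filtered-alignment coordinates")
        site_index = np.arange(n_sites)

    rows = {"dicot": [], "grass": [], "shared": []}
    for s in range(n_sites):
        d_hit = means["dicot"][s] > threshold
        g_hit = means["grass"][s] > threshold
        row = {"site": int(site_index[s]),
               "dicot_posterior": float(means["dicot"][s]),
               "grass_posterior": float(means["grass"][s])}
        if d_hit and g_hit:
            rows["shared"].append(row)
        elif d_hit:
            rows["dicot"].append(row)
        elif g_hit:
            rows["grass"].append(row)
    return {side: pd.DataFrame(r, columns=["site", "dicot_posterior",
                                           "grass_posterior"])
            for side, r in rows.items()}
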