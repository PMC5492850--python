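"""Canonical Saitou-Nei neighbor joining.

Standard Q-criterion agglomeration.  Ties are broken deterministically
by the smallest pair of (current) node indices, negative branch-length
estimates are clamped to zero and flagged in ``node.meta["clamped"]``,
and the result is returned unrooted (trifurcating root) for n >= 3.
"""

from __future__ import annotations

import numpy as np

from ..tree import Node

__all__ = ["nj_tree", "jtt_distance_matrix"]


def nj_tree(dist: np.ndarray, names: list[str]) -> Node:
    d = np.asarray(dist, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n) or n != len(names):
        raise ValueError("distance matrix / name mismatch")
    if n < 3:
        raise ValueError("neighbor joining needs n >= 3")
    if np.abs(d - d.T).max() > 1e-9:
        raise ValueError("distance matrix is not symmetric")
    if np.abs(np.diag(d)).max() > 1e-12:
        raise ValueError("distance matrix diagonal must be zero")

    nodes: list[Node] = [Node(name=nm) for nm in names]
    active = list(range(n))
    d = d.copy()

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # smallest Q; ties -> smallest (i, j) pair of positions
        flat = np.argmin(q)
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        limb_i = 0.5 * sub[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        limb_j = sub[i, j] - limb_i
        ai, aj = active[i], active[j]
        parent = Node()
        for child, limb in ((nodes[ai], limb_i), (nodes[aj], limb_j)):
            if limb < 0:
                child.meta["clamped"] = True
                limb = 0.0
            child.length = float(limb)
            parent.add_child(child)
        # distances from the new node
        new_row = 0.5 * (d[ai, :] + d[aj, :] - d[ai, aj])
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, : -1] = new_row
        d[: -1, -1] = new_row
        nodes.append(parent)
        active = [a for a in active if a not in (ai, aj)] + [len(nodes) - 1]

    # join the last three nodes at a trifurcating root (closed form)
    a, b, c = active
    root = Node()
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    for idx, limb in ((a, la), (b, lb), (c, lc)):
        child = nodes[idx]
        if limb < 0:
            child.meta["clamped"] = True
            limb = 0.0
        child.length = float(limb)
        root.add_child(child)
    return root


def jtt_distance_matrix(aln, tol: float = 1e-8) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise ML JTT distances with pairwise deletion of gapped sites.

    Returns (distance matrix, boolean saturation flags).  Raises if a
    pair shares no ungapped columns.
    """
    from .alignment import GAP_CODE, ProteinAlignment  # noqa: F401
    from .jtt import ml_distance

    mat = aln.matrix
    n = aln.n_sequences
    d = np.zeros((n, n))
    sat = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            ok = (mat[i] != GAP_CODE) & (mat[j] != GAP_CODE)
            if not ok.any():
                raise ValueError(
                    f"sequences {aln.ids[i]} and {aln.ids[j]} share no ungapped sites")
            a, b = mat[i, ok].astype(np.int64), mat[j, ok].astype(np.int64)
            counts = np.bincount(a * 20 + b, minlength=400).reshape(20, 20)
            if (a == b).all():
                t_hat, flag = 0.0, False
            else:
                # symmetrize so d(a,b) == d(b,a) exactly (JTT reversibility)
                t_hat, flag = ml_distance(0.5 * (counts + counts.T), tol=tol)
            d[i, j] = d[j, i] = t_hat
            sat[i, j] = sat[j, i] = flag
    return d, sat
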