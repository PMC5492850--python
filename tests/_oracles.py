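"""Independent brute-force oracles used by the test suite.

Each oracle deliberately reimplements a computation by the most direct
(often exponential-time) route available, without sharing code with the
package implementation it checks.
"""

from __future__ import annotations

import itertools

import numpy as np

from famevol.genetic_code import CODON_AA, NUCS, STOP_CODONS
from famevol.species import SpeciesTree
from famevol.tree import Node

# ---------------------------------------------------------------------------
# NG86 counting oracle


def ng86_sites_oracle(codon: str) -> tuple[float, float]:
    """Synonymous/nonsynonymous site counts by direct enumeration."""
    syn = non = 0.0
    for pos in range(3):
        for alt in NUCS:
            if alt == codon[pos]:
                continue
            mutated = codon[:pos] + alt + codon[pos + 1:]
            if mutated not in STOP_CODONS and CODON_AA[mutated] == CODON_AA[codon]:
                syn += 1
            else:
                non += 1
    return syn / 3.0, non / 3.0


def ng86_path_oracle(a: str, b: str) -> tuple[float, float]:
    """Average syn/nonsyn differences over minimal mutational paths,
    enumerated recursively (stop-traversing paths dropped when any
    stop-free path exists)."""
    def walk(cur: str, remaining: list[int], through_stop: bool):
        if not remaining:
            return [((0.0, 0.0), through_stop)]
        results = []
        for k, pos in enumerate(remaining):
            nxt = cur[:pos] + b[pos] + cur[pos + 1:]
            step_stop = nxt in STOP_CODONS
            syn_step = (not step_stop and cur not in STOP_CODONS
                        and CODON_AA[cur] == CODON_AA[nxt])
            rest = remaining[:k] + remaining[k + 1:]
            for (s, n), ts in walk(nxt, rest, through_stop or step_stop):
                results.append(((s + (1.0 if syn_step else 0.0),
                                 n + (0.0 if syn_step else 1.0)), ts))
        return results

    diffs = [i for i in range(3) if a[i] != b[i]]
    if not diffs:
        return 0.0, 0.0
    all_paths = walk(a, diffs, False)
    clean = [sn for sn, ts in all_paths if not ts]
    pool = clean if clean else [sn for sn, _ in all_paths]
    return (sum(s for s, _ in pool) / len(pool),
            sum(n for _, n in pool) / len(pool))


def ng86_oracle(seq_a: str, seq_b: str) -> tuple[float, float]:
    """(dN, dS) by direct enumeration + Jukes-Cantor."""
    S = N = Sd = Nd = 0.0
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i:i + 3], seq_b[i:i + 3]
        sa, na = ng86_sites_oracle(ca)
        sb, nb = ng86_sites_oracle(cb)
        S += (sa + sb) / 2
        N += (na + nb) / 2
        sd, nd = ng86_path_oracle(ca, cb)
        Sd += sd
        Nd += nd
    ps, pn = Sd / S, Nd / N
    jc = lambda p: -0.75 * np.log(1 - 4 * p / 3) if p < 0.75 else np.inf
    return jc(pn), jc(ps)


# ---------------------------------------------------------------------------
# reconciliation oracle


def _species_candidates(st: SpeciesTree, lca: int) -> list[int]:
    out = [lca]
    while st.parent[lca] != -1:
        lca = st.parent[lca]
        out.append(lca)
    return out


def min_duplications_oracle(gene_tree: Node, st: SpeciesTree) -> int:
    """Minimum duplication count over all valid reconciliation maps,
    by exhaustive enumeration (feasible for small gene trees)."""
    nodes = [n for n in gene_tree.postorder()]
    internal = [n for n in nodes if not n.is_leaf]
    leaf_map = {}
    lca_below = {}
    for n in nodes:
        if n.is_leaf:
            sp = n.name.split("_", 1)[0]
            leaf_map[n._uid] = st._leaf_idx[sp]
            lca_below[n._uid] = st._leaf_idx[sp]
        else:
            m = lca_below[n.children[0]._uid]
            for c in n.children[1:]:
                other = lca_below[c._uid]
                a, b = m, other
                while a != b:
                    if st.depth[a] >= st.depth[b]:
                        a = st.parent[a]
                    else:
                        b = st.parent[b]
                m = a
            lca_below[n._uid] = m

    candidates = {n._uid: _species_candidates(st, lca_below[n._uid])
                  for n in internal}

    def child_subtree_of(parent_sp: int, desc_sp: int) -> int:
        """Which child branch of parent_sp leads to desc_sp (-1 if equal)."""
        if desc_sp == parent_sp:
            return -1
        cur = desc_sp
        while st.parent[cur] != parent_sp:
            cur = st.parent[cur]
        return cur

    best = [np.inf]
    uids = [n._uid for n in internal]

    for combo in itertools.product(*(candidates[u] for u in uids)):
        assignment = dict(zip(uids, combo))
        assignment.update(leaf_map)
        ok = True
        dups = 0
        for n in internal:
            mv = assignment[n._uid]
            kids = [assignment[c._uid] for c in n.children]
            # validity: each child maps at-or-below the parent
            for k in kids:
                cur = k
                while cur != mv and st.parent[cur] != -1:
                    cur = st.parent[cur]
                if cur != mv:
                    ok = False
                    break
            if not ok:
                break
            branches = [child_subtree_of(mv, k) for k in kids]
            speciation = (-1 not in branches and len(set(branches)) == len(branches))
            if not speciation:
                dups += 1
        if ok and dups < best[0]:
            best[0] = dups
    return int(best[0])


# ---------------------------------------------------------------------------
# triangle-merge oracle


def cog_components_oracle(reciprocal_pairs: set[frozenset],
                          species_of: dict[str, str]) -> list[set[str]]:
    """COG cores via explicit triangle enumeration and connected
    components of the shares-an-edge triangle graph."""
    pairs = list(reciprocal_pairs)
    adj = {}
    for p in pairs:
        a, b = tuple(p)
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    triangles = []
    genes = sorted(adj)
    for a, b, c in itertools.combinations(genes, 3):
        if (b in adj[a] and c in adj[a] and c in adj[b]
                and len({species_of[a], species_of[b], species_of[c]}) == 3):
            triangles.append(frozenset((a, b, c)))
    # connected components: triangles sharing an edge (two genes)
    n = len(triangles)
    comp = list(range(n))

    def find(i):
        while comp[i] != i:
            comp[i] = comp[comp[i]]
            i = comp[i]
        return i

    for i, j in itertools.combinations(range(n), 2):
        if len(triangles[i] & triangles[j]) >= 2:
            ri, rj = find(i), find(j)
            if ri != rj:
                comp[ri] = rj
    clusters: dict[int, set[str]] = {}
    for i, t in enumerate(triangles):
        clusters.setdefault(find(i), set()).update(t)
    return sorted(clusters.values(), key=lambda s: min(s))


# ---------------------------------------------------------------------------
# misc


def tree_distance_matrix(root: Node, names: list[str]) -> np.ndarray:
    """Leaf-to-leaf path-length matrix (forward map for NJ tests)."""
    leaves = {l.name: l for l in root.leaves()}

    def depth_of(n: Node) -> float:
        d = 0.0
        while n.parent is not None:
            d += n.length
            n = n.parent
        return d
    n = len(names)
    D = np.zeros((n, n))
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            if i >= j:
                continue
            na, nb = leaves[a], leaves[b]
            anc = set()
            cur = na
            while cur is not None:
                anc.add(cur._uid)
                cur = cur.parent
            cur, d = nb, 0.0
            while cur._uid not in anc:
                d += cur.length
                cur = cur.parent
            lca = cur
            D[i, j] = D[j, i] = d + depth_of(na) - depth_of(lca)
    return D
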