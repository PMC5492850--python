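"""Felsenstein pruning over codon (or codon-x-class) state spaces.

Site patterns are compressed once; conditional likelihoods are
propagated in vectorized blocks of shape (n_patterns, n_states) with
per-node rescaling, so log-likelihoods stay finite on any alignment.
The engine is model-agnostic: callers supply one transition-probability
matrix per edge (and a root distribution), so the same instance serves
the one-ratio, branch, site-mixture and switching models.
"""

from __future__ import annotations

import numpy as np

from ..genetic_code import CODON_INDEX, N_CODONS, codons_of
from ..tree import Node

__all__ = ["encode_codon_alignment", "PruningEngine"]


def encode_codon_alignment(seqs: dict[str, str]) -> tuple[list[str], np.ndarray]:
    """Aligned CDS strings -> (ids, states) with -1 for gap/ambiguous codons."""
    ids = list(seqs)
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) != 1:
        raise ValueError("sequences are not aligned (unequal lengths)")
    L = lengths.pop()
    if L % 3:
        raise ValueError("alignment length is not a multiple of 3")
    states = np.full((len(ids), L // 3), -1, dtype=np.int32)
    for i, sid in enumerate(ids):
        for j, codon in enumerate(codons_of(seqs[sid].upper())):
            states[i, j] = CODON_INDEX.get(codon, -1)
    return ids, states


class PruningEngine:
    """Pruning likelihoods for one tree + one encoded alignment.

    Parameters
    ----------
    tree : Node
        Rooted tree whose leaf names match `ids`.
    ids, states
        Output of :func:`encode_codon_alignment` (or any integer state
        matrix with -1 meaning "missing").
    n_base_states : int
        Size of the observable state space (61 for codons).
    """

    def __init__(self, tree: Node, ids: list[str], states: np.ndarray,
                 n_base_states: int = N_CODONS):
        self.tree = tree
        self.nodes = list(tree.postorder())
        leaf_names = [n.name for n in self.nodes if n.is_leaf]
        if set(leaf_names) != set(ids):
            raise ValueError("tree leaves do not match alignment ids")
        row_of = {sid: i for i, sid in enumerate(ids)}
        # pattern compression
        patterns, inverse, counts = np.unique(
            states, axis=1, return_inverse=True, return_counts=True)
        self.patterns = patterns          # (n_seq, n_patterns)
        self.pattern_of_site = inverse.ravel()
        self.weights = counts.astype(float)
        self.n_patterns = patterns.shape[1]
        self.n_base = n_base_states
        self.leaf_pattern = {n._uid: patterns[row_of[n.name]]
                             for n in self.nodes if n.is_leaf}
        self.n_sites = states.shape[1]

    # -- core ----------------------------------------------------------
    def _leaf_partial(self, node: Node, n_states: int) -> np.ndarray:
        """(n_patterns, n_states) indicator partials for a leaf.

        For an expanded state space (codon x class) the observed codon is
        compatible with every class."""
        pat = self.leaf_pattern[node._uid]
        out = np.zeros((self.n_patterns, n_states))
        k = n_states // self.n_base
        obs = pat >= 0
        for c in range(k):
            out[np.arange(self.n_patterns)[obs], pat[obs] + c * self.n_base] = 1.0
        out[~obs, :] = 1.0
        return out

    def pattern_logliks(self, p_of_edge: dict[int, np.ndarray],
                        root_dist: np.ndarray) -> np.ndarray:
        """Per-pattern log-likelihoods given per-edge P matrices."""
        n_states = root_dist.shape[0]
        partial: dict[int, np.ndarray] = {}
        scale: dict[int, np.ndarray] = {}
        for node in self.nodes:
            if node.is_leaf:
                partial[node._uid] = self._leaf_partial(node, n_states)
                scale[node._uid] = np.zeros(self.n_patterns)
                continue
            prod = None
            logscale = np.zeros(self.n_patterns)
            for child in node.children:
                p = p_of_edge[child._uid]
                if child.is_leaf:
                    pat = self.leaf_pattern[child._uid]
                    k = n_states // self.n_base
                    obs = pat >= 0
                    if k == 1:
                        contrib = np.ones((self.n_patterns, n_states))
                        contrib[obs] = p[:, pat[obs]].T
                    else:
                        contrib = np.ones((self.n_patterns, n_states))
                        cols = np.concatenate([pat[obs] + c * self.n_base
                                               for c in range(k)])
                        block = p[:, cols].reshape(n_states, k, obs.sum())
                        contrib[obs] = block.sum(axis=1).T
                else:
                    contrib = partial[child._uid] @ p.T
                    logscale += scale[child._uid]
                prod = contrib if prod is None else prod * contrib
            mx = prod.max(axis=1)
            mx[mx == 0] = 1.0
            prod /= mx[:, None]
            partial[node._uid] = prod
            scale[node._uid] = logscale + np.log(mx)
        root = self.nodes[-1]
        site_l = partial[root._uid] @ root_dist
        return np.log(np.clip(site_l, 1e-300, None)) + scale[root._uid]

    def loglik(self, p_of_edge: dict[int, np.ndarray],
               root_dist: np.ndarray) -> float:
        return float(self.pattern_logliks(p_of_edge, root_dist) @ self.weights)

    def mixture_logliks(self, p_of_edge_per_class: list[dict[int, np.ndarray]],
                        root_dists: list[np.ndarray],
                        weights: np.ndarray) -> tuple[float, np.ndarray]:
        """Site-mixture log-likelihood and per-site class posteriors.

        Returns (total lnL, (n_patterns, K) posterior matrix)."""
        per_class = np.stack([
            self.pattern_logliks(p, d)
            for p, d in zip(p_of_edge_per_class, root_dists)], axis=1)
        logw = np.log(np.clip(np.asarray(weights, dtype=float), 1e-300, None))
        joint = per_class + logw[None, :]
        mx = joint.max(axis=1)
        site_log = mx + np.log(np.exp(joint - mx[:, None]).sum(axis=1))
        post = np.exp(joint - site_log[:, None])
        return float(site_log @ self.weights), post

    # -- inside-outside marginals for the expanded state space ----------
    def state_posteriors(self, p_of_edge: dict[int, np.ndarray],
                         root_dist: np.ndarray) -> dict[int, np.ndarray]:
        """Per-node, per-pattern marginal posterior over states.

        Standard inside-outside: returns {node uid: (n_patterns, n_states)}
        with rows summing to 1."""
        n_states = root_dist.shape[0]
        partial: dict[int, np.ndarray] = {}
        scale: dict[int, np.ndarray] = {}
        for node in self.nodes:
            if node.is_leaf:
                partial[node._uid] = self._leaf_partial(node, n_states)
                scale[node._uid] = np.zeros(self.n_patterns)
            else:
                prod = None
                logscale = np.zeros(self.n_patterns)
                for child in node.children:
                    contrib = partial[child._uid] @ p_of_edge[child._uid].T
                    logscale += scale[child._uid]
                    prod = contrib if prod is None else prod * contrib
                mx = prod.max(axis=1)
                mx[mx == 0] = 1.0
                prod /= mx[:, None]
                partial[node._uid] = prod
                scale[node._uid] = logscale + np.log(mx)

        outside: dict[int, np.ndarray] = {}
        root = self.nodes[-1]
        outside[root._uid] = np.broadcast_to(root_dist,
                                             (self.n_patterns, n_states)).copy()
        for node in root.preorder():
            for child in node.children:
                other = outside[node._uid].copy()
                for sib in node.children:
                    if sib is child:
                        continue
                    other *= partial[sib._uid] @ p_of_edge[sib._uid].T
                out = other @ p_of_edge[child._uid]
                mx = out.max(axis=1)
                mx[mx == 0] = 1.0
                outside[child._uid] = out / mx[:, None]
        posts = {}
        for node in self.nodes:
            joint = partial[node._uid] * outside[node._uid]
            total = joint.sum(axis=1, keepdims=True)
            total[total == 0] = 1.0
            posts[node._uid] = joint / total
        return posts
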