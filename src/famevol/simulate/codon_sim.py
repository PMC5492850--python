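"""Codon alignment simulation under the package's selection regimes.

Sequences evolve down a gene tree under the 61-state GY94 rate matrix.
Four regimes match the fitted models: a single omega everywhere
("one-ratio"), branch-specific omegas ("branch"), a discrete site
mixture ("M3"), and a Markov-modulated site mixture in which each site's
omega class switches along branches at rate delta ("M3S1", simulated
exactly on the expanded codon-x-class state space).  A "planted" hook
assigns chosen sites a different class on a chosen branch set, which
gives clade-specific positive selection with known ground truth.

Branch lengths of the input tree are interpreted as expected
substitutions per codon.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..genetic_code import CODONS, N_CODONS, translate_cds
from ..selection.codon_matrix import (CodonMatrixExp, build_rate_matrix,
                                      f3x4_frequencies, uniform_frequencies)
from ..tree import Node
from .config import SimulationConfig

__all__ = ["CodonAlignmentTruth", "simulate_codon_alignment", "switching_generator"]


@dataclass
class CodonAlignmentTruth:
    """Simulated codon alignment plus its ground truth."""

    sequences: dict[str, str]            # leaf name -> CDS string
    site_class: np.ndarray               # class index per site at the root
    node_class: dict[int, np.ndarray]    # node uid -> class index per site
    branch_omega: dict[int, float]       # node uid -> omega on branch above
    pi: np.ndarray
    regime: str

    @property
    def n_codons(self) -> int:
        return len(next(iter(self.sequences.values()))) // 3

    def proteins(self) -> dict[str, str]:
        return {k: translate_cds(v) for k, v in self.sequences.items()}


def _resolve_pi(cfg: SimulationConfig) -> np.ndarray:
    if cfg.pi is not None:
        return np.asarray(cfg.pi, dtype=float)
    if cfg.codon_freq == "uniform":
        return uniform_frequencies()
    return f3x4_frequencies()  # F3x4 of uniform nucleotide composition


def _sample_rows(p_cum: np.ndarray, states: np.ndarray,
                 rng: np.random.Generator) -> np.ndarray:
    u = rng.random(states.shape[0])
    return (p_cum[states] < u[:, None]).sum(axis=1)


def switching_generator(kappa: float, omegas: np.ndarray, props: np.ndarray,
                        delta: float, pi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Expanded (61*K)-state generator for the switching model.

    Within-class blocks are the class-k GY94 matrices (jointly normalized
    to one expected codon substitution per unit time under the stationary
    mixture); between-class rates are delta * p_l for a jump k -> l, which
    keeps the class marginal stationary at p and the chain reversible.
    Returns (generator, stationary distribution).
    """
    if delta < 0:
        raise ValueError("switching rate delta must be >= 0")
    k = len(omegas)
    n = N_CODONS * k
    qs = [build_rate_matrix(kappa, w, pi, normalize=False) for w in omegas]
    # joint normalization: expected codon substitutions per unit time = 1
    rate = sum(p * -(pi * np.diag(q)).sum() for p, q in zip(props, qs))
    if rate <= 0:
        raise ValueError("degenerate switching generator")
    big = np.zeros((n, n))
    eye = np.eye(N_CODONS)
    for a in range(k):
        big[a * 61:(a + 1) * 61, a * 61:(a + 1) * 61] = qs[a] / rate
        for b in range(k):
            if a != b:
                big[a * 61:(a + 1) * 61, b * 61:(b + 1) * 61] = delta * props[b] * eye
    np.fill_diagonal(big, 0.0)
    np.fill_diagonal(big, -big.sum(axis=1))
    stat = np.concatenate([p * pi for p in props])
    return big, stat


def simulate_codon_alignment(gene_tree: Node, cfg: SimulationConfig,
                             rng: np.random.Generator | None = None,
                             planted_sites: np.ndarray | None = None,
                             planted_class: int = 2,
                             planted_branches: set[int] | None = None,
                             planted_base_class: int | None = None,
                             ) -> CodonAlignmentTruth:
    """Simulate a gap-free codon alignment along `gene_tree`.

    Parameters
    ----------
    planted_sites, planted_class, planted_branches
        Optional override: on branches whose node uid is in
        `planted_branches`, the listed site indices evolve under class
        `planted_class` instead of their base class.  Only meaningful for
        the mixture regimes (base classes default to class 0 when the
        regime is "one-ratio").
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    pi = _resolve_pi(cfg)
    L = cfg.n_codons
    nodes = list(gene_tree.postorder())
    leaves = [n for n in nodes if n.is_leaf]
    if any(n.name is None for n in leaves):
        raise ValueError("gene tree leaves must be named")

    if cfg.regime == "M3S1" and cfg.switch_rate > 0 and planted_sites is None:
        return _simulate_switching(gene_tree, cfg, pi, rng)

    props = np.asarray(cfg.site_classes, dtype=float)
    omegas = np.asarray(cfg.site_omegas, dtype=float)

    # per-site base class
    if cfg.regime in ("M3", "M3S1"):
        site_class = rng.choice(len(props), size=L, p=props)
    else:
        site_class = np.zeros(L, dtype=int)
    if planted_sites is not None and planted_base_class is not None:
        site_class[np.asarray(planted_sites, dtype=int)] = planted_base_class

    # per-branch omega lookup
    def branch_omega_of(node: Node) -> float | None:
        if cfg.regime == "branch":
            cls = node.meta.get("branch_class", "default")
            return float(cfg.branch_omega.get(cls, cfg.omega))
        if cfg.regime == "one-ratio":
            return cfg.omega
        return None  # mixture regimes use per-site classes

    # one eigendecomposition per distinct branch omega; mixture classes
    # share a joint normalization so branch lengths stay in expected
    # substitutions per codon under the site mixture
    needed: set[float] = set()
    for n in nodes:
        if n.parent is None:
            continue
        w = branch_omega_of(n)
        if w is not None:
            needed.add(w)
    decomps = {w: CodonMatrixExp(build_rate_matrix(cfg.kappa, w, pi), pi)
               for w in sorted(needed)}
    class_decomps: list[CodonMatrixExp] = []
    if cfg.regime in ("M3", "M3S1") or planted_sites is not None:
        from ..selection.codon_matrix import mixture_rate_matrices
        class_decomps = [CodonMatrixExp(q, pi) for q in
                         mixture_rate_matrices(cfg.kappa, omegas, props, pi)]

    planted_sites = (np.asarray(planted_sites, dtype=int)
                     if planted_sites is not None else None)
    planted_branches = planted_branches or set()

    states: dict[int, np.ndarray] = {}
    node_class: dict[int, np.ndarray] = {}
    branch_omega: dict[int, float] = {}
    root = gene_tree
    states[root._uid] = rng.choice(N_CODONS, size=L, p=pi)
    node_class[root._uid] = site_class.copy()

    for node in root.preorder():
        if node.parent is None:
            continue
        parent_states = states[node.parent._uid]
        w_branch = branch_omega_of(node)
        classes = node_class[node.parent._uid].copy()
        if planted_sites is not None and node._uid in planted_branches:
            classes = classes.copy()
            classes[planted_sites] = planted_class
        node_class[node._uid] = classes
        child = np.empty(L, dtype=int)
        if w_branch is not None and planted_sites is None:
            dec = decomps[w_branch]
            p_cum = np.cumsum(dec.probability_matrix(node.length), axis=1)
            p_cum[:, -1] = 1.0
            child[:] = _sample_rows(p_cum, parent_states, rng)
            branch_omega[node._uid] = w_branch
        else:
            # sites grouped by class; one P(t) per class present
            for k in np.unique(classes):
                dec = class_decomps[int(k)]
                p_cum = np.cumsum(dec.probability_matrix(node.length), axis=1)
                p_cum[:, -1] = 1.0
                mask = classes == k
                child[mask] = _sample_rows(p_cum, parent_states[mask], rng)
            branch_omega[node._uid] = float("nan")
        states[node._uid] = child

    seqs = {leaf.name: "".join(CODONS[s] for s in states[leaf._uid])
            for leaf in leaves}
    return CodonAlignmentTruth(sequences=seqs, site_class=site_class,
                               node_class=node_class, branch_omega=branch_omega,
                               pi=pi, regime=cfg.regime)


def _simulate_switching(gene_tree: Node, cfg: SimulationConfig,
                        pi: np.ndarray, rng: np.random.Generator) -> CodonAlignmentTruth:
    """Exact simulation of the switching regime on 61*K states."""
    props = np.asarray(cfg.site_classes, dtype=float)
    omegas = np.asarray(cfg.site_omegas, dtype=float)
    L = cfg.n_codons
    big, stat = switching_generator(cfg.kappa, omegas, props, cfg.switch_rate, pi)
    dec = CodonMatrixExp(big, stat)
    root = gene_tree
    states = {root._uid: rng.choice(len(stat), size=L, p=stat)}
    for node in root.preorder():
        if node.parent is None:
            continue
        p_cum = np.cumsum(dec.probability_matrix(node.length), axis=1)
        p_cum[:, -1] = 1.0
        states[node._uid] = _sample_rows(p_cum, states[node.parent._uid], rng)
    node_class = {uid: s // N_CODONS for uid, s in states.items()}
    seqs = {leaf.name: "".join(CODONS[s % N_CODONS] for s in states[leaf._uid])
            for leaf in gene_tree.leaves()}
    return CodonAlignmentTruth(sequences=seqs,
                               site_class=node_class[root._uid].copy(),
                               node_class=node_class,
                               branch_omega={}, pi=pi, regime="M3S1")
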