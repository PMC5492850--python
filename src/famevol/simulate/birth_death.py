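"""Gene family birth-death histories along the species tree.

Each extant gene lineage duplicates at rate lambda and dies at rate mu,
independently, while it travels down a species-tree branch; at a
speciation node every surviving lineage enters both daughter branches.
The simulator keeps the complete history (including fully extinct
subtrees) in an event log, and returns the pruned gene tree(s) containing
only lineages with extant descendants — the part of the history any
inference method could see.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..species import SpeciesTree
from ..tree import Node
from .config import SimulationConfig

__all__ = ["GeneFamilyHistory", "simulate_family", "FamilyExplosionError"]


class FamilyExplosionError(RuntimeError):
    """Live lineage count exceeded the configured cap."""


@dataclass
class GeneFamilyHistory:
    """A simulated gene family with full ground truth.

    Attributes
    ----------
    gene_trees : list of Node
        Pruned gene trees (one per founding root copy with extant
        descendants).  Leaves are named ``<species>_<family>_<serial>``.
    events : pandas.DataFrame
        One row per duplication/loss event: columns ``event``,
        ``species_branch`` (name of the species-tree node below the
        branch), ``time`` along the branch, ``observable``.
    counts : dict
        Species-tree postorder node index -> number of gene lineages
        crossing that node (surviving to it), the true copy number.
    """

    species_tree: SpeciesTree
    family_id: str
    gene_trees: list = field(default_factory=list)
    events: pd.DataFrame = None
    counts: dict = field(default_factory=dict)

    @property
    def n_observable_duplications(self) -> int:
        if self.events.empty:
            return 0
        m = (self.events["event"] == "duplication") & self.events["observable"]
        return int(m.sum())

    def leaf_counts(self) -> dict[str, int]:
        """Extant gene count per species."""
        out = {s: 0 for s in self.species_tree.leaf_names()}
        for t in self.gene_trees:
            for leaf in t.leaves():
                out[leaf.meta["species"]] += 1
        return out


def simulate_family(species_tree: SpeciesTree, cfg: SimulationConfig,
                    rng: np.random.Generator | None = None,
                    family_id: str = "fam1") -> GeneFamilyHistory:
    """Simulate one gene family history along `species_tree`.

    Returns a :class:`GeneFamilyHistory` with pruned gene trees, the
    complete event log (extinct events flagged unobservable) and the true
    per-node copy numbers.
    """
    if not np.isfinite(cfg.birth_rate) or not np.isfinite(cfg.death_rate):
        raise ValueError("birth/death rates must be finite")
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    lam, mu = cfg.birth_rate, cfg.death_rate
    total_rate = lam + mu
    st = species_tree
    events: list[dict] = []
    live = [0]  # mutable live-lineage counter for the explosion guard

    def evolve_branch(gnode: Node, t_remaining: float, branch_idx: int,
                      t_elapsed: float) -> list[Node]:
        """Grow `gnode`'s branch along species branch `branch_idx`.

        Returns gene nodes alive at the bottom of the species branch.
        """
        while True:
            wait = rng.exponential(1.0 / total_rate) if total_rate > 0 else np.inf
            if wait >= t_remaining:
                gnode.length += t_remaining
                return [gnode]
            gnode.length += wait
            t_elapsed += wait
            t_remaining -= wait
            if rng.random() < lam / total_rate:
                events.append({"event": "duplication", "branch_idx": branch_idx,
                               "time": t_elapsed, "node": gnode})
                gnode.meta["event"] = "duplication"
                left, right = Node(), Node()
                gnode.add_child(left)
                gnode.add_child(right)
                live[0] += 1
                if live[0] > cfg.lineage_cap:
                    raise FamilyExplosionError(
                        f"live lineage count exceeded cap {cfg.lineage_cap}; "
                        "lower birth_rate or raise lineage_cap")
                survivors = evolve_branch(left, t_remaining, branch_idx, t_elapsed)
                survivors += evolve_branch(right, t_remaining, branch_idx, t_elapsed)
                return survivors
            events.append({"event": "loss", "branch_idx": branch_idx,
                           "time": t_elapsed, "node": gnode})
            gnode.meta["dead"] = True
            live[0] -= 1
            return []

    counts: dict[int, int] = {}

    def at_species_node(node_idx: int, lineages: list[Node]) -> None:
        counts[node_idx] = len(lineages)
        snode = st.nodes[node_idx]
        if snode.is_leaf:
            for g in lineages:
                g.meta["species"] = snode.name
                g.meta["extant"] = True
            return
        for g in lineages:
            g.meta["event"] = "speciation"
            g.meta["species_node"] = node_idx
        live[0] += len(lineages)  # each lineage doubles at the speciation
        if live[0] > cfg.lineage_cap:
            raise FamilyExplosionError(
                f"live lineage count exceeded cap {cfg.lineage_cap}")
        for child in snode.children:
            cidx = st.index[child._uid]
            entering: list[Node] = []
            for g in lineages:
                cg = Node()
                g.add_child(cg)
                entering.append(cg)
            survivors: list[Node] = []
            for g in entering:
                survivors += evolve_branch(g, child.length, cidx, 0.0)
            at_species_node(cidx, survivors)

    roots = [Node() for _ in range(cfg.root_copies)]
    live[0] = cfg.root_copies
    at_species_node(st.mrca_all, roots)

    # -- prune to observable gene trees --------------------------------
    def has_extant(node: Node) -> bool:
        return any(n.meta.get("extant") for n in node.postorder())

    def prune(node: Node) -> Node | None:
        if node.is_leaf:
            return node.copy() if node.meta.get("extant") else None
        kept = [prune(c) for c in node.children]
        kept = [k for k in kept if k is not None]
        if not kept:
            return None
        if len(kept) == 1:
            kept[0].length += node.length
            return kept[0]
        new = Node(length=node.length)
        new.meta = dict(node.meta)
        for k in kept:
            new.add_child(k)
        return new

    pruned = []
    for r in roots:
        p = prune(r)
        if p is not None:
            p.length = 0.0
            pruned.append(p)

    # deterministic leaf naming, by species then simulation order
    serial: dict[str, int] = {}
    for t in pruned:
        for leaf in t.leaves():
            sp = leaf.meta["species"]
            serial[sp] = serial.get(sp, 0) + 1
            leaf.name = f"{sp}_{family_id}_{serial[sp]}"

    # observability flags
    rows = []
    for ev in events:
        node = ev["node"]
        if ev["event"] == "duplication":
            obs = len(node.children) == 2 and all(has_extant(c) for c in node.children)
        else:
            obs = _loss_observable(node)
        rows.append({"event": ev["event"],
                     "species_branch": st.node_name(ev["branch_idx"]),
                     "branch_idx": ev["branch_idx"],
                     "time": ev["time"],
                     "observable": obs})
    ev_df = pd.DataFrame(rows, columns=["event", "species_branch", "branch_idx",
                                        "time", "observable"])
    return GeneFamilyHistory(species_tree=st, family_id=family_id,
                             gene_trees=pruned, events=ev_df, counts=counts)


def _loss_observable(dead: Node) -> bool:
    """A death leaves a detectable absence iff some relative survived.

    The nearest branching ancestor (duplication or speciation) must have
    extant descendants on another child; otherwise the whole clade
    vanished silently and no method can know it existed.
    """
    node = dead
    while node.parent is not None:
        parent = node.parent
        for sib in parent.children:
            if sib is node:
                continue
            if any(n.meta.get("extant") for n in sib.postorder()):
                return True
        node = parent
    return False
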