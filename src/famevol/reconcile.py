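"""Gene-tree/species-tree reconciliation and event classification.

The module mechanizes the manual COG inspection workflow: root the gene
tree, find the maximal all-dicot and all-grass clades (subgroups), call
duplications by LCA mapping, classify them as ancient (in the MRCA of
the dicots or grasses, or another multi-species ancestor) or recent
(confined to one or two species), call losses both by the
subgroup-absence rule (a partition species missing from a subgroup) and
by reconciliation (species-tree branches skipped by a gene lineage),
and aggregate per-branch gains/losses into ancestral copy-number
profiles that satisfy parent + gains - losses = child on every branch.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .species import SpeciesTree
from .tree import Node, reroot_above

__all__ = ["Reconciliation", "Subgroup", "species_of_leaf", "root_gene_tree",
           "detect_subgroups", "infer_events", "reconstruct_copy_numbers",
           "summarize_events", "CopyNumberProfile"]


def species_of_leaf(name: str) -> str:
    """Species tag from a ``<species>_<family>_<serial>`` gene id."""
    return name.split("_", 1)[0]


# ---------------------------------------------------------------------------
# reconciliation core


@dataclass
class Reconciliation:
    """LCA reconciliation of a rooted gene tree into the species tree."""

    gene_tree: Node
    species_tree: SpeciesTree
    mapping: dict[int, int]          # gene node uid -> species node index
    event: dict[int, str]            # gene node uid -> speciation|duplication|leaf
    branch_losses: dict[int, int]    # species node index -> losses on branch above
    branch_gains: dict[int, int]     # species node index -> duplications mapped there
    origination: int                 # species node index where the family starts

    @property
    def n_duplications(self) -> int:
        return sum(1 for e in self.event.values() if e == "duplication")

    @property
    def n_losses(self) -> int:
        return sum(self.branch_losses.values())

    def duplication_nodes(self) -> list[Node]:
        return [n for n in self.gene_tree.postorder()
                if self.event.get(n._uid) == "duplication"]


def reconcile(gene_tree: Node, st: SpeciesTree) -> Reconciliation:
    """Map each gene node to the species-tree LCA of its leaf species and
    derive duplication calls and per-branch implied losses."""
    mapping: dict[int, int] = {}
    event: dict[int, str] = {}
    for node in gene_tree.postorder():
        if node.is_leaf:
            sp = species_of_leaf(node.name)
            if sp not in st._leaf_idx:
                raise ValueError(f"species {sp!r} (gene {node.name}) not in species tree")
            mapping[node._uid] = st._leaf_idx[sp]
            event[node._uid] = "leaf"
        else:
            kids = [mapping[c._uid] for c in node.children]
            m = kids[0]
            for k in kids[1:]:
                m = _species_lca(st, m, k)
            mapping[node._uid] = m
            event[node._uid] = ("duplication" if any(k == m for k in kids)
                                else "speciation")

    branch_losses: dict[int, int] = {}
    branch_gains: dict[int, int] = {}
    for node in gene_tree.postorder():
        if node.is_leaf:
            continue
        if event[node._uid] == "duplication":
            branch_gains[mapping[node._uid]] = branch_gains.get(mapping[node._uid], 0) + 1
        for child in node.children:
            _count_path_losses(st, mapping[node._uid], mapping[child._uid],
                               event[node._uid] == "duplication", branch_losses)
    return Reconciliation(gene_tree=gene_tree, species_tree=st, mapping=mapping,
                          event=event, branch_losses=branch_losses,
                          branch_gains=branch_gains,
                          origination=mapping[gene_tree._uid])


def _species_lca(st: SpeciesTree, a: int, b: int) -> int:
    while a != b:
        if st.depth[a] >= st.depth[b]:
            a = st.parent[a]
        else:
            b = st.parent[b]
    return a


def _count_path_losses(st: SpeciesTree, top: int, bottom: int,
                       parent_is_dup: bool, out: dict[int, int]) -> None:
    """Losses implied by a gene edge whose ends map to `top` >= `bottom`.

    The lineage passes through every species node strictly between; at
    each it fails to populate the sibling branch (one loss there).  When
    the parent gene node is a duplication mapping to `top`, the lineage
    additionally passes through `top` itself.
    """
    path = []
    s = bottom
    while s != top:
        path.append(s)
        s = st.parent[s]
        if s == -1:
            raise ValueError("mapping inconsistency: bottom not under top")
    path.append(top)
    # interior passes: nodes strictly between bottom and top, plus top
    # itself for a duplication parent
    upper = len(path) - 1 if not parent_is_dup else len(path)
    for k in range(1, upper):
        s = path[k]
        on_path = path[k - 1]
        for child in st.nodes[s].children:
            ci = st.index[child._uid]
            if ci != on_path:
                out[ci] = out.get(ci, 0) + 1


# ---------------------------------------------------------------------------
# rooting


def _unrooted_edges(root: Node) -> list[Node]:
    """Nodes below each candidate rooting edge (every non-root node)."""
    return [n for n in root.postorder() if n.parent is not None]


def root_gene_tree(tree: Node, st: SpeciesTree, method: str = "minimize-duplication",
                   outgroup: str | None = None) -> Node:
    """Root an unrooted (or arbitrarily rooted) gene tree.

    ``minimize-duplication`` roots on the edge minimizing inferred
    duplications + reconciliation losses, with ties broken first by
    preferring a clean dicot/grass split at the root and then by the
    smallest leaf id below the rooting edge.  Alternatives: ``midpoint``
    and ``outgroup`` (requires `outgroup` id).
    """
    if method == "outgroup":
        if outgroup is None:
            raise ValueError("outgroup method requires an outgroup id")
        target = tree.find(outgroup)
        if target is None:
            raise ValueError(f"outgroup {outgroup!r} not found in tree")
        return reroot_above(target)
    if method == "midpoint":
        return _midpoint_root(tree)
    if method != "minimize-duplication":
        raise ValueError(f"unknown rooting method {method!r}")

    part = st.partition
    best = None
    for i, node in enumerate(_unrooted_edges(tree)):
        work = tree.copy()
        target = list(n for n in work.postorder() if n.parent is not None)[i]
        rooted = reroot_above(target)
        rec = reconcile(rooted, st)
        cost = rec.n_duplications + rec.n_losses
        clean = 0
        if len(rooted.children) == 2:
            sides = [{part[species_of_leaf(l.name)] for l in c.leaves()}
                     for c in rooted.children]
            if sides[0] != sides[1] and all(len(s) == 1 for s in sides):
                clean = -1  # prefer a dicot/grass bipartition at the root
        tiebreak = min(l.name for l in target.leaves())
        key = (cost, clean, tiebreak)
        if best is None or key < best[0]:
            best = (key, rooted)
    return best[1]


def _midpoint_root(tree: Node) -> Node:
    leaves = tree.leaves()
    if len(leaves) == 1:
        return tree
    # farthest pair by two BFS-style sweeps over all pairs (trees are small)
    depth = {n._uid: n.depth() for n in tree.postorder()}

    def path_dist(a: Node, b: Node) -> float:
        seen = {}
        n = a
        while n is not None:
            seen[n._uid] = n
            n = n.parent
        n, d = b, 0.0
        while n._uid not in seen:
            d += n.length
            n = n.parent
        return d + depth[a._uid] - depth[n._uid]

    pair = max(itertools.combinations(leaves, 2), key=lambda p: path_dist(*p))
    a, b = pair
    total = path_dist(a, b)
    # walk from the deeper end towards the other until passing total/2
    seen = set()
    n = a
    while n is not None:
        seen.add(n._uid)
        n = n.parent
    # path b -> lca -> a
    path_up_b = []
    n = b
    while n._uid not in seen:
        path_up_b.append(n)
        n = n.parent
    lca = n
    path_up_a = []
    n = a
    while n is not lca:
        path_up_a.append(n)
        n = n.parent
    # full path from a to b as edges (node, length): up from a then down to b
    edges = path_up_a + list(reversed(path_up_b))
    half = total / 2.0
    acc = 0.0
    for node in edges:
        if acc + node.length >= half - 1e-12:
            frac = (half - acc) / node.length if node.length > 0 else 0.5
            # reroot_above measures fraction from the node upward
            work_index = None
            candidates = [n for n in tree.postorder() if n.parent is not None]
            work = tree.copy()
            wcands = [n for n in work.postorder() if n.parent is not None]
            work_index = candidates.index(node)
            target = wcands[work_index]
            up_from_node = node in path_up_a  # walking towards the root
            f = frac if up_from_node else 1.0 - frac
            return reroot_above(target, fraction=f)
        acc += node.length
    return reroot_above(edges[-1], fraction=0.5)


# ---------------------------------------------------------------------------
# subgroups


@dataclass
class Subgroup:
    id: str
    partition: str                  # dicot | grass
    members: list[str]
    species: set[str]
    support: float | None = None
    low_support: bool = False

    @property
    def n_members(self) -> int:
        return len(self.members)


def detect_subgroups(rooted: Node, st: SpeciesTree, min_support: float = 0.0,
                     ) -> list[Subgroup]:
    """Maximal monophyletic all-dicot and all-grass clades.

    Singleton leaves form singleton subgroups.  Clades whose defining
    edge has support below `min_support` are still returned, flagged
    ``low_support``.
    """
    part = st.partition
    out: list[Subgroup] = []
    counter = itertools.count(1)

    def visit(node: Node) -> None:
        parts = {part[species_of_leaf(l.name)] for l in node.leaves()}
        if len(parts) == 1:
            p = parts.pop()
            members = sorted(l.name for l in node.leaves())
            support = node.support
            out.append(Subgroup(
                id=f"sg{next(counter)}", partition=p, members=members,
                species={species_of_leaf(m) for m in members},
                support=support,
                low_support=(support is not None and support < min_support)))
            return
        for c in node.children:
            visit(c)

    visit(rooted)
    return out


# ---------------------------------------------------------------------------
# event inference and classification


def classify_duplication(st: SpeciesTree, species_node: int,
                         recent_max_species: int = 2) -> str:
    """ancient/recent/pre-split class of a duplication mapped to a node."""
    if species_node == st.mrca_all:
        return "pre-split"
    in_dicot = st.is_ancestor(st.mrca_dicot, species_node)
    side = "dicot" if in_dicot else "grass"
    n_species = len(st.leafsets[species_node])
    return (f"recent-{side}" if n_species <= recent_max_species
            else f"ancient-{side}")


def infer_events(rooted: Node, st: SpeciesTree, subgroups: list[Subgroup],
                 cog_id: str = "cog1", recent_max_species: int = 2,
                 confirmed_absent: set[str] | None = None,
                 ) -> tuple[pd.DataFrame, Reconciliation]:
    """Duplications by LCA mapping; losses by the subgroup-absence rule.

    Duplication rows carry the ancient/recent/pre-split class of the
    species node they map to.  Loss rows (``method="subgroup"``) record,
    for each subgroup, each species of its partition absent from it.
    Reconciliation-based per-branch losses live on the returned
    :class:`Reconciliation` and feed the copy-number profile.

    `confirmed_absent` is a manual validation hook: when given, loss
    rows are flagged ``validated`` only for species in the whitelist
    (externally confirmed absences); no rows are dropped.
    """
    rec = reconcile(rooted, st)
    rows = []
    for node in rec.duplication_nodes():
        sp_node = rec.mapping[node._uid]
        cls = classify_duplication(st, sp_node, recent_max_species)
        rows.append({"cog_id": cog_id, "event": "duplication", "class": cls,
                     "species": st.node_name(sp_node),
                     "node": "|".join(sorted(l.name for l in node.leaves())),
                     "method": "reconciliation"})
    partition_species = {
        "dicot": [s for s in st.leaf_names() if st.partition[s] == "dicot"],
        "grass": [s for s in st.leaf_names() if st.partition[s] == "grass"],
    }
    for sg in subgroups:
        for sp in partition_species[sg.partition]:
            if sp not in sg.species:
                row = {"cog_id": cog_id, "event": "loss",
                       "class": sg.partition, "species": sp,
                       "node": sg.id, "method": "subgroup"}
                if confirmed_absent is not None:
                    row["validated"] = sp in confirmed_absent
                rows.append(row)
    cols = ["cog_id", "event", "class", "species", "node", "method"]
    if confirmed_absent is not None:
        cols.append("validated")
    return pd.DataFrame(rows, columns=cols), rec


def annotated_newick(rec: Reconciliation) -> str:
    """Newick of the reconciled gene tree with event labels (D/S and the
    mapped species node) on internal nodes."""
    from .tree import to_newick

    work = rec.gene_tree.copy()
    for orig, copy_node in zip(rec.gene_tree.postorder(), work.postorder()):
        if copy_node.is_leaf:
            continue
        event = rec.event[orig._uid]
        tag = "D" if event == "duplication" else "S"
        copy_node.name = f"{tag}_{rec.species_tree.node_name(rec.mapping[orig._uid])}"
    return to_newick(work)


# ---------------------------------------------------------------------------
# copy numbers


@dataclass
class CopyNumberProfile:
    """Gene counts at species-tree nodes and gains/losses per branch."""

    species_tree: SpeciesTree
    counts: dict[int, int] = field(default_factory=dict)
    gains: dict[int, int] = field(default_factory=dict)
    losses: dict[int, int] = field(default_factory=dict)

    def check_balance(self) -> None:
        st = self.species_tree
        for i, node in enumerate(st.nodes):
            p = st.parent[i]
            if p < 0:
                continue
            expect = (self.counts.get(p, 0) + self.gains.get(i, 0)
                      - self.losses.get(i, 0))
            if expect != self.counts.get(i, 0):
                raise AssertionError(
                    f"copy-number balance violated at {st.node_name(i)}: "
                    f"parent {self.counts.get(p, 0)} + gains {self.gains.get(i, 0)} "
                    f"- losses {self.losses.get(i, 0)} != {self.counts.get(i, 0)}")

    def to_frame(self) -> pd.DataFrame:
        st = self.species_tree
        rows = []
        for i in range(len(st.nodes)):
            rows.append({"node": st.node_name(i),
                         "count": self.counts.get(i, 0),
                         "gains": self.gains.get(i, 0),
                         "losses": self.losses.get(i, 0)})
        return pd.DataFrame(rows, columns=["node", "count", "gains", "losses"])


def reconstruct_copy_numbers(reconciliations: list[Reconciliation],
                             st: SpeciesTree) -> CopyNumberProfile:
    """Per-node gene counts summed over COGs, with per-branch gains and
    reconciliation losses; enforces the balance invariant."""
    prof = CopyNumberProfile(species_tree=st)
    for rec in reconciliations:
        for i, n in enumerate(st.nodes):
            prof.counts[i] = prof.counts.get(i, 0) + _lineages_crossing(rec, st, i)
        for s, g in rec.branch_gains.items():
            prof.gains[s] = prof.gains.get(s, 0) + g
        for s, l in rec.branch_losses.items():
            prof.losses[s] = prof.losses.get(s, 0) + l
        if rec.origination != st.mrca_all:
            prof.gains[rec.origination] = prof.gains.get(rec.origination, 0) + 1
    prof.check_balance()
    return prof


def _lineages_crossing(rec: Reconciliation, st: SpeciesTree, n: int) -> int:
    """Gene lineages present at species node `n`.

    A gene edge (p -> c) contributes when the lineage either ends at `n`
    (it maps there with a speciation/leaf event; a duplication happens on
    the branch above its node, before reaching it) or passes through `n`
    on its way further down.  The founding lineage occupies M(root)
    unless the root itself is a duplication (its children are counted
    there instead).
    """
    count = 0
    root = rec.gene_tree
    m_root = rec.mapping[root._uid]
    if n == m_root and rec.event[root._uid] != "duplication":
        count += 1
    for node in root.postorder():
        if node.parent is None:
            continue
        m_child = rec.mapping[node._uid]
        m_parent = rec.mapping[node.parent._uid]
        parent_dup = rec.event[node.parent._uid] == "duplication"
        if n == m_child:
            if rec.event[node._uid] != "duplication":
                count += 1
            continue
        # pass-through: strictly between the edge's end and its start
        if not st.is_ancestor(n, m_child):
            continue
        if st.is_ancestor(m_parent, n) and (m_parent != n or parent_dup):
            count += 1
    return count


# ---------------------------------------------------------------------------
# summaries

SUMMARY_COLUMNS = ["cog_id", "ancient_dicot", "ancient_grass", "recent_dicot",
                   "recent_grass", "pre_split", "loss_dicot", "loss_grass"]


def summarize_events(event_tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Table-style per-COG summary of duplication classes and subgroup
    losses, with a grand-total row."""
    rows = []
    for table in event_tables:
        if table.empty:
            continue
        cog = table["cog_id"].iloc[0]
        dup = table[table["event"] == "duplication"]
        loss = table[table["event"] == "loss"]
        rows.append({
            "cog_id": cog,
            "ancient_dicot": int((dup["class"] == "ancient-dicot").sum()),
            "ancient_grass": int((dup["class"] == "ancient-grass").sum()),
            "recent_dicot": int((dup["class"] == "recent-dicot").sum()),
            "recent_grass": int((dup["class"] == "recent-grass").sum()),
            "pre_split": int((dup["class"] == "pre-split").sum()),
            "loss_dicot": int((loss["class"] == "dicot").sum()),
            "loss_grass": int((loss["class"] == "grass").sum()),
        })
    df = pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
    total = {"cog_id": "total"}
    for c in SUMMARY_COLUMNS[1:]:
        total[c] = int(df[c].sum()) if not df.empty else 0
    return pd.concat([df, pd.DataFrame([total])], ignore_index=True)
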