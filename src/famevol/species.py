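"""The reference species tree: six dicots and five grasses.

The default tree covers the eleven angiosperm genomes the analyses are
framed around, with the dicots (Arabidopsis thaliana, Brassica rapa,
Glycine max, Medicago truncatula, Populus trichocarpa, Ricinus communis)
and the grasses (Brachypodium distachyon, Oryza sativa, Setaria italica,
Sorghum bicolor, Zea mays) each forming a monophyletic clade.  The tree
is the frame of reference for gene-tree reconciliation: duplication and
loss events are placed on its branches and ancestral copy numbers are
reported at its internal nodes.
"""

from __future__ import annotations

from .tree import Node, parse_newick, to_newick

DICOTS: tuple[str, ...] = ("Ath", "Bra", "Gma", "Mtr", "Ptr", "Rco")
GRASSES: tuple[str, ...] = ("Bdi", "Osa", "Sit", "Sbi", "Zma")

PARTITION: dict[str, str] = {**{s: "dicot" for s in DICOTS},
                             **{s: "grass" for s in GRASSES}}

_DEFAULT_NEWICK = ("(((Ath,Bra),((Gma,Mtr),(Ptr,Rco))),"
                   "((Bdi,Osa),(Sit,(Sbi,Zma))));")


class SpeciesTree:
    """Rooted binary species tree with a dicot/grass leaf partition.

    Wraps a :class:`famevol.tree.Node` and adds the lookups reconciliation
    needs: postorder indices, parent indices, per-node leaf sets, and the
    distinguished ancestors MRCA_all / MRCA_dicot / MRCA_grass.
    """

    def __init__(self, root: Node, partition: dict[str, str] | None = None):
        self.root = root
        self.partition = dict(partition or PARTITION)
        leaves = root.leaf_names()
        unknown = [l for l in leaves if l not in self.partition]
        if unknown:
            raise ValueError(f"leaves without a dicot/grass label: {unknown}")
        self._index()

    def _index(self) -> None:
        self.nodes: list[Node] = list(self.root.postorder())
        self.index: dict[int, int] = {n._uid: i for i, n in enumerate(self.nodes)}
        self.parent = [self.index[n.parent._uid] if n.parent else -1 for n in self.nodes]
        self.leafsets: list[frozenset[str]] = [
            frozenset(l.name for l in n.leaves()) for n in self.nodes
        ]
        self._leaf_idx = {n.name: i for i, n in enumerate(self.nodes) if n.is_leaf}
        depth = [0] * len(self.nodes)
        for i in reversed(range(len(self.nodes))):  # preorder over postorder list
            p = self.parent[i]
            if p >= 0:
                depth[i] = depth[p] + 1
        self.depth = depth

    # -- distinguished nodes -------------------------------------------
    def node_index_of(self, names: set[str]) -> int:
        """Index (postorder) of the LCA of a set of leaf names."""
        idxs = [self._leaf_idx[n] for n in names]
        cur = idxs[0]
        for other in idxs[1:]:
            a, b = cur, other
            while a != b:
                if self.depth[a] >= self.depth[b]:
                    a = self.parent[a]
                else:
                    b = self.parent[b]
            cur = a
        return cur

    @property
    def mrca_all(self) -> int:
        return len(self.nodes) - 1

    @property
    def mrca_dicot(self) -> int:
        return self.node_index_of({s for s in self.leaf_names() if self.partition[s] == "dicot"})

    @property
    def mrca_grass(self) -> int:
        return self.node_index_of({s for s in self.leaf_names() if self.partition[s] == "grass"})

    def leaf_names(self) -> list[str]:
        return self.root.leaf_names()

    def is_ancestor(self, anc: int, desc: int) -> bool:
        """True if node `anc` is `desc` or an ancestor of it."""
        while desc != -1:
            if desc == anc:
                return True
            desc = self.parent[desc]
        return False

    def node_name(self, i: int) -> str:
        node = self.nodes[i]
        if node.is_leaf:
            return node.name
        if i == self.mrca_all:
            return "MRCA_all"
        if i == self.mrca_dicot:
            return "MRCA_dicot"
        if i == self.mrca_grass:
            return "MRCA_grass"
        return "anc_" + "+".join(sorted(self.leafsets[i]))

    def to_newick(self) -> str:
        return to_newick(self.root)


def build_default_species_tree(branch_length: float = 1.0) -> SpeciesTree:
    """The fixed 11-taxon dicot/grass species tree with unit branch lengths.

    Topology follows accepted angiosperm relationships:
    ``((Ath,Bra),((Gma,Mtr),(Ptr,Rco)))`` for the dicots and
    ``((Bdi,Osa),(Sit,(Sbi,Zma)))`` for the grasses, joined at the root.
    """
    root = parse_newick(_DEFAULT_NEWICK)
    for node in root.postorder():
        if node.parent is not None:
            node.length = branch_length
    return SpeciesTree(root)
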