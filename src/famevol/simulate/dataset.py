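"""End-to-end synthetic dataset generation and serialization.

`generate_dataset` strings the pieces together: birth-death gene family
histories on the species tree, codon alignments evolved down each gene
tree (branch lengths scaled from time units to expected substitutions
per codon by ``subst_rate``), and optional planted artifacts.
`write_dataset` emits everything as plain text (FASTA, newick, TSV) with
a SHA-256 manifest; identical seed and config give identical bytes.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ..genetic_code import translate_cds
from ..species import SpeciesTree, build_default_species_tree
from ..tree import Node, to_newick
from .artifacts import GeneRecord, plant_alleles, plant_fragments
from .birth_death import GeneFamilyHistory, simulate_family
from .codon_sim import CodonAlignmentTruth, simulate_codon_alignment
from .config import SimulationConfig

__all__ = ["FamilyData", "SyntheticDataset", "generate_dataset", "write_dataset"]


@dataclass
class FamilyData:
    family_id: str
    history: GeneFamilyHistory
    alignments: list[CodonAlignmentTruth] = field(default_factory=list)

    def gene_trees(self) -> list[Node]:
        return self.history.gene_trees


@dataclass
class SyntheticDataset:
    species_tree: SpeciesTree
    config: SimulationConfig
    families: list[FamilyData]
    records: list[GeneRecord]
    artifact_truth: pd.DataFrame

    def records_by_id(self) -> dict[str, GeneRecord]:
        return {r.id: r for r in self.records}


def _scaled_copy(tree: Node, factor: float) -> Node:
    out = tree.copy()
    for n in out.postorder():
        n.length *= factor
    return out


def generate_dataset(cfg: SimulationConfig, n_families: int = 1,
                     species_tree: SpeciesTree | None = None,
                     n_alleles: int = 0, n_fragments: int = 0) -> SyntheticDataset:
    """Simulate `n_families` gene families with sequences and artifacts."""
    st = species_tree or build_default_species_tree()
    rng = np.random.default_rng(cfg.seed)
    families: list[FamilyData] = []
    records: list[GeneRecord] = []
    for f in range(1, n_families + 1):
        fam_id = f"fam{f}"
        hist = simulate_family(st, cfg, rng=rng, family_id=fam_id)
        fam = FamilyData(family_id=fam_id, history=hist)
        for gt in hist.gene_trees:
            scaled = _scaled_copy(gt, cfg.subst_rate)
            truth = simulate_codon_alignment(scaled, cfg, rng=rng)
            fam.alignments.append(truth)
            for gid, cds in truth.sequences.items():
                species = gid.split("_", 1)[0]
                records.append(GeneRecord(id=gid, species=species,
                                          family=fam_id, cds=cds))
        families.append(fam)

    truth_frames = []
    if n_alleles:
        records, t = plant_alleles(records, n_alleles, cfg.allele_identity, rng)
        truth_frames.append(t)
    if n_fragments:
        records, t = plant_fragments(records, n_fragments, cfg.fragment_length_nt, rng)
        truth_frames.append(t)
    artifact_truth = (pd.concat(truth_frames, ignore_index=True) if truth_frames
                      else pd.DataFrame(columns=["record_id", "kind", "source_id",
                                                 "identity", "length_nt"]))
    return SyntheticDataset(species_tree=st, config=cfg, families=families,
                            records=records, artifact_truth=artifact_truth)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_dataset(dataset: SyntheticDataset, out_dir) -> dict[str, str]:
    """Write the dataset as plain-text files; returns {path: sha256}."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    cds_recs, prot_recs = [], []
    for r in dataset.records:
        prot = translate_cds(r.cds)  # raises on internal stops (simulator bug)
        cds_recs.append(SeqRecord(Seq(r.cds), id=r.id, description=""))
        prot_recs.append(SeqRecord(Seq(prot), id=r.id, description=""))
    SeqIO.write(cds_recs, out / "cds.fasta", "fasta")
    SeqIO.write(prot_recs, out / "proteins.fasta", "fasta")

    with open(out / "species_tree.nwk", "w") as fh:
        fh.write(dataset.species_tree.to_newick() + "\n")
    with open(out / "gene_trees.nwk", "w") as fh:
        for fam in dataset.families:
            for gt in fam.gene_trees():
                fh.write(to_newick(gt) + "\n")

    events = pd.concat(
        [fam.history.events.assign(family=fam.family_id)
         for fam in dataset.families],
        ignore_index=True) if dataset.families else pd.DataFrame()
    events.to_csv(out / "truth_events.tsv", sep="\t", index=False,
                  lineterminator="\n")

    site_rows = []
    for fam in dataset.families:
        for k, truth in enumerate(fam.alignments):
            for site, cls in enumerate(truth.site_class):
                site_rows.append({"family": fam.family_id, "tree": k,
                                  "site": site, "class": int(cls)})
    pd.DataFrame(site_rows, columns=["family", "tree", "site", "class"]).to_csv(
        out / "truth_site_classes.tsv", sep="\t", index=False, lineterminator="\n")

    dataset.artifact_truth.to_csv(out / "truth_artifacts.tsv", sep="\t",
                                  index=False, lineterminator="\n")
    dataset.config.to_yaml(out / "config.yaml")

    names = ["cds.fasta", "proteins.fasta", "species_tree.nwk", "gene_trees.nwk",
             "truth_events.tsv", "truth_site_classes.tsv", "truth_artifacts.tsv",
             "config.yaml"]
    return {name: _sha256(out / name) for name in names}
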