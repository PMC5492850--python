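"""Sequence filtering and Clusters of Orthologous Groups (COGs).

The clustering stage mirrors the classic COG protocol: for every gene
and every foreign species, find the best-scoring homolog (the BeT);
edges that are mutual are *reciprocal*, the rest *asymmetric*; triangles
of reciprocal BeTs spanning three species are merged (transitively,
whenever two triangles share an edge) into COGs, which therefore capture
one-to-one, one-to-many and many-to-many orthology.

Before clustering, two filters clean the input the way a curated
transcript set would be cleaned: same-species records that align
end-to-end without indels at high DNA identity are treated as alleles
(one representative kept), and short fragments are dropped.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import pandas as pd
from Bio import Align, SeqIO
from Bio.Align import substitution_matrices

from .genetic_code import translate_cds

__all__ = ["SequenceRecord", "load_records", "filter_sequences", "score_all_pairs",
           "load_hit_table", "compute_bets", "build_cogs", "cog_report", "BeTGraph",
           "COG"]


@dataclass(frozen=True)
class SequenceRecord:
    id: str
    species: str
    cds: str
    protein: str

    @property
    def length_nt(self) -> int:
        return len(self.cds)


def load_records(cds_fasta, species_of=None) -> list[SequenceRecord]:
    """Read CDS FASTA into records; species defaults to the id prefix
    (ids follow ``<species>_<family>_<serial>``)."""
    records = []
    for rec in SeqIO.parse(str(cds_fasta), "fasta"):
        cds = str(rec.seq).upper()
        species = species_of[rec.id] if species_of else rec.id.split("_", 1)[0]
        records.append(SequenceRecord(id=rec.id, species=species, cds=cds,
                                      protein=translate_cds(cds)))
    return records


# ---------------------------------------------------------------------------
# filters

_DNA_MATCH, _DNA_MISMATCH = 2.0, -3.0
_DNA_OPEN, _DNA_EXTEND = -5.0, -2.0


def _dna_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = _DNA_MATCH
    a.mismatch_score = _DNA_MISMATCH
    a.open_gap_score = _DNA_OPEN
    a.extend_gap_score = _DNA_EXTEND
    return a


def _is_allele_pair(a: str, b: str, identity_threshold: float,
                    aligner: Align.PairwiseAligner) -> bool:
    """True iff a gap-free alignment of a and b is optimal under the
    global scheme AND its identity exceeds the threshold.

    Only equal-length pairs can align gap-free; for those the ungapped
    alignment is optimal iff its score matches the optimal score.
    """
    if len(a) != len(b):
        return False
    matches = sum(x == y for x, y in zip(a, b))
    identity = matches / len(a)
    if identity <= identity_threshold:
        return False
    ungapped_score = matches * _DNA_MATCH + (len(a) - matches) * _DNA_MISMATCH
    return ungapped_score >= aligner.score(a, b) - 1e-9


def filter_sequences(records: list[SequenceRecord], min_len_nt: int = 400,
                     allele_identity: float = 0.95,
                     max_length_diff: float = 0.05,
                     ) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Remove short sequences and allele-like same-species duplicates.

    Length filtering comes first; then, within each species, pairs whose
    lengths differ by at most `max_length_diff` are globally aligned and
    called alleles when the optimal alignment is indel-free with DNA
    identity above `allele_identity`.  From each connected component of
    allele pairs the longest CDS is kept (ties broken by smallest id).

    Returns the kept records and a removal report with one row per
    removed record (columns ``id``, ``reason``, ``detail``).
    """
    report_rows = []
    valid: list[SequenceRecord] = []
    for r in records:
        try:
            expected = translate_cds(r.cds)
        except ValueError as exc:
            report_rows.append({"id": r.id, "reason": "invalid_cds", "detail": str(exc)})
            continue
        if r.protein != expected:
            report_rows.append({"id": r.id, "reason": "translation_mismatch",
                                "detail": "protein differs from CDS translation"})
            continue
        valid.append(r)

    long_enough = []
    for r in valid:
        if r.length_nt < min_len_nt:
            report_rows.append({"id": r.id, "reason": "short",
                                "detail": f"{r.length_nt} nt < {min_len_nt} nt"})
        else:
            long_enough.append(r)

    aligner = _dna_aligner()
    by_species: dict[str, list[SequenceRecord]] = {}
    for r in long_enough:
        by_species.setdefault(r.species, []).append(r)

    # union-find over allele pairs
    parent: dict[str, str] = {r.id: r.id for r in long_enough}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for species, group in by_species.items():
        for a, b in itertools.combinations(group, 2):
            la, lb = a.length_nt, b.length_nt
            if abs(la - lb) > max_length_diff * max(la, lb):
                continue
            if _is_allele_pair(a.cds, b.cds, allele_identity, aligner):
                ra, rb = find(a.id), find(b.id)
                if ra != rb:
                    parent[ra] = rb

    components: dict[str, list[SequenceRecord]] = {}
    for r in long_enough:
        components.setdefault(find(r.id), []).append(r)

    kept: list[SequenceRecord] = []
    for comp in components.values():
        comp.sort(key=lambda r: (-r.length_nt, r.id))
        rep = comp[0]
        kept.append(rep)
        for other in comp[1:]:
            report_rows.append({"id": other.id, "reason": "allele",
                                "detail": f"allele of {rep.id}"})
    kept.sort(key=lambda r: r.id)
    report = pd.DataFrame(report_rows, columns=["id", "reason", "detail"])
    return kept, report


# ---------------------------------------------------------------------------
# similarity scoring

HIT_COLUMNS = ["query", "subject", "score", "pident", "length"]

_OUTFMT6 = ["qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
            "qstart", "qend", "sstart", "send", "evalue", "bitscore"]


def _protein_aligner() -> Align.PairwiseAligner:
    # blast-style affine costs: a gap of length k costs 11 + k, so the
    # first gapped position scores -(11 + 1) under Biopython's convention
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.substitution_matrix = substitution_matrices.load("BLOSUM62")
    a.open_gap_score = -12.0
    a.extend_gap_score = -1.0
    return a


def score_all_pairs(records: list[SequenceRecord]) -> pd.DataFrame:
    """All-against-all Smith-Waterman protein similarity (BLOSUM62,
    affine gaps open 11 / extend 1).  Self-hits are not retained.
    The scheme is symmetric, so each unordered pair is aligned once and
    reported in both directions."""
    aligner = _protein_aligner()
    rows = []
    for a, b in itertools.combinations(records, 2):
        aln = aligner.align(a.protein, b.protein)[0]
        score = aln.score
        counts = aln.counts()
        ncols = counts.identities + counts.mismatches + counts.gaps
        pident = 100.0 * counts.identities / max(counts.identities + counts.mismatches, 1)
        rows.append({"query": a.id, "subject": b.id, "score": float(score),
                     "pident": pident, "length": int(ncols)})
        rows.append({"query": b.id, "subject": a.id, "score": float(score),
                     "pident": pident, "length": int(ncols)})
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


def load_hit_table(path, valid_ids: set[str]) -> pd.DataFrame:
    """Ingest a blast outfmt-6-style 12-column TSV as a hit table."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] != 12:
        raise ValueError(f"expected 12 columns, found {df.shape[1]}")
    df.columns = _OUTFMT6
    unknown = (set(df["qseqid"]) | set(df["sseqid"])) - set(valid_ids)
    if unknown:
        raise ValueError(f"hit table references unknown ids: {sorted(unknown)[:5]}")
    out = pd.DataFrame({"query": df["qseqid"], "subject": df["sseqid"],
                        "score": df["bitscore"].astype(float),
                        "pident": df["pident"].astype(float),
                        "length": df["length"].astype(int)})
    out = out[out["query"] != out["subject"]].reset_index(drop=True)
    if (out["score"] < 0).any() or not out["score"].notna().all():
        raise ValueError("scores must be finite and >= 0")
    return out


# ---------------------------------------------------------------------------
# BeT graph and COGs


@dataclass
class BeTGraph:
    """Directed best-hit edges with reciprocal/asymmetric labels."""

    bets: dict[tuple[str, str], str]     # (gene, foreign species) -> best subject
    species_of: dict[str, str]
    scores: dict[tuple[str, str], float] = field(default_factory=dict)

    def edges(self) -> list[tuple[str, str, str]]:
        """(gene, target, label) with label reciprocal|asymmetric."""
        out = []
        for (g, _), h in sorted(self.bets.items()):
            out.append((g, h, "reciprocal" if self.is_reciprocal(g, h) else "asymmetric"))
        return out

    def is_reciprocal(self, g: str, h: str) -> bool:
        return self.bets.get((h, self.species_of[g])) == g

    def reciprocal_pairs(self) -> set[frozenset[str]]:
        return {frozenset((g, h)) for (g, _), h in self.bets.items()
                if self.is_reciprocal(g, h)}


def compute_bets(hits: pd.DataFrame, species_of: dict[str, str]) -> BeTGraph:
    """Best hiT per (gene, foreign species); ties broken by higher
    identity, then smaller subject id."""
    if hits.empty:
        raise ValueError("hit table is empty")
    df = hits.copy()
    df["qspecies"] = df["query"].map(species_of)
    df["sspecies"] = df["subject"].map(species_of)
    if df["qspecies"].isna().any() or df["sspecies"].isna().any():
        missing = set(df.loc[df["qspecies"].isna(), "query"]) | \
            set(df.loc[df["sspecies"].isna(), "subject"])
        raise ValueError(f"genes without species assignment: {sorted(missing)[:5]}")
    df = df[df["qspecies"] != df["sspecies"]]
    df = df.sort_values(["query", "sspecies", "score", "pident", "subject"],
                        ascending=[True, True, False, False, True],
                        kind="mergesort")
    best = df.groupby(["query", "sspecies"], sort=True).first().reset_index()
    bets = {(r["query"], r["sspecies"]): r["subject"] for _, r in best.iterrows()}
    scores = {(r["query"], r["subject"]): float(r["score"]) for _, r in best.iterrows()}
    return BeTGraph(bets=bets, species_of=dict(species_of), scores=scores)


@dataclass
class COG:
    id: str
    core: list[str]
    satellites: list[str] = field(default_factory=list)
    edges: list[tuple[str, str, str]] = field(default_factory=list)

    @property
    def members(self) -> list[str]:
        return sorted(self.core) + sorted(self.satellites)

    def species_coverage(self, species_of, partition) -> dict[str, int]:
        species = {species_of[g] for g in self.members}
        return {"dicot": sum(partition.get(s) == "dicot" for s in species),
                "grass": sum(partition.get(s) == "grass" for s in species)}


def build_cogs(bets: BeTGraph, include_satellites: bool = True) -> list[COG]:
    """Triangle-seeded COGs.

    Triangles of reciprocal BeT edges spanning three distinct species
    are enumerated; triangles sharing an edge are merged transitively.
    Genes outside every triangle are attached as non-core satellites to
    the COG of their best-scoring partner, when that partner is core.
    """
    pairs = bets.reciprocal_pairs()
    adj: dict[str, set[str]] = {}
    for p in pairs:
        a, b = sorted(p)
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)

    # union-find over reciprocal edges, merged through shared triangles
    parent: dict[frozenset, frozenset] = {p: p for p in pairs}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[rx] = ry

    sp = bets.species_of
    triangle_edges: set[frozenset] = set()
    for a in sorted(adj):
        for b in sorted(adj[a]):
            if b <= a:
                continue
            for c in sorted(adj[a] & adj[b]):
                if c <= b:
                    continue
                if len({sp[a], sp[b], sp[c]}) != 3:
                    continue
                e1, e2, e3 = frozenset((a, b)), frozenset((b, c)), frozenset((a, c))
                union(e1, e2)
                union(e2, e3)
                triangle_edges.update((e1, e2, e3))

    clusters: dict[frozenset, set[str]] = {}
    for e in triangle_edges:
        clusters.setdefault(find(e), set()).update(e)

    cores = sorted(clusters.values(), key=lambda s: min(s))
    gene_to_cog: dict[str, int] = {}
    for i, core in enumerate(cores):
        for g in core:
            gene_to_cog[g] = i

    satellites: dict[int, set[str]] = {i: set() for i in range(len(cores))}
    if include_satellites:
        candidates: dict[str, tuple[float, int]] = {}
        for (g, _), h in sorted(bets.bets.items()):
            if g in gene_to_cog or h not in gene_to_cog:
                continue
            score = bets.scores.get((g, h), 0.0)
            best = candidates.get(g)
            if best is None or score > best[0]:
                candidates[g] = (score, gene_to_cog[h])
        for g, (_, i) in candidates.items():
            satellites[i].add(g)

    cogs = []
    for i, core in enumerate(cores):
        members = core | satellites[i]
        edges = [(a, b, lab) for a, b, lab in bets.edges()
                 if a in members and b in members]
        cogs.append(COG(id=f"cog{i + 1}", core=sorted(core),
                        satellites=sorted(satellites[i]), edges=edges))
    return cogs


def cog_report(cogs: list[COG], species_of: dict[str, str],
               partition: dict[str, str], n_dicots: int = 6,
               n_grasses: int = 5) -> pd.DataFrame:
    """Per-COG membership counts and completeness flags (flags only —
    nothing is filtered)."""
    rows = []
    for cog in cogs:
        members = cog.members
        d_members = sum(partition.get(species_of[g]) == "dicot" for g in members)
        g_members = sum(partition.get(species_of[g]) == "grass" for g in members)
        cov = cog.species_coverage(species_of, partition)
        complete = d_members >= n_dicots and g_members >= n_grasses
        rows.append({"cog_id": cog.id, "n_members": len(members),
                     "n_core": len(cog.core),
                     "dicot_members": d_members, "grass_members": g_members,
                     "dicot_species": cov["dicot"], "grass_species": cov["grass"],
                     "flag": "complete" if complete else "incomplete"})
    return pd.DataFrame(rows, columns=["cog_id", "n_members", "n_core",
                                       "dicot_members", "grass_members",
                                       "dicot_species", "grass_species", "flag"])


def write_membership_tsv(cogs: list[COG], species_of: dict[str, str], path) -> None:
    rows = []
    for cog in cogs:
        for g in sorted(cog.core):
            rows.append({"cog_id": cog.id, "gene_id": g,
                         "species": species_of[g], "role": "core"})
        for g in sorted(cog.satellites):
            rows.append({"cog_id": cog.id, "gene_id": g,
                         "species": species_of[g], "role": "satellite"})
    pd.DataFrame(rows, columns=["cog_id", "gene_id", "species", "role"]).to_csv(
        path, sep="\t", index=False, lineterminator="\n")


def write_cog_dot(cog: COG, path) -> None:
    """DOT-format graph of one COG (solid = reciprocal, dashed = asymmetric)."""
    seen = set()
    with open(path, "w") as fh:
        fh.write(f'graph "{cog.id}" {{\n')
        for g in cog.members:
            shape = "ellipse" if g in cog.core else "box"
            fh.write(f'  "{g}" [shape={shape}];\n')
        for a, b, lab in cog.edges:
            key = frozenset((a, b))
            if lab == "reciprocal":
                if key in seen:
                    continue
                seen.add(key)
                fh.write(f'  "{a}" -- "{b}";\n')
            else:
                fh.write(f'  "{a}" -- "{b}" [style=dashed];\n')
        fh.write("}\n")
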