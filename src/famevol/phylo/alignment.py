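"""Protein alignments: container, column-quality scores, filtering, and
protein-to-codon back-translation.

Column quality is scored on a 0-100 scale from the mean BLOSUM62 value
over all residue pairs in the column (pairs involving a gap contribute
the matrix minimum), linearly rescaled so the matrix minimum maps to 0
and the maximum (W/W) to 100.  The default retention cutoff of 12 keeps
columns that score above the most weakly conserved end of the scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import SeqIO
from Bio.Align import substitution_matrices

from ..genetic_code import translate_cds

__all__ = ["ProteinAlignment", "column_scores", "filter_columns", "back_translate"]

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
GAP_CODE = 20
_AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}


@dataclass
class ProteinAlignment:
    """Aligned protein rows as a (n_sequences, n_columns) uint8 matrix.

    Codes 0-19 are amino acids in ``AA_ALPHABET`` order; 20 is the gap.
    """

    ids: list[str]
    matrix: np.ndarray

    def __post_init__(self):
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate sequence ids")
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.ids):
            raise ValueError("matrix shape does not match ids")

    @classmethod
    def from_strings(cls, seqs: dict[str, str]) -> "ProteinAlignment":
        ids = list(seqs)
        lengths = {len(s) for s in seqs.values()}
        if len(lengths) != 1:
            raise ValueError(f"unequal row lengths: {sorted(lengths)}")
        mat = np.empty((len(ids), lengths.pop()), dtype=np.uint8)
        for i, sid in enumerate(ids):
            for j, ch in enumerate(seqs[sid].upper()):
                mat[i, j] = _AA_INDEX.get(ch, GAP_CODE) if ch != "-" else GAP_CODE
        return cls(ids=ids, matrix=mat)

    @classmethod
    def from_fasta(cls, path) -> "ProteinAlignment":
        return cls.from_strings({r.id: str(r.seq) for r in SeqIO.parse(str(path), "fasta")})

    def to_strings(self) -> dict[str, str]:
        lookup = AA_ALPHABET + "-"
        return {sid: "".join(lookup[c] for c in self.matrix[i])
                for i, sid in enumerate(self.ids)}

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    @property
    def n_sequences(self) -> int:
        return self.matrix.shape[0]

    def take_columns(self, idx: np.ndarray) -> "ProteinAlignment":
        return ProteinAlignment(ids=list(self.ids), matrix=self.matrix[:, idx])


def _blosum_pair_matrix() -> tuple[np.ndarray, float, float]:
    """(21x21 pair score matrix incl. gap row/col at the minimum,
    matrix min, matrix max) over the 20 standard amino acids."""
    b = substitution_matrices.load("BLOSUM62")
    sub = np.array([[b[a1, a2] for a2 in AA_ALPHABET] for a1 in AA_ALPHABET],
                   dtype=float)
    lo, hi = sub.min(), sub.max()
    full = np.full((21, 21), lo)
    full[:20, :20] = sub
    return full, lo, hi


def column_scores(aln: ProteinAlignment) -> np.ndarray:
    """Per-column conservation on a 0-100 scale (see module docstring)."""
    if aln.n_sequences < 2:
        raise ValueError("need at least 2 sequences")
    if aln.n_columns == 0:
        raise ValueError("empty alignment")
    pair_scores, lo, hi = _blosum_pair_matrix()
    n = aln.n_sequences
    # per-column symbol counts -> mean over all unordered pairs
    counts = np.zeros((21, aln.n_columns), dtype=np.int64)
    for code in range(21):
        counts[code] = (aln.matrix == code).sum(axis=0)
    # sum over ordered pairs incl. self, then remove self-pairs
    total = np.einsum("ic,jc,ij->c", counts, counts, pair_scores)
    self_scores = np.diag(pair_scores)  # per-symbol self score
    total -= (counts * self_scores[:, None]).sum(axis=0)
    n_pairs = n * (n - 1)  # ordered
    mean = total / n_pairs
    return 100.0 * (mean - lo) / (hi - lo)


def filter_columns(aln: ProteinAlignment, threshold: float = 12.0,
                   ) -> tuple[ProteinAlignment, np.ndarray]:
    """Keep columns scoring strictly above `threshold`.

    Returns the filtered alignment and the original-column index of each
    kept column (needed to map codon positions and reported sites back
    to the input coordinates).
    """
    scores = column_scores(aln)
    kept = np.flatnonzero(scores > threshold)
    if kept.size == 0:
        raise ValueError("all columns removed; review the score threshold")
    return aln.take_columns(kept), kept


def back_translate(aln: ProteinAlignment, cds_by_id: dict[str, str],
                   kept_column_map: np.ndarray | None = None) -> dict[str, str]:
    """Expand each aligned amino acid to its source codon.

    Every ungapped residue must match the translation of its codon; a
    mismatch raises with the sequence id and alignment position.  When
    `kept_column_map` is given, only those original columns are emitted.
    Gap columns become ``---``.
    """
    rows = aln.to_strings()
    out: dict[str, str] = {}
    for sid, row in rows.items():
        cds = cds_by_id[sid]
        protein = translate_cds(cds)
        codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
        expanded: list[str] = []
        k = 0  # residue index into the ungapped sequence
        for pos, ch in enumerate(row):
            if ch == "-":
                expanded.append("---")
                continue
            if k >= len(protein) or protein[k] != ch:
                raise ValueError(
                    f"{sid}: aligned residue {ch!r} at alignment column {pos} "
                    f"does not match CDS translation")
            expanded.append(codons[k])
            k += 1
        if k != len(protein):
            raise ValueError(f"{sid}: alignment uses {k} residues but CDS "
                             f"translates to {len(protein)}")
        out[sid] = expanded
    if kept_column_map is not None:
        idx = np.asarray(kept_column_map, dtype=int)
        out = {sid: [cods[i] for i in idx] for sid, cods in out.items()}
    return {sid: "".join(cods) for sid, cods in out.items()}
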