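"""Standard genetic code tables shared by the simulator and the codon models.

The package works exclusively with the standard (universal) nuclear code:
61 sense codons, 3 stops.  Codons are indexed in lexicographic order over
the alphabet ACGT; every codon-state vector and rate matrix in the package
follows this ordering.
"""

from __future__ import annotations

import itertools

from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

NUCS = "ACGT"

STOP_CODONS: tuple[str, ...] = tuple(sorted(standard_dna_table.stop_codons))
CODONS: tuple[str, ...] = tuple(
    c for c in ("".join(p) for p in itertools.product(NUCS, repeat=3))
    if c not in STOP_CODONS
)
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(CODONS)}
N_CODONS = len(CODONS)  # 61

CODON_AA: dict[str, str] = {c: standard_dna_table.forward_table[c] for c in CODONS}
AA_OF: tuple[str, ...] = tuple(CODON_AA[c] for c in CODONS)

_PURINES = frozenset("AG")


def is_transition(a: str, b: str) -> bool:
    """A<->G or C<->T single-nucleotide change."""
    return (a in _PURINES) == (b in _PURINES)


def translate_cds(cds: str) -> str:
    """Standard-code translation of an in-frame CDS (no internal stops allowed)."""
    if len(cds) % 3:
        raise ValueError(f"CDS length {len(cds)} is not a multiple of 3")
    prot = str(Seq(cds).translate(table=standard_dna_table))
    if "*" in prot:
        raise ValueError("CDS contains an internal stop codon")
    return prot


def codons_of(cds: str) -> list[str]:
    if len(cds) % 3:
        raise ValueError(f"sequence length {len(cds)} is not a multiple of 3")
    return [cds[i:i + 3] for i in range(0, len(cds), 3)]
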