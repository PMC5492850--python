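"""Planted filter-exercising artifacts.

Real transcript collections contain records the clustering stage must
discard: near-identical same-species entries that are alleles (or
assembly redundancy) rather than paralogs, and short fragments.  This
module plants both kinds with known truth so the filters' recall and
false-removal rate are measurable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from ..genetic_code import STOP_CODONS

__all__ = ["GeneRecord", "plant_alleles", "plant_fragments"]

_NUCS = "ACGT"


@dataclass(frozen=True)
class GeneRecord:
    """One CDS record with its species tag and provenance flags."""

    id: str
    species: str
    family: str
    cds: str
    planted: str | None = None   # None | "allele" | "fragment"
    source_id: str | None = None


def _mutate_no_stops(cds: str, n_subs: int, rng: np.random.Generator) -> str:
    """Apply `n_subs` point substitutions, never creating a stop codon."""
    seq = list(cds)
    positions = rng.permutation(len(seq))
    done = 0
    for pos in positions:
        if done == n_subs:
            break
        original = seq[pos]
        choices = [n for n in _NUCS if n != original]
        rng.shuffle(choices)
        for new in choices:
            seq[pos] = new
            cstart = (pos // 3) * 3
            if "".join(seq[cstart:cstart + 3]) not in STOP_CODONS:
                done += 1
                break
            seq[pos] = original
    if done < n_subs:
        raise RuntimeError("could not place requested substitutions without stops")
    return "".join(seq)


def plant_alleles(records: list[GeneRecord], n: int, identity: float,
                  rng: np.random.Generator) -> tuple[list[GeneRecord], pd.DataFrame]:
    """Add `n` allele-like copies of randomly chosen genes.

    Copies have the same length, no indels, and are point-mutated to the
    configured DNA identity.  Returns (augmented records, truth rows).
    """
    if not 0.0 < identity <= 1.0:
        raise ValueError("identity must lie in (0, 1]")
    originals = [r for r in records if r.planted is None]
    if not originals:
        raise ValueError("no source records to copy")
    idx = rng.choice(len(originals), size=n, replace=n > len(originals))
    out = list(records)
    rows = []
    for k, i in enumerate(idx, 1):
        src = originals[int(i)]
        n_subs = int(round((1.0 - identity) * len(src.cds)))
        mutated = _mutate_no_stops(src.cds, n_subs, rng)
        rec = GeneRecord(id=f"{src.species}_{src.family}_a{k}", species=src.species,
                         family=src.family, cds=mutated, planted="allele",
                         source_id=src.id)
        out.append(rec)
        achieved = sum(a == b for a, b in zip(src.cds, mutated)) / len(src.cds)
        rows.append({"record_id": rec.id, "kind": "allele", "source_id": src.id,
                     "identity": achieved, "length_nt": len(mutated)})
    return out, pd.DataFrame(rows)


def plant_fragments(records: list[GeneRecord], n: int, length_nt: int,
                    rng: np.random.Generator) -> tuple[list[GeneRecord], pd.DataFrame]:
    """Add `n` truncated copies of `length_nt` nucleotides (rounded down
    to a codon boundary so the record still translates)."""
    length_nt -= length_nt % 3
    originals = [r for r in records if r.planted is None and len(r.cds) > length_nt]
    if not originals:
        raise ValueError("no source records longer than the fragment length")
    idx = rng.choice(len(originals), size=n, replace=n > len(originals))
    out = list(records)
    rows = []
    for k, i in enumerate(idx, 1):
        src = originals[int(i)]
        rec = GeneRecord(id=f"{src.species}_{src.family}_f{k}", species=src.species,
                         family=src.family, cds=src.cds[:length_nt],
                         planted="fragment", source_id=src.id)
        out.append(rec)
        rows.append({"record_id": rec.id, "kind": "fragment", "source_id": src.id,
                     "identity": 1.0, "length_nt": length_nt})
    return out, pd.DataFrame(rows)
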