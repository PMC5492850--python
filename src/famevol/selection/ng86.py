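"""Nei-Gojobori (1986) pairwise dN/dS with Jukes-Cantor correction.

Synonymous and nonsynonymous *sites* are counted per codon from the
nine possible single-nucleotide changes (changes creating a stop codon
count as nonsynonymous); observed differences between a codon pair are
averaged over all minimal mutational paths, skipping paths that pass
through a stop codon (falling back to all paths if every path does).
Proportions are corrected with the Jukes-Cantor formula.  This counting
estimator is deliberately simple: it serves as the independent
cross-check for the ML pairwise estimator.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from ..genetic_code import CODON_AA, CODONS, NUCS, STOP_CODONS, codons_of

__all__ = ["PairwiseOmega", "ng86_pairwise", "syn_nonsyn_sites", "path_differences"]


@dataclass
class PairwiseOmega:
    pair: tuple[str, str]
    dn: float
    ds: float
    omega: float          # nan when undefined (ds == 0 or saturated)
    method: str
    saturated: bool = False
    undefined: bool = False
    lnl: float | None = None
    t: float | None = None
    kappa: float | None = None


@lru_cache(maxsize=None)
def syn_nonsyn_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts for one codon; sums to 3."""
    aa = CODON_AA[codon]
    syn = 0.0
    for pos in range(3):
        for nuc in NUCS:
            if nuc == codon[pos]:
                continue
            alt = codon[:pos] + nuc + codon[pos + 1:]
            if alt not in STOP_CODONS and CODON_AA[alt] == aa:
                syn += 1.0 / 3.0
    return syn, 3.0 - syn


@lru_cache(maxsize=None)
def path_differences(a: str, b: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between codons a and b,
    averaged over all minimal mutational paths.

    Paths traversing a stop codon are excluded; if every path is blocked
    the average is over all paths.
    """
    positions = [i for i in range(3) if a[i] != b[i]]
    if not positions:
        return 0.0, 0.0
    valid: list[tuple[float, float]] = []
    blocked: list[tuple[float, float]] = []
    for order in itertools.permutations(positions):
        cur = a
        syn = non = 0.0
        hit_stop = False
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS:
                hit_stop = True
            if (CODON_AA.get(cur) or "*") == (CODON_AA.get(nxt) or "*") and \
                    nxt not in STOP_CODONS and cur not in STOP_CODONS:
                syn += 1.0
            else:
                non += 1.0
            cur = nxt
        (blocked if hit_stop else valid).append((syn, non))
    pool = valid if valid else blocked
    s = sum(p[0] for p in pool) / len(pool)
    n = sum(p[1] for p in pool) / len(pool)
    return s, n


def _jukes_cantor(p: float) -> tuple[float, bool]:
    if p < 0:
        raise ValueError("proportion must be >= 0")
    if p >= 0.75:
        return float("inf"), True
    return -0.75 * np.log(1.0 - 4.0 * p / 3.0), False


def ng86_pairwise(seq_a: str, seq_b: str, ids: tuple[str, str] = ("a", "b"),
                  ) -> PairwiseOmega:
    """NG86 dN/dS for an aligned pair of CDS; gap codons are deleted
    pairwise, sequences must be equal length with no internal stops."""
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must be aligned to equal length")
    cod_a, cod_b = codons_of(seq_a), codons_of(seq_b)
    s_sites = n_sites = 0.0
    s_diff = n_diff = 0.0
    for ca, cb in zip(cod_a, cod_b):
        if "-" in ca or "-" in cb:
            continue
        if ca in STOP_CODONS or cb in STOP_CODONS:
            raise ValueError("internal stop codon in input")
        sa, na = syn_nonsyn_sites(ca)
        sb, nb = syn_nonsyn_sites(cb)
        s_sites += 0.5 * (sa + sb)
        n_sites += 0.5 * (na + nb)
        sd, nd = path_differences(ca, cb)
        s_diff += sd
        n_diff += nd
    if s_sites == 0 or n_sites == 0:
        raise ValueError("no comparable codons")
    ps, pn = s_diff / s_sites, n_diff / n_sites
    ds, sat_s = _jukes_cantor(ps)
    dn, sat_n = _jukes_cantor(pn)
    saturated = sat_s or sat_n
    undefined = (ds == 0.0) or saturated
    omega = float("nan") if undefined else dn / ds
    return PairwiseOmega(pair=ids, dn=dn, ds=ds, omega=omega, method="counting",
                         saturated=saturated, undefined=undefined)
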