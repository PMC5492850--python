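"""Goldman-Yang style codon rate matrices over the 61 sense codons.

The instantaneous rate from codon i to codon j is zero unless the codons
differ at exactly one position; otherwise it is

    q_ij = pi_j * kappa^[transition] * omega^[nonsynonymous]

with the matrix normalized so that branch lengths measure expected
substitutions per codon.  The matrix is reversible with stationary
distribution pi, so transition probabilities are computed through the
symmetrized eigendecomposition, which is numerically stable and lets one
decomposition serve every branch length.
"""

from __future__ import annotations

import itertools

import numpy as np

from ..genetic_code import AA_OF, CODONS, N_CODONS, NUCS, is_transition

__all__ = ["StructuralMasks", "build_rate_matrix", "CodonMatrixExp",
           "f3x4_frequencies", "uniform_frequencies", "stationary_check"]


def _build_masks():
    n = N_CODONS
    single = np.zeros((n, n), dtype=bool)
    ts = np.zeros((n, n), dtype=bool)
    nonsyn = np.zeros((n, n), dtype=bool)
    for i, ci in enumerate(CODONS):
        for j, cj in enumerate(CODONS):
            if i == j:
                continue
            diffs = [(a, b) for a, b in zip(ci, cj) if a != b]
            if len(diffs) != 1:
                continue
            single[i, j] = True
            a, b = diffs[0]
            ts[i, j] = is_transition(a, b)
            nonsyn[i, j] = AA_OF[i] != AA_OF[j]
    return single, ts, nonsyn


class StructuralMasks:
    """Precomputed single-change / transition / nonsynonymous masks."""

    single, transition, nonsynonymous = _build_masks()


def uniform_frequencies() -> np.ndarray:
    return np.full(N_CODONS, 1.0 / N_CODONS)


def f3x4_frequencies(pos_freqs: np.ndarray | None = None) -> np.ndarray:
    """Codon frequencies from position-specific nucleotide frequencies.

    `pos_freqs` is a 3x4 array (rows = codon positions, columns = ACGT);
    defaults to uniform nucleotide composition.  Stop codons receive zero
    mass and the vector is renormalized over the 61 sense codons.
    """
    if pos_freqs is None:
        pos_freqs = np.full((3, 4), 0.25)
    pos_freqs = np.asarray(pos_freqs, dtype=float)
    if pos_freqs.shape != (3, 4):
        raise ValueError("pos_freqs must be 3x4 (positions x ACGT)")
    nuc_idx = {n: k for k, n in enumerate(NUCS)}
    pi = np.array([pos_freqs[0, nuc_idx[c[0]]]
                   * pos_freqs[1, nuc_idx[c[1]]]
                   * pos_freqs[2, nuc_idx[c[2]]] for c in CODONS])
    total = pi.sum()
    if total <= 0:
        raise ValueError("degenerate position frequencies")
    return pi / total


def f3x4_from_sequences(seqs: list[str]) -> np.ndarray:
    """F3x4 frequencies estimated from observed codon sequences."""
    counts = np.zeros((3, 4))
    nuc_idx = {n: k for k, n in enumerate(NUCS)}
    for s in seqs:
        for i in range(0, len(s) - len(s) % 3, 3):
            for pos in range(3):
                ch = s[i + pos]
                if ch in nuc_idx:
                    counts[pos, nuc_idx[ch]] += 1
    counts += 0.5  # avoid zero-mass codons on short alignments
    counts /= counts.sum(axis=1, keepdims=True)
    return f3x4_frequencies(counts)


def build_rate_matrix(kappa: float, omega: float, pi: np.ndarray,
                      normalize: bool = True) -> np.ndarray:
    """The 61x61 generator Q(kappa, omega, pi), optionally scaled to
    one expected substitution per codon per unit branch length."""
    if kappa <= 0:
        raise ValueError("kappa must be > 0")
    if omega < 0:
        raise ValueError("omega must be >= 0")
    pi = np.asarray(pi, dtype=float)
    m = StructuralMasks
    q = np.where(m.single, pi[None, :], 0.0)
    q = q * np.where(m.transition, kappa, 1.0) * np.where(m.nonsynonymous, omega, 1.0)
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    if normalize:
        rate = -(pi * np.diag(q)).sum()
        if rate <= 0:
            raise ValueError("degenerate rate matrix (total rate 0)")
        q /= rate
    return q


def mixture_rate_matrices(kappa: float, omegas, props, pi: np.ndarray,
                          ) -> list[np.ndarray]:
    """Per-class generators under joint normalization.

    The class matrices share one scale factor, chosen so the *mixture*
    has one expected substitution per codon per unit branch length
    (low-omega classes evolve slower than high-omega ones, as they
    should); this matches the switching model's within-class blocks in
    its delta -> 0 limit.
    """
    omegas = np.asarray(omegas, dtype=float)
    props = np.asarray(props, dtype=float)
    qs = [build_rate_matrix(kappa, w, pi, normalize=False) for w in omegas]
    rate = sum(p * -(pi * np.diag(q)).sum() for p, q in zip(props, qs))
    if rate <= 0:
        raise ValueError("degenerate mixture (total rate 0)")
    return [q / rate for q in qs]


def nonsyn_flux_fraction(kappa: float, omega: float, pi: np.ndarray) -> float:
    """Fraction of the total substitution flux that is nonsynonymous."""
    q = build_rate_matrix(kappa, omega, pi, normalize=False)
    flux = pi[:, None] * q
    m = StructuralMasks
    total = flux[m.single].sum()
    return float(flux[m.single & m.nonsynonymous].sum() / total)


class CodonMatrixExp:
    """Eigendecomposition of a reversible generator for fast P(t).

    For reversible Q with stationary pi, S = D Q D^-1 (D = diag(sqrt(pi)))
    is symmetric; P(t) = D^-1 U exp(L t) U' D from the eigenpairs (U, L)
    of S.  Construction is O(n^3); each P(t) afterwards is two matrix
    products.
    """

    def __init__(self, q: np.ndarray, pi: np.ndarray):
        pi = np.asarray(pi, dtype=float)
        if (pi <= 0).any():
            raise ValueError("stationary frequencies must be strictly positive")
        d = np.sqrt(pi)
        s = (q * d[:, None]) / d[None, :]
        s = 0.5 * (s + s.T)  # symmetrize away rounding asymmetry
        vals, vecs = np.linalg.eigh(s)
        self.pi = pi
        self._left = vecs / d[:, None]     # D^-1 U
        self._right = vecs.T * d[None, :]  # U' D
        self.eigenvalues = vals

    def probability_matrix(self, t: float) -> np.ndarray:
        if t < 0:
            raise ValueError("branch length must be >= 0")
        p = (self._left * np.exp(self.eigenvalues * t)) @ self._right
        np.clip(p, 0.0, None, out=p)
        p /= p.sum(axis=1, keepdims=True)
        return p


def stationary_check(q: np.ndarray, pi: np.ndarray) -> float:
    """Residual || pi' Q ||_inf; ~0 when pi is stationary for Q."""
    return float(np.abs(pi @ q).max())
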