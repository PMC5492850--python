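"""JTT amino-acid replacement model and ML pairwise distances.

The rate matrix is assembled from the published JTT exchangeabilities
and stationary frequencies, normalized to one expected replacement per
site per unit time.  Pairwise distances are maximum-likelihood under
this model: for a sequence pair the likelihood is a product over shared
ungapped sites of pi_a * P(b | a, t), and t is found by bounded
derivative-free maximization.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.optimize import minimize_scalar

from ._jtt_data import JTT_AA_ORDER, JTT_EXCHANGEABILITIES, JTT_FREQUENCIES

__all__ = ["JTT_AA_ORDER", "jtt_rate_matrix", "JttModel", "ml_distance",
           "DISTANCE_UPPER_BOUND", "SaturationError"]

DISTANCE_UPPER_BOUND = 50.0
_LOWER = 1e-9


class SaturationError(RuntimeError):
    pass


def jtt_rate_matrix() -> tuple[np.ndarray, np.ndarray]:
    """(Q, pi): the normalized JTT generator and stationary frequencies.

    Rows/columns are permuted into the package's alphabetical amino-acid
    order (``famevol.phylo.alignment.AA_ALPHABET``) so alignment codes
    index the matrix directly.
    """
    from .alignment import AA_ALPHABET

    n = 20
    s = np.zeros((n, n))
    k = 0
    for i in range(1, n):
        for j in range(i):
            s[i, j] = s[j, i] = JTT_EXCHANGEABILITIES[k]
            k += 1
    pi = np.asarray(JTT_FREQUENCIES, dtype=float)
    pi = pi / pi.sum()
    q = s * pi[None, :]
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    rate = -(pi * np.diag(q)).sum()
    perm = [JTT_AA_ORDER.index(a) for a in AA_ALPHABET]
    return (q / rate)[np.ix_(perm, perm)], pi[perm]


class JttModel:
    """Eigendecomposition of the JTT generator for fast P(t)."""

    def __init__(self):
        q, pi = jtt_rate_matrix()
        d = np.sqrt(pi)
        sym = 0.5 * ((q * d[:, None]) / d[None, :] +
                     ((q * d[:, None]) / d[None, :]).T)
        vals, vecs = np.linalg.eigh(sym)
        self.pi = pi
        self.eigenvalues = vals
        self._left = vecs / d[:, None]
        self._right = vecs.T * d[None, :]

    def probability_matrix(self, t: float) -> np.ndarray:
        p = (self._left * np.exp(self.eigenvalues * t)) @ self._right
        np.clip(p, 1e-300, None, out=p)
        p /= p.sum(axis=1, keepdims=True)
        return p


@lru_cache(maxsize=1)
def _model() -> JttModel:
    return JttModel()


def ml_distance(pair_counts: np.ndarray, tol: float = 1e-8) -> tuple[float, bool]:
    """ML distance from a 20x20 matrix of aligned residue-pair counts.

    Returns (t_hat, saturated).  A likelihood maximized at the upper
    search bound is returned as the bound with ``saturated=True``.
    """
    model = _model()
    if pair_counts.sum() == 0:
        raise ValueError("no shared ungapped sites")
    log_pi = np.log(model.pi)

    def neg_ll(t: float) -> float:
        p = model.probability_matrix(t)
        return -float((pair_counts * (log_pi[:, None] + np.log(p))).sum())

    res = minimize_scalar(neg_ll, bounds=(_LOWER, DISTANCE_UPPER_BOUND),
                          method="bounded", options={"xatol": tol})
    t_hat = float(res.x)
    saturated = t_hat > DISTANCE_UPPER_BOUND * 0.98
    if saturated:
        t_hat = DISTANCE_UPPER_BOUND
    return t_hat, saturated
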