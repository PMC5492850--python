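"""Codon substitution models in a Model / Results idiom.

Each model class is built from data (aligned codon sequences and a
tree); ``fit()`` runs bounded quasi-Newton optimization on
log-transformed parameters and returns a :class:`CodonModelResults`
carrying the maximized log-likelihood, parameter estimates, posteriors
where the model has site classes, and a ``summary()`` table.

Models
------
``OneRatioModel``      one omega shared by every branch and site
``BranchModel``        one omega per branch class (k-ratio)
``SiteMixtureModel``   M3: K discrete omega classes over sites
``SwitchingModel``     M3+S1: M3 whose site classes switch along
                       branches at rate delta (61*K expanded states)

Branch lengths are optimized per branch for the branch models and, by
default, through a single rate-scale factor for the site models (whose
input trees come from the phylogeny stage); ``optimize_branch_lengths``
switches between the two behaviours.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from ..genetic_code import N_CODONS
from ..tree import Node
from .codon_matrix import (CodonMatrixExp, build_rate_matrix, f3x4_from_sequences,
                           mixture_rate_matrices, nonsyn_flux_fraction,
                           uniform_frequencies)
from .ng86 import PairwiseOmega
from .pruning import PruningEngine, encode_codon_alignment

__all__ = ["CodonModelResults", "OneRatioModel", "BranchModel",
           "SiteMixtureModel", "SwitchingModel", "ml_pairwise",
           "label_branches_by_partition", "read_branch_labeled_newick",
           "write_branch_labeled_newick"]

_LOG_T_BOUNDS = (np.log(1e-6), np.log(20.0))
_LOG_KAPPA_BOUNDS = (np.log(0.05), np.log(50.0))
_LOG_OMEGA_BOUNDS = (np.log(1e-4), np.log(50.0))
_LOG_DELTA_BOUNDS = (np.log(1e-8), np.log(20.0))
_LOGIT_BOUNDS = (-10.0, 10.0)


@dataclass
class CodonModelResults:
    """Fitted codon model.

    ``loglik`` is the maximized log-likelihood (report ``-loglik`` to
    compare with conventional -lnL tables).
    """

    model: object
    name: str
    loglik: float
    params: dict
    branch_lengths: dict[int, float]
    n_free_params: int
    converged: bool
    site_posteriors: pd.DataFrame | None = None
    branch_class_posteriors: dict[int, np.ndarray] | None = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def neg_loglik(self) -> float:
        return -self.loglik

    def positive_sites(self, posterior_threshold: float = 0.5,
                       strong_threshold: float = 0.95) -> pd.DataFrame:
        """Sites whose most probable class has omega > 1 (NEB calls)."""
        if self.site_posteriors is None:
            raise ValueError(f"{self.name} has no site posteriors")
        omegas = np.asarray(self.params["omegas"])
        top = int(np.argmax(omegas))
        rows = []
        if omegas[top] <= 1.0:
            return pd.DataFrame(rows, columns=["site", "posterior", "call"])
        post = self.site_posteriors[f"class{top + 1}"].to_numpy()
        for site, pp in enumerate(post):
            if pp > posterior_threshold:
                rows.append({"site": site, "posterior": float(pp),
                             "call": "strong" if pp > strong_threshold else "positive"})
        return pd.DataFrame(rows, columns=["site", "posterior", "call"])

    def summary(self) -> str:
        lines = [f"{self.name}",
                 "=" * len(self.name),
                 f"-lnL            {self.neg_loglik:.4f}",
                 f"free parameters {self.n_free_params}",
                 f"converged       {self.converged}"]
        for key, val in self.params.items():
            if isinstance(val, dict):
                for k2, v2 in val.items():
                    lines.append(f"{key}[{k2}]".ljust(16) + f"{v2:.4f}")
            elif isinstance(val, (list, tuple, np.ndarray)):
                vals = ", ".join(f"{v:.4f}" for v in np.atleast_1d(val))
                lines.append(f"{key}".ljust(16) + vals)
            else:
                lines.append(f"{key}".ljust(16) + f"{val:.4f}")
        tl = sum(self.branch_lengths.values())
        lines.append(f"tree length     {tl:.4f}")
        return "\n".join(lines)


def _softmax_from_logits(logits: np.ndarray) -> np.ndarray:
    z = np.concatenate([logits, [0.0]])
    z -= z.max()
    e = np.exp(z)
    return e / e.sum()


def _logits_from_props(props: np.ndarray) -> np.ndarray:
    p = np.clip(np.asarray(props, dtype=float), 1e-8, None)
    p /= p.sum()
    return np.log(p[:-1]) - np.log(p[-1])


class _BaseCodonModel:
    """Shared plumbing: encoding, engine, frequencies, optimizer."""

    def __init__(self, sequences: dict[str, str], tree: Node,
                 codon_freq: str = "F3x4",
                 optimize_branch_lengths: str = "all"):
        self.tree = tree.copy()
        # the model works on a private copy; translate caller-side node
        # uids (branch classes, posterior lookups) to the copy's uids
        self.uid_map = {o._uid: c._uid for o, c in
                        zip(tree.postorder(), self.tree.postorder())}
        ids, states = encode_codon_alignment(sequences)
        self.engine = PruningEngine(self.tree, ids, states)
        if codon_freq == "uniform":
            self.pi = uniform_frequencies()
        elif codon_freq == "F3x4":
            self.pi = f3x4_from_sequences(list(sequences.values()))
        else:
            raise ValueError("codon_freq must be 'uniform' or 'F3x4'")
        if optimize_branch_lengths not in ("all", "scale"):
            raise ValueError("optimize_branch_lengths must be 'all' or 'scale'")
        self.blen_mode = optimize_branch_lengths
        self.edges = [n for n in self.engine.nodes if n.parent is not None]
        self._init_blens = np.array([max(n.length, 1e-3) for n in self.edges])
        self._decomp_cache: dict[tuple, object] = {}

    # branch-length packing -------------------------------------------
    def _blen_param_init(self) -> np.ndarray:
        if self.blen_mode == "all":
            return np.log(self._init_blens)
        return np.array([0.0])  # log scale factor

    def _blens_from(self, theta: np.ndarray) -> np.ndarray:
        if self.blen_mode == "all":
            return np.exp(theta)
        return self._init_blens * np.exp(theta[0])

    @property
    def _n_blen_params(self) -> int:
        return len(self.edges) if self.blen_mode == "all" else 1

    def _decomp(self, key: tuple, builder) -> object:
        if key not in self._decomp_cache:
            if len(self._decomp_cache) > 64:
                self._decomp_cache.clear()
            self._decomp_cache[key] = builder()
        return self._decomp_cache[key]

    def _optimize(self, fun, x0: np.ndarray, bounds, n_restarts: int = 1,
                  seed: int = 0, ftol: float = 1e-8):
        best = None
        rng = np.random.default_rng(seed)
        for r in range(n_restarts):
            start = x0 if r == 0 else x0 + rng.normal(0, 0.3, size=len(x0))
            start = np.clip(start, [b[0] for b in bounds], [b[1] for b in bounds])
            res = minimize(fun, start, method="L-BFGS-B", bounds=bounds,
                           options={"ftol": ftol, "maxiter": 500})
            if best is None or res.fun < best.fun:
                best = res
        return best


class OneRatioModel(_BaseCodonModel):
    """Single omega across all branches and sites."""

    name = "one-ratio"

    def fit(self, kappa0: float = 2.0, omega0: float = 0.3,
            init_from: CodonModelResults | None = None,
            n_restarts: int = 1, seed: int = 0,
            ftol: float = 1e-8) -> CodonModelResults:
        """Fit; `init_from` can seed branch lengths and kappa from a
        richer fit on the same data (profile polishing for LRTs)."""
        nb = self._n_blen_params

        def neg_ll(theta):
            blens = self._blens_from(theta[:nb])
            kappa, omega = np.exp(theta[nb]), np.exp(theta[nb + 1])
            dec = self._decomp(("one", kappa, omega), lambda: CodonMatrixExp(
                build_rate_matrix(kappa, omega, self.pi), self.pi))
            p_of_edge = {e._uid: dec.probability_matrix(t)
                         for e, t in zip(self.edges, blens)}
            return -self.engine.loglik(p_of_edge, self.pi)

        blen_init = self._blen_param_init()
        if init_from is not None:
            kappa0 = init_from.params["kappa"]
            om = init_from.params["omega"]
            omega0 = om if np.isscalar(om) else float(np.mean(list(om.values())))
            src = [init_from.branch_lengths[e._uid]
                   for e in init_from.model.edges]
            if self.blen_mode == "all" and len(src) == len(self.edges):
                blen_init = np.log(np.clip(src, 1e-6, None))
        x0 = np.concatenate([blen_init, [np.log(kappa0), np.log(omega0)]])
        bounds = ([_LOG_T_BOUNDS] * nb if self.blen_mode == "all"
                  else [(-8.0, 8.0)]) + [_LOG_KAPPA_BOUNDS, _LOG_OMEGA_BOUNDS]
        res = self._optimize(neg_ll, x0, bounds, n_restarts, seed, ftol=ftol)
        blens = self._blens_from(res.x[:nb])
        params = {"kappa": float(np.exp(res.x[nb])),
                  "omega": float(np.exp(res.x[nb + 1]))}
        return CodonModelResults(
            model=self, name=self.name, loglik=-res.fun, params=params,
            branch_lengths={e._uid: float(t) for e, t in zip(self.edges, blens)},
            n_free_params=nb + 2, converged=bool(res.success))


class BranchModel(_BaseCodonModel):
    """One omega per branch class (codeml-style k-ratio branch model).

    `branch_classes` maps edge node uid -> class label; edges absent
    from the map share the class "background".
    """

    name = "branch"

    def __init__(self, sequences, tree, branch_classes: dict[int, str],
                 codon_freq: str = "F3x4",
                 optimize_branch_lengths: str = "all"):
        super().__init__(sequences, tree, codon_freq, optimize_branch_lengths)
        remapped = {self.uid_map.get(k, k): v for k, v in branch_classes.items()}
        declared = set(remapped.values())
        self.classes = sorted(declared | {remapped.get(e._uid, "background")
                                          for e in self.edges})
        self.class_idx = {c: i for i, c in enumerate(self.classes)}
        self.edge_class = np.array([
            self.class_idx[remapped.get(e._uid, "background")]
            for e in self.edges])
        for c in self.classes:
            if not (self.edge_class == self.class_idx[c]).any():
                raise ValueError(f"branch class {c!r} has no branches")

    def fit(self, kappa0: float = 2.0, omega0: float = 0.3,
            init_from: CodonModelResults | None = None,
            n_restarts: int = 1, seed: int = 0,
            ftol: float = 1e-8) -> CodonModelResults:
        """Fit; `init_from` (typically a one-ratio fit on the same data)
        seeds branch lengths, kappa and all class omegas, which also
        guarantees lnL(k-ratio) >= lnL(one-ratio) up to optimizer noise."""
        nb, nc = self._n_blen_params, len(self.classes)

        def neg_ll(theta):
            blens = self._blens_from(theta[:nb])
            kappa = np.exp(theta[nb])
            omegas = np.exp(theta[nb + 1: nb + 1 + nc])
            decs = [self._decomp(("br", kappa, w), lambda w=w: CodonMatrixExp(
                build_rate_matrix(kappa, w, self.pi), self.pi)) for w in omegas]
            p_of_edge = {e._uid: decs[self.edge_class[i]].probability_matrix(blens[i])
                         for i, e in enumerate(self.edges)}
            return -self.engine.loglik(p_of_edge, self.pi)

        blen_init = self._blen_param_init()
        if init_from is not None:
            kappa0 = init_from.params["kappa"]
            om = init_from.params["omega"]
            omega0 = om if np.isscalar(om) else float(np.mean(list(om.values())))
            src = [init_from.branch_lengths[e._uid]
                   for e in init_from.model.edges]
            if self.blen_mode == "all" and len(src) == len(self.edges):
                blen_init = np.log(np.clip(src, 1e-6, None))
        x0 = np.concatenate([blen_init, [np.log(kappa0)],
                             np.full(nc, np.log(omega0))])
        bounds = ([_LOG_T_BOUNDS] * nb if self.blen_mode == "all"
                  else [(-8.0, 8.0)]) + [_LOG_KAPPA_BOUNDS] + \
            [_LOG_OMEGA_BOUNDS] * nc
        res = self._optimize(neg_ll, x0, bounds, n_restarts, seed, ftol=ftol)
        blens = self._blens_from(res.x[:nb])
        omegas = np.exp(res.x[nb + 1: nb + 1 + nc])
        params = {"kappa": float(np.exp(res.x[nb])),
                  "omega": {c: float(omegas[i]) for c, i in self.class_idx.items()}}
        return CodonModelResults(
            model=self, name=f"{self.name}({nc}-ratio)", loglik=-res.fun,
            params=params,
            branch_lengths={e._uid: float(t) for e, t in zip(self.edges, blens)},
            n_free_params=nb + 1 + nc, converged=bool(res.success))


class SiteMixtureModel(_BaseCodonModel):
    """M3: K discrete omega classes with free proportions.

    Omega classes are sorted ascending after fitting for identifiability;
    NEB posteriors P(class | site) are attached to the results.
    """

    name = "M3"

    def __init__(self, sequences, tree, n_classes: int = 3,
                 codon_freq: str = "F3x4",
                 optimize_branch_lengths: str = "scale"):
        if n_classes < 2:
            raise ValueError("need at least 2 site classes")
        super().__init__(sequences, tree, codon_freq, optimize_branch_lengths)
        self.K = n_classes

    def _unpack(self, theta):
        nb, K = self._n_blen_params, self.K
        blens = self._blens_from(theta[:nb])
        kappa = np.exp(theta[nb])
        props = _softmax_from_logits(theta[nb + 1: nb + K])
        omegas = np.exp(theta[nb + K: nb + 2 * K])
        return blens, kappa, props, omegas

    def _class_decomps(self, kappa, props, omegas):
        key = ("m3", kappa, tuple(props), tuple(omegas))
        return self._decomp(key, lambda: [
            CodonMatrixExp(q, self.pi)
            for q in mixture_rate_matrices(kappa, omegas, props, self.pi)])

    def _neg_ll(self, theta):
        blens, kappa, props, omegas = self._unpack(theta)
        decs = self._class_decomps(kappa, props, omegas)
        per_class = [{e._uid: d.probability_matrix(t)
                      for e, t in zip(self.edges, blens)} for d in decs]
        lnl, _ = self.engine.mixture_logliks(
            per_class, [self.pi] * self.K, props)
        return -lnl

    def _default_x0(self, kappa0, props0, omegas0):
        props0 = np.asarray(props0 if props0 is not None
                            else np.full(self.K, 1.0 / self.K))
        omegas0 = np.asarray(omegas0 if omegas0 is not None
                             else np.geomspace(0.05, 2.0, self.K))
        return np.concatenate([self._blen_param_init(), [np.log(kappa0)],
                               _logits_from_props(props0), np.log(omegas0)])

    def _bounds(self):
        nb, K = self._n_blen_params, self.K
        return ([_LOG_T_BOUNDS] * nb if self.blen_mode == "all"
                else [(-8.0, 8.0)]) + [_LOG_KAPPA_BOUNDS] + \
            [_LOGIT_BOUNDS] * (K - 1) + [_LOG_OMEGA_BOUNDS] * K

    def fit(self, kappa0: float = 2.0, props0=None, omegas0=None,
            n_restarts: int = 2, seed: int = 0,
            ftol: float = 1e-8) -> CodonModelResults:
        x0 = self._default_x0(kappa0, props0, omegas0)
        res = self._optimize(self._neg_ll, x0, self._bounds(), n_restarts,
                             seed, ftol=ftol)
        blens, kappa, props, omegas = self._unpack(res.x)
        order = np.argsort(omegas)
        props, omegas = props[order], omegas[order]
        decs = [CodonMatrixExp(q, self.pi) for q in
                mixture_rate_matrices(kappa, omegas, props, self.pi)]
        per_class = [{e._uid: d.probability_matrix(t)
                      for e, t in zip(self.edges, blens)} for d in decs]
        lnl, post_pat = self.engine.mixture_logliks(
            per_class, [self.pi] * self.K, props)
        post = post_pat[self.engine.pattern_of_site]
        post_df = pd.DataFrame(post, columns=[f"class{k + 1}"
                                              for k in range(self.K)])
        collapse = np.min(np.diff(np.sort(omegas))) < 1e-4 if self.K > 1 else False
        params = {"kappa": float(kappa), "proportions": props.tolist(),
                  "omegas": omegas.tolist()}
        return CodonModelResults(
            model=self, name=self.name, loglik=lnl, params=params,
            branch_lengths={e._uid: float(t) for e, t in zip(self.edges, blens)},
            n_free_params=self._n_blen_params + 1 + (self.K - 1) + self.K,
            converged=bool(res.success), site_posteriors=post_df,
            diagnostics={"class_collapse": bool(collapse)})


class SwitchingModel(SiteMixtureModel):
    """M3+S1: the site class itself evolves along the tree.

    The process lives on the 61*K codon-x-class state space: within-class
    blocks are the class GY94 matrices, the class jumps k -> l at rate
    delta * p_l (one switching parameter; stationary class weights p).
    Marginal per-branch class posteriors come from inside-outside on the
    expanded space.  With delta -> 0 the likelihood collapses to M3.
    """

    name = "M3+S1"

    def _neg_ll_switch(self, theta):
        from .codon_matrix import stationary_check
        from ..simulate.codon_sim import switching_generator
        nb, K = self._n_blen_params, self.K
        blens = self._blens_from(theta[:nb])
        kappa = np.exp(theta[nb])
        props = _softmax_from_logits(theta[nb + 1: nb + K])
        omegas = np.exp(theta[nb + K: nb + 2 * K])
        delta = np.exp(theta[nb + 2 * K])
        key = ("s1", kappa, tuple(props), tuple(omegas), delta)

        def build():
            big, stat = switching_generator(kappa, omegas, props, delta, self.pi)
            if np.abs(big.sum(axis=1)).max() > 1e-9:
                raise AssertionError("expanded generator rows do not sum to 0")
            if stationary_check(big, stat) > 1e-8:
                raise AssertionError("stationary vector mismatch in generator")
            return CodonMatrixExp(big, stat), stat

        dec, stat = self._decomp(key, build)
        p_of_edge = {e._uid: dec.probability_matrix(t)
                     for e, t in zip(self.edges, blens)}
        return -self.engine.loglik(p_of_edge, stat)

    def fit(self, kappa0: float = 2.0, props0=None, omegas0=None,
            delta0: float = 0.3, init_from: CodonModelResults | None = None,
            n_restarts: int = 1, seed: int = 0,
            ftol: float = 1e-8) -> CodonModelResults:
        from ..simulate.codon_sim import switching_generator
        nb, K = self._n_blen_params, self.K
        if init_from is not None:
            p0 = np.asarray(init_from.params["proportions"])
            w0 = np.asarray(init_from.params["omegas"]).copy()
            # a site mixture averaged over branches dilutes episodic
            # positive selection; start the top class above neutrality so
            # the optimizer can reach switching solutions (the delta -> 0
            # boundary guard below still recovers the M3 null when the
            # data carry no switching signal)
            w0[-1] = max(w0[-1], 2.5)
            kappa0 = init_from.params["kappa"]
            if self.blen_mode == "scale":
                total0 = sum(init_from.branch_lengths.values())
                scale0 = total0 / max(self._init_blens.sum(), 1e-12)
                blen_init = np.array([np.log(max(scale0, 1e-6))])
            else:
                blen_init = np.log(np.clip(
                    [init_from.branch_lengths[e._uid] for e in self.edges],
                    1e-6, None))
            x0 = np.concatenate([blen_init, [np.log(kappa0)],
                                 _logits_from_props(p0),
                                 np.log(np.clip(w0, 1e-4, None)),
                                 [np.log(delta0)]])
            w_null = np.asarray(init_from.params["omegas"])
            x_boundary = x0.copy()
            x_boundary[nb + K: nb + 2 * K] = np.log(np.clip(w_null, 1e-4, None))
        else:
            x0 = np.concatenate([self._default_x0(kappa0, props0, omegas0),
                                 [np.log(delta0)]])
            x_boundary = x0.copy()
        bounds = self._bounds() + [_LOG_DELTA_BOUNDS]
        res = self._optimize(self._neg_ll_switch, x0, bounds, n_restarts,
                             seed, ftol=ftol)
        # the delta -> 0 boundary is the M3 null; guard against the
        # optimizer stalling on the flat switching-rate profile there
        x_boundary[-1] = _LOG_DELTA_BOUNDS[0]
        f_boundary = self._neg_ll_switch(x_boundary)
        if f_boundary < res.fun:
            res.x, res.fun = x_boundary, f_boundary

        blens = self._blens_from(res.x[:nb])
        kappa = float(np.exp(res.x[nb]))
        props = _softmax_from_logits(res.x[nb + 1: nb + K])
        omegas = np.exp(res.x[nb + K: nb + 2 * K])
        delta = float(np.exp(res.x[nb + 2 * K]))
        order = np.argsort(omegas)
        props, omegas = props[order], omegas[order]

        big, stat = switching_generator(kappa, omegas, props, delta, self.pi)
        dec = CodonMatrixExp(big, stat)
        p_of_edge = {e._uid: dec.probability_matrix(t)
                     for e, t in zip(self.edges, blens)}
        lnl = self.engine.loglik(p_of_edge, stat)
        state_posts = self.engine.state_posteriors(p_of_edge, stat)
        branch_posts: dict[int, np.ndarray] = {}
        for uid, sp in state_posts.items():
            per_class = sp.reshape(self.engine.n_patterns, self.K, N_CODONS).sum(axis=2)
            branch_posts[uid] = per_class[self.engine.pattern_of_site]
        root_post = branch_posts[self.engine.nodes[-1]._uid]
        post_df = pd.DataFrame(root_post, columns=[f"class{k + 1}"
                                                   for k in range(self.K)])
        params = {"kappa": kappa, "proportions": props.tolist(),
                  "omegas": omegas.tolist(), "delta": delta}
        return CodonModelResults(
            model=self, name=self.name, loglik=lnl, params=params,
            branch_lengths={e._uid: float(t) for e, t in zip(self.edges, blens)},
            n_free_params=nb + 1 + (K - 1) + K + 1,
            converged=bool(res.success), site_posteriors=post_df,
            branch_class_posteriors=branch_posts)


# ---------------------------------------------------------------------------
# pairwise ML


def ml_pairwise(seq_a: str, seq_b: str, ids: tuple[str, str] = ("a", "b"),
                codon_freq: str = "F3x4") -> PairwiseOmega:
    """ML dN/dS for one pair under GY94, optimizing (t, kappa, omega).

    dN and dS are decomposed from the fitted divergence t through the
    matrix's nonsynonymous/synonymous flux fractions, with site totals
    taken from the neutral (omega = 1) flux at the fitted kappa.
    """
    ids_enc, states = encode_codon_alignment({ids[0]: seq_a, ids[1]: seq_b})
    ok = (states >= 0).all(axis=0)
    a, b = states[0, ok], states[1, ok]
    counts = np.zeros((N_CODONS, N_CODONS))
    np.add.at(counts, (a, b), 1.0)
    if counts.sum() == 0:
        raise ValueError("no comparable codons")
    pi = (f3x4_from_sequences([seq_a, seq_b]) if codon_freq == "F3x4"
          else uniform_frequencies())
    log_pi = np.log(pi)
    if (a == b).all():
        # identical sequences: t -> 0 limit, multinomial likelihood
        lnl = float(np.diag(counts) @ log_pi)
        return PairwiseOmega(pair=ids, dn=0.0, ds=0.0, omega=float("nan"),
                             method="ML", undefined=True, lnl=lnl, t=0.0)

    cache: dict[tuple, CodonMatrixExp] = {}

    def neg_ll(theta):
        t, kappa, omega = np.exp(theta)
        key = (kappa, omega)
        if key not in cache:
            if len(cache) > 64:
                cache.clear()
            cache[key] = CodonMatrixExp(build_rate_matrix(kappa, omega, pi), pi)
        p = np.clip(cache[key].probability_matrix(t), 1e-300, None)
        return -float((counts * (log_pi[:, None] + np.log(p))).sum())

    x0 = np.log([0.3, 2.0, 0.3])
    bounds = [_LOG_T_BOUNDS, _LOG_KAPPA_BOUNDS, _LOG_OMEGA_BOUNDS]
    res = minimize(neg_ll, x0, method="L-BFGS-B", bounds=bounds,
                   options={"ftol": 1e-10})
    t, kappa, omega = np.exp(res.x)
    f_n = nonsyn_flux_fraction(kappa, omega, pi)
    sigma = 1.0 - nonsyn_flux_fraction(kappa, 1.0, pi)  # neutral syn fraction
    ds = t * (1.0 - f_n) / (3.0 * sigma)
    dn = t * f_n / (3.0 * (1.0 - sigma))
    saturated = bool(t > 0.98 * np.exp(_LOG_T_BOUNDS[1]))
    return PairwiseOmega(pair=ids, dn=float(dn), ds=float(ds),
                         omega=float(omega), method="ML",
                         saturated=saturated,
                         undefined=bool(ds == 0.0),
                         lnl=-float(res.fun), t=float(t), kappa=float(kappa))


# ---------------------------------------------------------------------------
# helpers


def read_branch_labeled_newick(text: str) -> tuple[Node, dict[int, str]]:
    """Parse a newick carrying codeml-dialect branch class labels.

    Labels are ``#k`` suffixes after a leaf name or a closing
    parenthesis (e.g. ``(A,B)#1`` or ``Osa_f_1 #2``).  Returns the tree
    and a {node uid: class label} map for the labeled branches.
    """
    import re

    from ..tree import parse_newick as _parse

    transformed = re.sub(r"\s*#\s*(\d+)", r"__HASH\1", text)
    root = _parse(transformed)
    labels: dict[int, str] = {}
    for node in root.postorder():
        name = node.name
        if name and "__HASH" in name:
            base, k = name.split("__HASH", 1)
            node.name = base or None
            labels[node._uid] = k
    return root, labels


def write_branch_labeled_newick(tree: Node, labels: dict[int, str]) -> str:
    """Inverse of :func:`read_branch_labeled_newick` (codeml ``#k``)."""
    import re

    work = tree.copy()
    for orig, copied in zip(tree.postorder(), work.postorder()):
        if orig._uid in labels:
            copied.name = (copied.name or "") + f"__HASH{labels[orig._uid]}"
    from ..tree import to_newick as _to
    text = _to(work)
    return re.sub(r"__HASH(\d+)", r" #\1", text)


def label_branches_by_partition(tree: Node, partition: dict[str, str],
                                species_of=None) -> dict[int, str]:
    """Edge uid -> 'dicot' / 'grass' / 'mixed' by the leaves below it."""
    from ..reconcile import species_of_leaf
    species_of = species_of or species_of_leaf
    out: dict[int, str] = {}
    for node in tree.postorder():
        if node.parent is None:
            continue
        parts = {partition[species_of(l.name)] for l in node.leaves()}
        out[node._uid] = parts.pop() if len(parts) == 1 else "mixed"
    return out
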