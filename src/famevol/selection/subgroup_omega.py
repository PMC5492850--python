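"""Within-subgroup pairwise omega and dicot-vs-grass comparison.

All pairs inside each dicot/grass subgroup are scored by the ML pairwise
estimator; pairs beyond the synonymous saturation cutoff (dS > 2 by
default) are discarded; subgroup means are compared with a two-sided
Mann-Whitney U test.

Pairwise omega values within a subgroup share sequences and are not
independent; results carry an explicit ``nonindependent_pairs`` caveat
flag and a subsampling option (disjoint pairs only) is provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from ..reconcile import Subgroup
from .models import ml_pairwise
from .ng86 import PairwiseOmega

__all__ = ["SubgroupOmega", "subgroup_pairwise_omega", "compare_subgroup_means"]


@dataclass
class SubgroupOmega:
    subgroup_id: str
    partition: str
    pairs: list[PairwiseOmega] = field(default_factory=list)
    n_discarded_saturated: int = 0
    caveat: str = "nonindependent_pairs"

    @property
    def omegas(self) -> np.ndarray:
        vals = [p.omega for p in self.pairs if not p.undefined
                and np.isfinite(p.omega)]
        return np.asarray(vals, dtype=float)

    @property
    def mean_omega(self) -> float:
        vals = self.omegas
        return float(vals.mean()) if vals.size else float("nan")


def _disjoint_pairs(members: list[str]) -> list[tuple[str, str]]:
    ordered = sorted(members)
    return [(ordered[i], ordered[i + 1]) for i in range(0, len(ordered) - 1, 2)]


def subgroup_pairwise_omega(alignment: dict[str, str], subgroups: list[Subgroup],
                            ds_max: float = 2.0, subsample: bool = False,
                            ) -> list[SubgroupOmega]:
    """Pairwise omega sets per subgroup, with dS-saturation filtering.

    `alignment` maps gene id -> aligned CDS.  With ``subsample=True``
    only disjoint pairs (each gene used once) enter, removing the
    shared-sequence dependence at the cost of fewer values.
    """
    out = []
    for sg in subgroups:
        members = [m for m in sg.members if m in alignment]
        res = SubgroupOmega(subgroup_id=sg.id, partition=sg.partition)
        if len(members) >= 2:
            if subsample:
                pair_ids = _disjoint_pairs(members)
            else:
                pair_ids = [(a, b) for i, a in enumerate(sorted(members))
                            for b in sorted(members)[i + 1:]]
            for a, b in pair_ids:
                pw = ml_pairwise(alignment[a], alignment[b], ids=(a, b))
                if pw.ds > ds_max or pw.saturated:
                    res.n_discarded_saturated += 1
                    continue
                res.pairs.append(pw)
        out.append(res)
    return out


def compare_subgroup_means(dicot_omegas: np.ndarray, grass_omegas: np.ndarray,
                           ) -> dict:
    """Two-sided Mann-Whitney U between dicot and grass omega sets.

    Exact null distribution for small tie-free samples, normal
    approximation with tie correction otherwise.  Returns the raw p,
    the U statistic, and the star label at the conventional thresholds
    (n.s., * p<0.05, ** p<0.01).
    """
    d = np.asarray(dicot_omegas, dtype=float)
    g = np.asarray(grass_omegas, dtype=float)
    if d.size == 0 or g.size == 0:
        raise ValueError("both omega sets must be non-empty")
    pooled = np.concatenate([d, g])
    if np.unique(pooled).size == 1:
        return {"pvalue": 1.0, "statistic": float(d.size * g.size / 2.0),
                "label": "n.s.", "n_dicot": d.size, "n_grass": g.size}
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (d.size <= 8 and g.size <= 8 and not has_ties) \
        else "asymptotic"
    stat, p = mannwhitneyu(d, g, alternative="two-sided", method=method)
    label = "**" if p < 0.01 else ("*" if p < 0.05 else "n.s.")
    return {"pvalue": float(p), "statistic": float(stat), "label": label,
            "n_dicot": int(d.size), "n_grass": int(g.size)}
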