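"""Simulation configuration.

One dataclass mirrors every knob of the generator: the gene birth-death
process along the species tree, the codon substitution regime, and the
planted filter-exercising artifacts.  A YAML file with the same field
names round-trips through :func:`load_config` / :func:`SimulationConfig.to_yaml`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import yaml

REGIMES = ("one-ratio", "branch", "M3", "M3S1")


@dataclass
class SimulationConfig:
    # gene birth-death process (events per lineage per unit time)
    birth_rate: float = 0.1
    death_rate: float = 0.05
    root_copies: int = 1
    lineage_cap: int = 10_000

    # codon alignment
    n_codons: int = 300
    regime: str = "one-ratio"
    kappa: float = 2.0
    omega: float = 0.2                       # one-ratio
    branch_omega: dict = field(default_factory=dict)   # branch regime: class -> omega
    site_classes: Sequence[float] = (0.6, 0.3, 0.1)    # M3 / M3S1 proportions
    site_omegas: Sequence[float] = (0.05, 0.5, 2.0)    # M3 / M3S1 class omegas
    switch_rate: float = 0.0                 # M3S1 delta
    codon_freq: str = "F3x4-uniform"         # or "uniform", or explicit 61-vector
    pi: Optional[Sequence[float]] = None
    subst_rate: float = 0.1                  # substitutions/codon per unit tree time

    # planted artifacts
    allele_identity: float = 0.97
    fragment_length_nt: int = 300

    seed: int = 0

    def __post_init__(self) -> None:
        if self.birth_rate < 0 or self.death_rate < 0:
            raise ValueError("birth and death rates must be >= 0")
        if self.root_copies < 1:
            raise ValueError("root_copies must be >= 1")
        if self.regime not in REGIMES:
            raise ValueError(f"regime must be one of {REGIMES}")
        p = np.asarray(self.site_classes, dtype=float)
        if p.size and abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("site class proportions must sum to 1")
        if (p < 0).any():
            raise ValueError("site class proportions must be >= 0")
        if self.switch_rate < 0:
            raise ValueError("switch rate delta must be >= 0")
        if not 0.0 < self.allele_identity <= 1.0:
            raise ValueError("allele_identity must lie in (0, 1]")
        if self.pi is not None:
            pi = np.asarray(self.pi, dtype=float)
            if pi.size != 61:
                raise ValueError("pi must have 61 entries (sense codons)")
            if abs(pi.sum() - 1.0) > 1e-8 or (pi < 0).any():
                raise ValueError("pi must be a probability vector over 61 codons")

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        if d["pi"] is not None:
            d["pi"] = [float(x) for x in d["pi"]]
        d["site_classes"] = [float(x) for x in d["site_classes"]]
        d["site_omegas"] = [float(x) for x in d["site_omegas"]]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


def load_config(path) -> SimulationConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return SimulationConfig(**raw)
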