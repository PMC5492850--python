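"""Likelihood ratio tests between nested codon model fits."""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import chi2

from .models import CodonModelResults

__all__ = ["LRTResult", "lrt"]

_NEG_TOL = 1e-3


@dataclass
class LRTResult:
    null: CodonModelResults
    alternative: CodonModelResults
    statistic: float
    df: int
    pvalue: float
    clipped: bool = False

    def significant(self, alpha: float = 0.05) -> bool:
        return self.pvalue < alpha

    def __str__(self) -> str:
        return (f"LRT {self.null.name} vs {self.alternative.name}: "
                f"2*dlnL = {self.statistic:.4f}, df = {self.df}, "
                f"p = {self.pvalue:.4g}")


def lrt(null: CodonModelResults, alternative: CodonModelResults,
        df: int | None = None) -> LRTResult:
    """2*(lnL_alt - lnL_null) against the chi-squared upper tail.

    `df` defaults to the free-parameter difference; it can be overridden
    (some published switching-model tests use df = 2 where this
    parameterization adds a single switching rate).
    """
    if df is None:
        df = alternative.n_free_params - null.n_free_params
    if df < 1:
        raise ValueError("alternative must have more free parameters than null")
    stat = 2.0 * (alternative.loglik - null.loglik)
    clipped = False
    if stat < 0:
        if stat < -_NEG_TOL:
            raise RuntimeError(
                f"negative LRT statistic {stat:.6f}: the alternative fit did "
                "not converge; refit with more restarts")
        stat, clipped = 0.0, True
    p = float(chi2.sf(stat, df))
    return LRTResult(null=null, alternative=alternative, statistic=float(stat),
                     df=int(df), pvalue=p, clipped=clipped)
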