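"""Fisher meta-analysis, significance thresholds and effect-size estimators.

Per-gene evidence from three independent sources — de novo enrichment,
transmission disequilibrium, and case-control burden (two references,
larger P taken) — is combined with Fisher's method (-2 sum ln p ~ chi-square
with 2k d.f.). Effect sizes follow from mutation-selection balance: at
equilibrium the cumulative allele frequency of LoF alleles is f = mu / s,
so a point estimate of the selection coefficient is s_hat = mu / f_hat; the
relative risk gamma is estimated as the ratio of carrier rates in cases over
controls, and the population-attributable-risk contribution as the excess
case carrier rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

from scipy import stats

from rarefam.case_control import dual_control_max_p


def fisher_combine(p_values: Sequence[float]) -> float:
    """Fisher's method: upper chi-square tail of -2 sum ln p at 2k d.f."""
    if not len(p_values):
        raise ValueError("need at least one P value")
    for p in p_values:
        if not 0.0 < p <= 1.0:
            raise ValueError(f"P value {p} outside (0, 1]")
    x = -2.0 * sum(math.log(p) for p in p_values)
    return float(stats.chi2.sf(x, 2 * len(p_values)))


@dataclass
class MetaInput:
    gene_id: str
    p_dnv: float
    p_tdt: float
    p_cc_pair: tuple[float, float]


def meta_gene(inp: MetaInput) -> float:
    """Per-gene meta P: Fisher over (DNV, TDT, max of the two CC P values)."""
    return fisher_combine([inp.p_dnv, inp.p_tdt, dual_control_max_p(*inp.p_cc_pair)])


def bonferroni_threshold(n_tests: int) -> float:
    """0.05 / n_tests (study-wide: n = 5,754 constrained genes -> 8.7e-6)."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return 0.05 / n_tests


#: Conventional exome-wide significance level (0.05 / 20,000 genes).
EXOME_WIDE_ALPHA = 2.5e-6
#: Number of autosomal constrained genes defining study-wide significance.
N_CONSTRAINED_GENES = 5754


def equilibrium_caf(mu: float, s: float) -> float:
    """Cumulative allele frequency at mutation-selection balance, f = mu / s."""
    if s <= 0:
        raise ValueError("selection coefficient must be > 0")
    if mu < 0:
        raise ValueError("mutation rate must be >= 0")
    return mu / s


def selection_from_caf(mu: float, f: float) -> float:
    """Point estimate of the selection coefficient, s_hat = mu / f (capped at 1)."""
    if f <= 0:
        raise ValueError("cumulative allele frequency must be > 0")
    if mu < 0:
        raise ValueError("mutation rate must be >= 0")
    return min(1.0, mu / f)


def relative_risk_from_rates(rate_case: float, rate_control: float) -> float:
    """Relative risk approximated by the carrier-rate ratio (rare variants)."""
    if rate_case < 0 or rate_control < 0:
        raise ValueError("rates must be >= 0")
    if rate_control == 0:
        return math.inf
    return rate_case / rate_control


def par_excess(rate_case: float, rate_control: float) -> float:
    """PAR contribution: excess carrier rate in cases, floored at 0."""
    if rate_case < 0 or rate_control < 0:
        raise ValueError("rates must be >= 0")
    return max(0.0, rate_case - rate_control)
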