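"""Analytic power and sample-size calculation for rare-variant case-control tests.

The test compares the cumulative allele frequency (CAF) of LoF alleles in N
unrelated cases against the population CAF f, assumed to sit at
mutation-selection equilibrium f = mu / s. All LoF alleles in a gene share
relative risk gamma. The test statistic is asymptotically noncentral
chi-square with 1 d.f.; the noncentrality parameter is

    lambda = 4N [ gamma f ln(gamma) + (1 - gamma f) ln((1 - gamma f)/(1 - f)) ]

("corrected" form; the variant with a (1 - gamma) factor in the second term
is also available as ``form="as_printed"``; the corrected form is the one
whose small-f limit, 4Nf[gamma ln gamma - (gamma - 1)], underlies the
sample-size approximation). Power is 1 - F(F^-1(1 - alpha; 0); lambda) where
F is the noncentral chi-square CDF.

Fitness constrains the feasible parameter space: a risk allele reduces
fitness by at least gamma * prevalence * s_D, so with prevalence 1/54 and a
sex-averaged fitness reduction s_D = 0.71 among affected individuals, only
(s, gamma) combinations with s >= 0.013 * gamma are considered plausible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq

from rarefam.meta import equilibrium_caf

#: Default experiment-wise error rate (study-wide threshold used in power analysis).
DEFAULT_ALPHA = 9e-6
DEFAULT_PREVALENCE = 1.0 / 54.0
DEFAULT_FITNESS_REDUCTION = 0.71  # sex-averaged s_D at a 4.2 male:female ratio


@dataclass
class PowerParams:
    alpha: float = DEFAULT_ALPHA
    target_power: float = 0.9
    n_cases: Optional[int] = None
    gamma: float = 2.0
    s: Optional[float] = None
    f: Optional[float] = None
    mu_lof: Optional[float] = None
    prevalence_pi: float = DEFAULT_PREVALENCE
    fitness_reduction_sd: float = DEFAULT_FITNESS_REDUCTION

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.gamma < 1.0:
            raise ValueError("gamma must be >= 1")
        if self.s is not None and not 0.0 < self.s <= 1.0:
            raise ValueError("s must be in (0, 1]")

    def caf(self) -> float:
        if self.f is not None:
            return self.f
        if self.mu_lof is None or self.s is None:
            raise ValueError("need either f or both mu_lof and s")
        return equilibrium_caf(self.mu_lof, self.s)

    @property
    def fitness_constant(self) -> float:
        """pi_hat * s_D_hat (~0.013): minimum s per unit of gamma."""
        return self.prevalence_pi * self.fitness_reduction_sd


@dataclass
class PowerResult:
    lambda_ncp: float
    power: float
    n_required: Optional[int] = None
    feasible: bool = True


def ncp_lambda(n_cases: float, gamma: float, f: float, form: str = "corrected") -> float:
    """Noncentrality parameter of the CAF comparison for N cases.

    ``form="corrected"`` uses the (1 - gamma f) factor in the second term;
    ``form="as_printed"`` uses (1 - gamma). Both vanish at gamma = 1.
    """
    if not 0.0 < f < 1.0:
        raise ValueError("f must be in (0, 1)")
    if gamma * f >= 1.0:
        raise ValueError("gamma * f must be < 1")
    if n_cases < 0:
        raise ValueError("n_cases must be >= 0")
    log_term = math.log((1.0 - gamma * f) / (1.0 - f))
    if form == "corrected":
        factor = 1.0 - gamma * f
    elif form == "as_printed":
        factor = 1.0 - gamma
    else:
        raise ValueError(f"unknown form {form!r}")
    return 4.0 * n_cases * (gamma * f * math.log(gamma) + factor * log_term)


def power_at(lambda_ncp: float, alpha: float) -> float:
    """1 - F(F^-1(1 - alpha; central); lambda) for chi-square with 1 d.f."""
    if lambda_ncp < 0:
        raise ValueError("lambda must be >= 0")
    q = stats.chi2.isf(alpha, 1)
    if lambda_ncp == 0:
        return float(alpha)
    return float(stats.ncx2.sf(q, 1, lambda_ncp))


def solve_lambda(alpha: float, target_power: float) -> float:
    """NCP at which the 1-d.f. noncentral chi-square test reaches target power."""
    lo, hi = 1e-9, 10.0
    while power_at(hi, alpha) < target_power:
        hi *= 2.0
        if hi > 1e7:
            raise RuntimeError("failed to bracket the required NCP")
    return float(brentq(lambda l: power_at(l, alpha) - target_power, lo, hi, xtol=1e-10))


def required_sample_size(params: PowerParams, method: str = "exact") -> PowerResult:
    """Cases needed to reach the target power.

    ``method="approx"`` uses n ~= lambda_{alpha,beta} / (4 f [gamma ln gamma
    - (gamma - 1)]) (small-f limit); ``method="exact"`` finds the smallest
    integer N whose exact noncentral chi-square power meets the target, by
    bracketed bisection. Diverges at gamma = 1 (no effect to detect).
    """
    if params.gamma <= 1.0:
        raise ValueError("sample size diverges at gamma = 1")
    f = params.caf()
    lam_req = solve_lambda(params.alpha, params.target_power)
    n_approx = lam_req / (
        4.0 * f * (params.gamma * math.log(params.gamma) - (params.gamma - 1.0))
    )
    if method == "approx":
        n = int(math.ceil(n_approx))
        lam = ncp_lambda(n, params.gamma, f)
        return PowerResult(lam, power_at(lam, params.alpha), n)
    if method != "exact":
        raise ValueError(f"unknown method {method!r}")

    def _power(n: float) -> float:
        return power_at(ncp_lambda(n, params.gamma, f), params.alpha)

    hi = max(2, int(math.ceil(n_approx)))
    while _power(hi) < params.target_power:
        hi *= 2
    lo = 1
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if _power(mid) >= params.target_power:
            hi = mid
        else:
            lo = mid
    n = hi if _power(hi) >= params.target_power else None
    if n is None:
        raise RuntimeError("bracketed search failed")
    lam = ncp_lambda(n, params.gamma, f)
    return PowerResult(lam, power_at(lam, params.alpha), n)


def feasible_grid(
    gamma_range: Sequence[float],
    s_range: Sequence[float],
    mu_values: Sequence[float],
    params: Optional[PowerParams] = None,
    mode: str = "power",
) -> pd.DataFrame:
    """Power (or required N) over a (gamma, s, mu) grid with the fitness mask.

    Combinations violating s >= 0.013 * gamma (with 0.013 = prevalence x
    fitness reduction, overridable through ``params``) are marked
    infeasible and get NaN results. ``mode="power"`` needs
    ``params.n_cases``; ``mode="sample_size"`` inverts for the target power.
    """
    params = params or PowerParams()
    c = params.fitness_constant
    rows = []
    for mu in mu_values:
        for g in gamma_range:
            for s in s_range:
                feasible = s >= c * g
                row = {
                    "mu_lof": mu,
                    "gamma": g,
                    "s": s,
                    "f": equilibrium_caf(mu, s),
                    "feasible": feasible,
                    "lambda_ncp": np.nan,
                    "power": np.nan,
                    "n_required": np.nan,
                }
                if feasible and g > 1.0:
                    f = row["f"]
                    if mode == "power":
                        if params.n_cases is None:
                            raise ValueError("mode='power' needs params.n_cases")
                        lam = ncp_lambda(params.n_cases, g, f)
                        row["lambda_ncp"] = lam
                        row["power"] = power_at(lam, params.alpha)
                    elif mode == "sample_size":
                        p = PowerParams(
                            alpha=params.alpha,
                            target_power=params.target_power,
                            gamma=g,
                            s=s,
                            mu_lof=mu,
                            prevalence_pi=params.prevalence_pi,
                            fitness_reduction_sd=params.fitness_reduction_sd,
                        )
                        res = required_sample_size(p, method="exact")
                        row["lambda_ncp"] = res.lambda_ncp
                        row["power"] = res.power
                        row["n_required"] = res.n_required
                    else:
                        raise ValueError(f"unknown mode {mode!r}")
                rows.append(row)
    return pd.DataFrame(rows)
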