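"""Case-control burden of rare high-confidence LoF carriers.

Carrier rates are expressed per effective sample, where the effective sample
size is the (possibly fractional) number of samples multiplied by the
fraction of callable coding bases for the gene. The two-rate "Poisson test"
is the exact conditional binomial: given the combined carrier count K, the
case share is Binomial(K, exposure fraction) under the null. Against two
population references the larger of the two P values is carried forward
(conservative, robust to the choice of reference). Synonymous variants
provide a calibration surface: per-gene one-sided P values should be uniform
when case and control rates match, summarized by a Q-Q plot and a genomic
inflation factor lambda.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

CHI2_MEDIAN_1DF = 0.4549364231195724  # median of chi-square with 1 d.f.


@dataclass
class AlleleCountSet:
    """Carrier count with fractional effective sample size for one gene."""

    gene_id: str
    carriers: float
    sample_size: float
    callable_fraction: float = 1.0
    source: str = ""

    def __post_init__(self) -> None:
        if self.carriers < 0:
            raise ValueError("carriers must be >= 0")
        if not 0.0 <= self.callable_fraction <= 1.0:
            raise ValueError("callable_fraction outside [0, 1]")
        if self.carriers > 0 and self.effective_n <= 0:
            raise ValueError("positive carriers require a positive effective sample size")

    @property
    def effective_n(self) -> float:
        return self.sample_size * self.callable_fraction


@dataclass
class RateTestResult:
    rate_case: float
    rate_control: float
    p_one_sided: float
    source: str = ""


def carrier_rate(counts: AlleleCountSet) -> float:
    """Carriers per effective sample."""
    if counts.effective_n <= 0:
        raise ValueError("effective sample size must be > 0")
    return counts.carriers / counts.effective_n


def poisson_two_rate_test(case: AlleleCountSet, control: AlleleCountSet) -> RateTestResult:
    """One-sided (case rate > control rate) exact conditional binomial.

    Given K = k_case + k_control total carriers, the case carrier count is
    Binomial(K, n_case_eff / (n_case_eff + n_control_eff)) under equal rates;
    P = P(X >= k_case). Equivalent to the exact comparison of two Poisson
    rates with the effective sample sizes as exposures.
    """
    if case.effective_n <= 0 or control.effective_n <= 0:
        raise ValueError("both effective sample sizes must be > 0")
    k_case = int(round(case.carriers))
    k_ctrl = int(round(control.carriers))
    K = k_case + k_ctrl
    if K == 0:
        p = 1.0
    else:
        frac = case.effective_n / (case.effective_n + control.effective_n)
        p = float(stats.binom.sf(k_case - 1, K, frac))
    return RateTestResult(
        rate_case=carrier_rate(case),
        rate_control=carrier_rate(control),
        p_one_sided=p,
        source=control.source,
    )


def dual_control_max_p(p_ref1: float, p_ref2: float) -> float:
    """Conservative P against two references: take the larger."""
    for p in (p_ref1, p_ref2):
        if not 0.0 < p <= 1.0:
            raise ValueError(f"P value {p} outside (0, 1]")
    return max(p_ref1, p_ref2)


def synonymous_calibration(
    case_counts: Sequence[AlleleCountSet],
    control_counts: Sequence[AlleleCountSet],
) -> tuple[pd.DataFrame, float]:
    """Q-Q calibration of the burden test on (neutral) synonymous carriers.

    Computes the per-gene one-sided two-rate P, sorts into Q-Q points
    (expected vs observed -log10 P under uniformity), and the inflation
    factor lambda = median(chi2_1 quantile of 1 - P) / 0.4549. Genes are
    matched by order; at least 20 genes are required for a stable median.
    """
    if len(case_counts) != len(control_counts):
        raise ValueError("case and control count lists must align")
    if len(case_counts) < 20:
        raise ValueError("need >= 20 genes for calibration")
    rows = []
    for ca, co in zip(case_counts, control_counts):
        if ca.gene_id != co.gene_id:
            raise ValueError(f"gene mismatch: {ca.gene_id} vs {co.gene_id}")
        rows.append((ca.gene_id, poisson_two_rate_test(ca, co).p_one_sided))
    df = pd.DataFrame(rows, columns=["gene_id", "p"]).sort_values("p").reset_index(drop=True)
    m = len(df)
    df["expected_p"] = (np.arange(m) + 0.5) / m
    df["observed_neglog10"] = -np.log10(df["p"])
    df["expected_neglog10"] = -np.log10(df["expected_p"])
    # mid-P style conversion of the discrete one-sided P to a chi-square quantile
    chisq = stats.chi2.isf(np.clip(df["p"].to_numpy(), 1e-300, 1.0), 1)
    lam = float(np.median(chisq) / CHI2_MEDIAN_1DF)
    return df, lam


def qq_plot(calibration: pd.DataFrame, path, inflation_lambda: Optional[float] = None) -> None:
    """Write a Q-Q plot (PNG/PDF by extension) of the calibration table."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(calibration["expected_neglog10"], calibration["observed_neglog10"], s=8)
    lim = max(calibration["expected_neglog10"].max(), calibration["observed_neglog10"].max())
    ax.plot([0, lim], [0, lim], color="grey", lw=1)
    ax.set_xlabel("expected -log10 P")
    ax.set_ylabel("observed -log10 P")
    if inflation_lambda is not None:
        ax.set_title(f"synonymous calibration (lambda = {inflation_lambda:.2f})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
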