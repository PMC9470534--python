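"""De novo variant analysis.

Preprocessing (100-bp within-gene collapsing to the most severe variant,
twin deduplication), cohort-level burden (rate ratio / rate difference with
the rate difference doubling as the population-attributable-risk
contribution), positive-predictive-value weights per (constraint x class)
stratum, a severity-weighted gene-level enrichment test against the Poisson
expectation (DeNovoWEST-style), and a gene-set permutation test that
re-places mutations across constrained genes proportionally to class-specific
mutation rates (DNENRICH-style, with sequence context collapsed into the
per-gene class rates).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from rarefam.mutation import GeneModel, expected_dnv_count

logger = logging.getLogger(__name__)

SEVERITY_ORDER = ("lof", "dmis", "other_mis", "syn")  # most to least severe
NONSYN_CLASSES = ("lof", "dmis", "other_mis")
CLUSTER_WINDOW_BP = 100

#: DeNovoWEST-style exome-wide significance threshold, 0.05 / (18,000 genes x 2 tests)
EXOME_WIDE_DNV_ALPHA = 0.05 / (18_000 * 2)

DNV_COLUMNS = ["individual_id", "gene_id", "variant_class", "position", "twin_group"]


def _severity_rank(variant_class: str) -> int:
    return SEVERITY_ORDER.index(variant_class)


def preprocess_dnvs(records: pd.DataFrame, pedigrees=None) -> pd.DataFrame:
    """Collapse within-100-bp same-gene clusters and deduplicate twin sharing.

    Per (individual, gene), variants falling in a chain whose consecutive
    positions are <= 100 bp apart are collapsed to the single most severe
    variant (ties: smallest position). Identical variants shared within a
    twin group are counted once (the lexicographically first carrier is
    kept). Idempotent.
    """
    if not len(records):
        return records.copy()
    df = records.copy()
    if "twin_group" not in df.columns:
        df["twin_group"] = None
    # twin dedup: one record per (twin_group, gene, class, position)
    twinned = df["twin_group"].notna()
    if twinned.any():
        tw = df[twinned].sort_values("individual_id")
        tw = tw.drop_duplicates(subset=["twin_group", "gene_id", "variant_class", "position"])
        df = pd.concat([df[~twinned], tw], ignore_index=True)
    # 100-bp clustering per individual-gene
    kept = []
    for _, grp in df.groupby(["individual_id", "gene_id"], sort=False):
        grp = grp.sort_values("position")
        pos = grp["position"].to_numpy()
        cluster_start = np.r_[True, np.diff(pos) > CLUSTER_WINDOW_BP].cumsum()
        for _, cluster in grp.groupby(cluster_start):
            best = min(
                cluster.itertuples(index=True),
                key=lambda r: (_severity_rank(r.variant_class), r.position),
            )
            kept.append(best.Index)
    out = df.loc[sorted(kept)].reset_index(drop=True)
    return out


def poisson_tail_p(observed: int, expected: float) -> float:
    """Exact one-sided P(X >= observed) for X ~ Poisson(expected)."""
    if observed < 0:
        raise ValueError("observed count must be >= 0")
    if observed == 0:
        return 1.0
    if expected <= 0:
        raise ValueError("expected must be > 0 when observed > 0")
    return float(stats.poisson.sf(observed - 1, expected))


@dataclass
class BurdenResult:
    rate_case: float
    rate_control: float
    rate_ratio: float
    rate_difference: float
    ci_low: float
    ci_high: float
    p_value: float
    n_case: int
    n_control: int

    @property
    def par_contribution(self) -> float:
        """Excess damaging-DNV rate per offspring (PAR contribution)."""
        return self.rate_difference


def cohort_burden(
    case_records: pd.DataFrame,
    control_records: pd.DataFrame,
    n_case_trios: int,
    n_control_trios: int,
    gene_subset: Optional[set] = None,
    classes: Sequence[str] = ("lof", "dmis"),
) -> BurdenResult:
    """Damaging-DNV rate comparison between case and control offspring.

    One-sided P (cases higher) from the exact conditional binomial given the
    total event count; 95% CI on the rate difference by the normal
    approximation.
    """
    if n_case_trios <= 0 or n_control_trios <= 0:
        raise ValueError("trio counts must be positive")

    def _count(df: pd.DataFrame) -> int:
        if not len(df):
            return 0
        m = df["variant_class"].isin(classes)
        if gene_subset is not None:
            m &= df["gene_id"].isin(gene_subset)
        return int(m.sum())

    k_case, k_ctrl = _count(case_records), _count(control_records)
    rate_case = k_case / n_case_trios
    rate_ctrl = k_ctrl / n_control_trios
    diff = rate_case - rate_ctrl
    se = math.sqrt(rate_case / n_case_trios + rate_ctrl / n_control_trios)
    ratio = math.inf if rate_ctrl == 0 else rate_case / rate_ctrl
    K = k_case + k_ctrl
    if K == 0:
        p = 1.0
    else:
        frac = n_case_trios / (n_case_trios + n_control_trios)
        p = float(stats.binom.sf(k_case - 1, K, frac))
    return BurdenResult(
        rate_case=rate_case,
        rate_control=rate_ctrl,
        rate_ratio=ratio,
        rate_difference=diff,
        ci_low=diff - 1.96 * se,
        ci_high=diff + 1.96 * se,
        p_value=p,
        n_case=k_case,
        n_control=k_ctrl,
    )


# ---------------------------------------------------------------------------
# PPV weights
# ---------------------------------------------------------------------------

class WeightTable:
    """Variant-class weights per (constrained, class) stratum, in [0, 1]."""

    def __init__(self, weights: Mapping[tuple[bool, str], float]):
        for key, w in weights.items():
            if not 0.0 <= w <= 1.0:
                raise ValueError(f"weight {w} for stratum {key} outside [0, 1]")
        self._weights = dict(weights)

    def get(self, constrained: bool, variant_class: str) -> float:
        return self._weights[(constrained, variant_class)]

    def items(self):
        return self._weights.items()

    def __eq__(self, other) -> bool:
        return isinstance(other, WeightTable) and self._weights == other._weights


def derive_ppv_weights(
    observed_by_stratum: Mapping[tuple[bool, str], float],
    expected_by_stratum: Mapping[tuple[bool, str], float],
) -> WeightTable:
    """Positive-predictive-value weight max(0, (O - E) / O) per stratum.

    The weight estimates the fraction of observed mutations in the stratum
    that are in excess of the null expectation (and hence plausibly causal).
    Strata with O <= E (no excess) get weight 0.
    """
    weights = {}
    for stratum, obs in observed_by_stratum.items():
        exp = expected_by_stratum[stratum]
        if exp <= 0:
            raise ValueError(f"expected count must be > 0 in stratum {stratum}")
        weights[stratum] = 0.0 if obs <= 0 else max(0.0, (obs - exp) / obs)
    return WeightTable(weights)


def flat_weights(value: float = 1.0, classes: Sequence[str] = NONSYN_CLASSES) -> WeightTable:
    return WeightTable({(c, k): value for c in (False, True) for k in classes})


# ---------------------------------------------------------------------------
# Weighted gene-level enrichment test
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    gene_id: str
    observed_score: float
    p_value: float
    n_sim: int
    seed: Optional[int]
    expected_by_class: dict
    method: str = "simulation"


def _enrichment_inputs(
    gene: GeneModel,
    counts_by_class: Mapping[str, int],
    weights: WeightTable,
    n_trios: int,
    classes: Sequence[str],
):
    w = np.array([weights.get(gene.constrained, c) for c in classes])
    lam = np.array(
        [
            expected_dnv_count(
                n_trios, gene.mu(c), gene.callable_fraction_case, gene.chrom_class
            )
            for c in classes
        ]
    )
    obs = np.array([float(counts_by_class.get(c, 0)) for c in classes])
    return w, lam, obs


def weighted_enrichment_score_tail(
    weights: Sequence[float], lambdas: Sequence[float], observed_score: float
) -> float:
    """Exact P(sum_c w_c X_c >= observed) for independent X_c ~ Poisson(lambda_c).

    Enumerates each class count up to a truncation point leaving < 1e-12
    probability mass per class, convolving the weighted-score distribution.
    Intended for the small expectations typical of per-gene de novo counts.
    """
    scores = np.array([0.0])
    probs = np.array([1.0])
    for w, lam in zip(weights, lambdas):
        if lam <= 0:
            continue
        kmax = int(stats.poisson.isf(1e-13, lam)) + 1
        k = np.arange(kmax + 1)
        pmf = stats.poisson.pmf(k, lam)
        scores = (scores[:, None] + w * k[None, :]).ravel()
        probs = (probs[:, None] * pmf[None, :]).ravel()
        # consolidate duplicate scores and prune negligible mass
        order = np.argsort(scores)
        scores, probs = scores[order], probs[order]
        uniq, idx = np.unique(np.round(scores, 9), return_inverse=True)
        probs = np.bincount(idx, weights=probs)
        scores = uniq
        keep = probs > 1e-300
        scores, probs = scores[keep], probs[keep]
    return float(probs[scores >= observed_score - 1e-9].sum())


def weighted_enrichment_test(
    gene: GeneModel,
    counts_by_class: Mapping[str, int],
    weights: WeightTable,
    n_trios: int,
    n_sim: int = 100_000,
    seed: Optional[int] = 0,
    classes: Sequence[str] = NONSYN_CLASSES,
    method: str = "simulation",
) -> EnrichmentResult:
    """Severity-weighted enrichment of nonsynonymous DNVs in one gene.

    The observed score is ``sum_class weight * count``; under the null each
    class count is Poisson with mean ``expected_dnv_count``. ``method
    ="simulation"`` draws the null (P = (1 + #{sim >= obs}) / (1 + n_sim),
    reproducible given ``seed``); ``method="exact"`` computes the same tail
    by enumeration, with no Monte Carlo floor.
    """
    w, lam, obs = _enrichment_inputs(gene, counts_by_class, weights, n_trios, classes)
    observed_score = float(w @ obs)
    expected = {c: float(l) for c, l in zip(classes, lam)}
    if observed_score <= 0:
        return EnrichmentResult(gene.gene_id, observed_score, 1.0, 0, seed, expected, method)
    if float(lam.sum()) <= 0:
        logger.warning(
            "gene %s: zero expected counts in all classes with nonzero observed score",
            gene.gene_id,
        )
        return EnrichmentResult(
            gene.gene_id, observed_score, 1.0 / (1.0 + n_sim), n_sim, seed, expected, method
        )
    if method == "exact":
        p = weighted_enrichment_score_tail(w, lam, observed_score)
        return EnrichmentResult(gene.gene_id, observed_score, p, 0, seed, expected, "exact")
    if method != "simulation":
        raise ValueError(f"unknown method {method!r}")
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    rng = np.random.default_rng(seed)
    exceed = 0
    chunk = 2_000_000 // max(1, len(classes))
    remaining = n_sim
    while remaining > 0:
        m = min(chunk, remaining)
        draws = rng.poisson(lam, size=(m, len(classes)))
        sim_scores = draws @ w
        exceed += int((sim_scores >= observed_score - 1e-9).sum())
        remaining -= m
    p = (1.0 + exceed) / (1.0 + n_sim)
    return EnrichmentResult(gene.gene_id, observed_score, p, n_sim, seed, expected, "simulation")


# ---------------------------------------------------------------------------
# Gene-set permutation test (DNENRICH-style)
# ---------------------------------------------------------------------------

@dataclass
class GenesetPermutationResult:
    fold_enrichment: float
    p_value: float
    ci_low: float
    ci_high: float
    observed_stat: float
    n_perm: int
    seed: Optional[int]


def _weighted_set_fraction(
    records: pd.DataFrame,
    geneset: set,
    weights: WeightTable,
    classes: Sequence[str],
) -> tuple[float, float]:
    """(weighted sum in set, weighted total) over constrained-gene records."""
    in_set = total = 0.0
    for row in records.itertuples(index=False):
        if row.variant_class not in classes:
            continue
        w = weights.get(True, row.variant_class)
        total += w
        if row.gene_id in geneset:
            in_set += w
    return in_set, total


def geneset_permutation_test(
    case_records: pd.DataFrame,
    geneset: set,
    genes: Sequence[GeneModel],
    weights: WeightTable,
    n_perm: int = 10_000,
    seed: Optional[int] = 0,
    control_records: Optional[pd.DataFrame] = None,
    classes: Sequence[str] = ("lof", "dmis"),
) -> GenesetPermutationResult:
    """Gene-set enrichment of damaging DNVs by mutation placement.

    The statistic is the weighted fraction of case mutations falling in the
    set (divided by the same fraction for control mutations when controls
    are supplied). The null re-places each mutation onto the constrained-gene
    universe with probability proportional to the gene's class-specific
    mutation rate, holding the number of mutations per class (and the
    case/control split) fixed. The 95% CI of the fold enrichment assumes
    log(FE) is normal with s.d. set by the permutation P value.
    """
    if not geneset:
        raise ValueError("geneset must be non-empty")
    universe = [g for g in genes if g.constrained]
    universe_ids = {g.gene_id for g in universe}
    if not geneset <= universe_ids:
        raise ValueError("geneset must be a subset of the constrained genes")
    rng = np.random.default_rng(seed)

    def _restrict(df: pd.DataFrame) -> pd.DataFrame:
        return df[df["gene_id"].isin(universe_ids) & df["variant_class"].isin(classes)]

    case_r = _restrict(case_records)
    ctrl_r = _restrict(control_records) if control_records is not None else None

    def _stat(in_case, tot_case, in_ctrl, tot_ctrl):
        frac_case = in_case / tot_case if tot_case > 0 else np.nan
        if ctrl_r is None:
            return frac_case
        frac_ctrl = in_ctrl / tot_ctrl if np.all(tot_ctrl > 0) else np.nan
        return frac_case / frac_ctrl

    in_case, tot_case = _weighted_set_fraction(case_r, geneset, weights, classes)
    in_ctrl, tot_ctrl = (
        _weighted_set_fraction(ctrl_r, geneset, weights, classes) if ctrl_r is not None else (0, 0)
    )
    observed = _stat(in_case, tot_case, in_ctrl, tot_ctrl)

    # class-specific probability that a re-placed mutation lands in the set
    p_set = {}
    for c in classes:
        mus = np.array([g.mu(c) for g in universe])
        tot = mus.sum()
        p_set[c] = float(mus[[g.gene_id in geneset for g in universe]].sum() / tot) if tot > 0 else 0.0

    def _permuted(df: pd.DataFrame) -> tuple[np.ndarray, float]:
        in_sum = np.zeros(n_perm)
        total = 0.0
        for c in classes:
            n_c = int((df["variant_class"] == c).sum())
            if n_c == 0:
                continue
            w = weights.get(True, c)
            total += w * n_c
            in_sum += w * rng.binomial(n_c, p_set[c], size=n_perm)
        return in_sum, total

    perm_case_in, perm_case_tot = _permuted(case_r)
    if ctrl_r is not None:
        perm_ctrl_in, perm_ctrl_tot = _permuted(ctrl_r)
    else:
        perm_ctrl_in, perm_ctrl_tot = np.zeros(n_perm), 0.0
    perm_stats = _stat(perm_case_in, perm_case_tot, perm_ctrl_in, perm_ctrl_tot)
    perm_stats = np.asarray(perm_stats, dtype=float)

    p = (1.0 + np.sum(perm_stats >= observed - 1e-12)) / (1.0 + n_perm)
    mean_perm = float(np.nanmean(perm_stats))
    fe = observed / mean_perm if mean_perm > 0 else math.inf
    if fe > 0 and fe != 1.0 and 0 < p < 1:
        z = stats.norm.ppf(1.0 - p)
        sigma = abs(math.log(fe)) / z if z > 0 else math.inf
        ci_low, ci_high = math.exp(math.log(fe) - 1.96 * sigma), math.exp(
            math.log(fe) + 1.96 * sigma
        )
    else:
        ci_low = ci_high = fe
    return GenesetPermutationResult(fe, float(p), ci_low, ci_high, float(observed), n_perm, seed)
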