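"""Transmission disequilibrium analysis of rare high-confidence LoF alleles.

Rare alleles are first identified in heterozygous parents without an ASD
diagnosis or intellectual disability; each eligible parental allele x
offspring pair yields one transmission record. Overtransmission to affected
offspring is tested with an exact binomial against a null transmission
probability of 0.5; the per-gene TDT statistic is z = (T - NT) / sqrt(T + NT).
Duos count as half-trios when expressing overtransmission per trio. On the
X chromosome (non-PAR) only transmissions from unaffected mothers are
considered. Gene-set and phenotype-group contrasts use 2x2 chi-square tests
without continuity correction (large-count regime).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from rarefam.mutation import X_NONPAR
from rarefam.pedigree import MALE, Pedigree, _one_per_twin_group

logger = logging.getLogger(__name__)

TRANSMISSION_COLUMNS = [
    "gene_id",
    "parent_id",
    "offspring_id",
    "transmitted",
    "offspring_affected",
    "offspring_sex",
    "chrom_class",
    "phenotype_group",
]


@dataclass
class TdtCounts:
    T: int = 0
    NT: int = 0
    n_trios: int = 0
    n_duos: int = 0

    def __post_init__(self) -> None:
        if self.T < 0 or self.NT < 0:
            raise ValueError("transmission counts must be >= 0")


@dataclass
class TdtResult:
    counts: TdtCounts
    z: float
    p_binomial: float
    overtransmission_per_trio: float


def tally_transmissions(
    variants: pd.DataFrame,
    pedigrees: Sequence[Pedigree],
    max_af: float = 1e-5,
    require_high_confidence: bool = False,
    classes: Sequence[str] = ("lof",),
    pext_baseline: float = 0.1,
    gene_pext: Optional[Mapping[str, float]] = None,
) -> pd.DataFrame:
    """One transmission record per eligible heterozygous parental allele x offspring.

    ``variants`` needs columns individual_id, gene_id, variant_class,
    allele_id; optional af, high_confidence, pext, chrom_class. A parent is
    eligible if unaffected, sequenced and not flagged excluded (ASD diagnosis
    or intellectual disability). Transmission is resolved by the offspring
    carrying the same ``allele_id``. X non-PAR alleles only generate records
    from mothers. Monozygotic twin offspring are counted once.
    """
    if not len(variants):
        return pd.DataFrame(columns=TRANSMISSION_COLUMNS)
    v = variants[variants["variant_class"].isin(classes)]
    if "af" in v.columns:
        v = v[v["af"] <= max_af]
    if require_high_confidence and "high_confidence" in v.columns:
        v = v[v["high_confidence"].astype(bool)]
    if "pext" in v.columns:
        thr = v["gene_id"].map(gene_pext).fillna(pext_baseline) if gene_pext else pext_baseline
        v = v[v["pext"] >= thr]
    by_ind = v.groupby("individual_id")
    carriers = {iid: set(grp["allele_id"]) for iid, grp in by_ind}
    records = []
    for ped in pedigrees:
        for parent in ped.members.values():
            if parent.affected or parent.excluded_parent or not parent.sequenced:
                continue
            if parent.id not in by_ind.groups:
                continue
            kids = [
                k
                for k in _one_per_twin_group(ped.offspring(parent.id))
                if k.sequenced
            ]
            if not kids:
                continue
            for row in by_ind.get_group(parent.id).itertuples(index=False):
                chrom = getattr(row, "chrom_class", "autosomal")
                if chrom == X_NONPAR and parent.sex == MALE:
                    continue  # father-offspring X transmission never counted
                for kid in kids:
                    records.append(
                        {
                            "gene_id": row.gene_id,
                            "parent_id": parent.id,
                            "offspring_id": kid.id,
                            "transmitted": row.allele_id in carriers.get(kid.id, ()),
                            "offspring_affected": kid.affected,
                            "offspring_sex": kid.sex,
                            "chrom_class": chrom,
                            "phenotype_group": kid.cognitive_impairment,
                        }
                    )
    return pd.DataFrame(records, columns=TRANSMISSION_COLUMNS)


def count_trios_duos(pedigrees: Sequence[Pedigree], affected: bool = True) -> tuple[int, int]:
    """Number of (both-parent, single-parent) offspring of the given status."""
    n_trios = n_duos = 0
    for ped in pedigrees:
        for kid in _one_per_twin_group(ped.members.values()):
            if kid.affected != affected or not kid.sequenced:
                continue
            n_parents = sum(
                1
                for p in ped.parents(kid.id)
                if p.sequenced and not p.affected and not p.excluded_parent
            )
            if n_parents == 2:
                n_trios += 1
            elif n_parents == 1:
                n_duos += 1
    return n_trios, n_duos


def tdt_counts(
    records: pd.DataFrame,
    affected_only: bool = True,
    gene_id: Optional[str] = None,
    n_trios: int = 0,
    n_duos: int = 0,
) -> TdtCounts:
    r = records
    if affected_only and len(r):
        r = r[r["offspring_affected"]]
    if gene_id is not None and len(r):
        r = r[r["gene_id"] == gene_id]
    t = int(r["transmitted"].sum()) if len(r) else 0
    nt = int((~r["transmitted"].astype(bool)).sum()) if len(r) else 0
    return TdtCounts(T=t, NT=nt, n_trios=n_trios, n_duos=n_duos)


def tdt_binomial(counts: TdtCounts) -> float:
    """Exact one-sided binomial P(X >= T | n = T + NT, p = 0.5)."""
    n = counts.T + counts.NT
    if n == 0:
        return 1.0
    return float(stats.binom.sf(counts.T - 1, n, 0.5))


def tdt_z(counts: TdtCounts) -> float:
    """TDT statistic z = (T - NT) / sqrt(T + NT); 0 for no informative events."""
    n = counts.T + counts.NT
    if n == 0:
        return 0.0
    return (counts.T - counts.NT) / math.sqrt(n)


def overtransmission_rate(counts: TdtCounts) -> float:
    """Net overtransmission (T - NT) per trio-equivalent (duos = half-trios)."""
    denom = counts.n_trios + 0.5 * counts.n_duos
    if denom <= 0:
        raise ValueError("n_trios + 0.5 * n_duos must be > 0")
    return (counts.T - counts.NT) / denom


def tdt_result(counts: TdtCounts) -> TdtResult:
    return TdtResult(
        counts=counts,
        z=tdt_z(counts),
        p_binomial=tdt_binomial(counts),
        overtransmission_per_trio=overtransmission_rate(counts)
        if counts.n_trios + 0.5 * counts.n_duos > 0
        else math.nan,
    )


def _chi2_2x2(a: float, b: float, c: float, d: float) -> float:
    """Pearson chi-square P on a 2x2 table, no continuity correction."""
    n = a + b + c + d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        return 1.0
    x2 = n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
    return float(stats.chi2.sf(x2, 1))


def geneset_tdt_enrichment(
    set_counts: TdtCounts, background_counts: TdtCounts
) -> tuple[float, float]:
    """Odds ratio and two-sided chi-square P for T:NT in set vs background."""
    t_s, nt_s = set_counts.T, set_counts.NT
    t_b, nt_b = background_counts.T, background_counts.NT
    if min(t_s + nt_s, t_b + nt_b) < 0 or any(x < 0 for x in (t_s, nt_s, t_b, nt_b)):
        raise ValueError("all cells must be >= 0")
    if nt_s == 0 or t_b == 0:
        logger.warning("zero marginal cell: odds ratio undefined")
        odds = math.inf if t_s > 0 else math.nan
    else:
        odds = (t_s * nt_b) / (nt_s * t_b)
    return odds, _chi2_2x2(t_s, nt_s, t_b, nt_b)


def compare_overtransmission(group_a: TdtResult, group_b: TdtResult) -> tuple[float, float]:
    """Ratio of per-trio overtransmission rates and chi-square P on (T, NT) x group."""
    ra, rb = group_a.overtransmission_per_trio, group_b.overtransmission_per_trio
    if rb == 0:
        logger.warning("zero overtransmission rate in comparison group: ratio infinite")
        ratio = math.inf if ra > 0 else math.nan
    else:
        ratio = ra / rb
    p = _chi2_2x2(group_a.counts.T, group_a.counts.NT, group_b.counts.T, group_b.counts.NT)
    return ratio, p


def prioritize_tdt_genes(per_gene: pd.DataFrame, genes: pd.DataFrame) -> pd.Series:
    """Stage-1 TDT prioritization mask.

    A gene is prioritized when its TDT z exceeds 1 and it sits in the top
    LOEUF decile, or in the top two LOEUF deciles with an A-risk score of at
    least 0.4. ``per_gene`` needs columns gene_id and z; ``genes`` needs
    gene_id, loeuf_decile and a_risk.
    """
    merged = per_gene.merge(genes[["gene_id", "loeuf_decile", "a_risk"]], on="gene_id", how="left")
    a_risk = merged["a_risk"].fillna(0.0)
    mask = (merged["z"] > 1) & (
        (merged["loeuf_decile"] == 1) | ((merged["loeuf_decile"] <= 2) & (a_risk >= 0.4))
    )
    return pd.Series(mask.to_numpy(), index=per_gene.index, name="tdt_prioritized")
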