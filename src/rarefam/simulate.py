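"""Synthetic family cohorts and population controls with known per-gene truth.

The generator emulates the statistical structure the analysis stages assume,
at the carrier level (no sequence, no linkage, no ancestry structure):

* a gene panel with haploid LoF mutation rates mu, selection coefficients s
  and relative risks gamma (gamma = 1 for non-risk genes), and population
  cumulative allele frequency at mutation-selection equilibrium f = mu / s;
* trio/duo parents carrying a gene's LoF allele with probability 2f
  (rare-variant approximation; every simulated allele is individually
  ultra-rare, the gene-level f being spread over many such alleles);
* transmission to affected offspring distorted to gamma / (1 + gamma), and
  to unaffected offspring (1 - gamma pi) / ((1 - gamma pi) + (1 - pi));
* per-gene de novo counts Poisson(2 N mu) in control offspring and
  Poisson(2 N mu gamma) for the LoF class in case offspring (the de novo
  enrichment factor is tied to the same gamma as inherited risk);
* population-control carrier counts Binomial(n, 2f) per gene, and singleton
  cases enriched through the relative-risk conditional
  P(carrier | case) = q gamma / (q gamma + 1 - q) with q = 2(f + mu);
* a carrier-dependent binary cognitive-impairment phenotype.

All draws descend from a single integer seed; identical configs reproduce
identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from rarefam.mutation import AUTOSOMAL, GeneModel, genes_to_frame
from rarefam.pedigree import FEMALE, MALE, Individual, Pedigree, write_ped

#: male fraction among affected offspring, from a 4.2 male:female case ratio
MALE_CASE_FRACTION = 4.2 / 5.2

#: crude neutral-variation proxy: synonymous CAF = syn_caf_scale * mu_syn
SYN_CAF_SCALE = 500.0

VARIANT_COLUMNS = [
    "individual_id",
    "family_id",
    "gene_id",
    "variant_class",
    "allele_id",
    "af",
    "high_confidence",
    "pext",
    "inheritance",
    "chrom_class",
]


Distribution = tuple  # ("fixed", v) | ("loguniform", lo, hi) | ("uniform", lo, hi)


def _draw(dist: Distribution, size: int, rng: np.random.Generator) -> np.ndarray:
    kind = dist[0]
    if kind == "fixed":
        return np.full(size, float(dist[1]))
    if kind == "loguniform":
        lo, hi = float(dist[1]), float(dist[2])
        return np.exp(rng.uniform(np.log(lo), np.log(hi), size))
    if kind == "uniform":
        return rng.uniform(float(dist[1]), float(dist[2]), size)
    raise ValueError(f"unknown distribution {dist!r}")


@dataclass
class SimConfig:
    """Study conditions for one synthetic cohort.

    Defaults mirror the scale of the real two-stage study: a 5,000-trio
    family arm, ~2,000 duos, 5,764 unaffected comparison trios, 15,780
    unrelated singleton cases and two population reference panels of 104,068
    and 132,345 subjects.
    """

    seed: int = 0
    n_genes: int = 1000
    risk_gene_fraction: float = 0.02
    gamma_distribution: Distribution = ("loguniform", 2.0, 10.0)
    s_distribution: Distribution = ("loguniform", 0.01, 0.5)
    mu_lof_distribution: Distribution = ("loguniform", 1e-7, 1e-5)
    n_trios: int = 5000
    n_duos: int = 2000
    n_control_trios: int = 5764
    n_singleton_cases: int = 15780
    control_panel_sizes: tuple[int, ...] = (104068, 132345)
    prevalence_pi: float = 1.0 / 54.0
    impairment_base_rate: float = 0.5
    impairment_carrier_rate: float = 0.88
    enforce_fitness_constraint: bool = True
    fitness_constant: float = 0.013  # prevalence x fitness reduction s_D

    def __post_init__(self) -> None:
        for name in (
            "n_genes",
            "n_trios",
            "n_duos",
            "n_control_trios",
            "n_singleton_cases",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.risk_gene_fraction <= 1.0:
            raise ValueError("risk_gene_fraction outside [0, 1]")


TRUTH_COLUMNS = ["gene_id", "is_risk", "gamma", "s", "mu_lof", "f", "expected_t_nt_ratio"]


def simulate_gene_panel(cfg: SimConfig) -> tuple[list[GeneModel], pd.DataFrame]:
    """Gene panel plus truth table (per-gene gamma, s, mu, f = mu/s).

    Risk genes are drawn with the configured gamma and, when the fitness
    constraint is enforced, s resampled into [0.013 gamma, s_max]; an
    infeasible constraint raises with the offending (gamma, s) range. Risk
    genes are placed in the most constrained stratum (top LOEUF decile).
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_genes
    gene_ids = [f"G{i:05d}" for i in range(n)]
    n_risk = int(round(cfg.risk_gene_fraction * n))
    is_risk = np.zeros(n, dtype=bool)
    if n_risk:
        is_risk[rng.choice(n, size=n_risk, replace=False)] = True
    mu_lof = _draw(cfg.mu_lof_distribution, n, rng)
    s = _draw(cfg.s_distribution, n, rng)
    gamma = np.ones(n)
    gamma[is_risk] = _draw(cfg.gamma_distribution, int(is_risk.sum()), rng)
    if cfg.enforce_fitness_constraint and n_risk:
        s_min = cfg.fitness_constant * gamma[is_risk]
        s_max = float(cfg.s_distribution[-1])
        bad = s_min > s_max
        if bad.any():
            pairs = [(float(g), float(m)) for g, m in zip(gamma[is_risk][bad], s_min[bad])]
            raise ValueError(f"fitness constraint infeasible for (gamma, min s): {pairs}")
        # resample the violating risk genes' s into [0.013 gamma, s_max]
        viol = s[is_risk] < s_min
        if viol.any():
            lo, hi = s_min[viol], np.full(int(viol.sum()), s_max)
            resampled = np.exp(rng.uniform(np.log(lo), np.log(np.maximum(hi, lo))))
            s_risk = s[is_risk]
            s_risk[viol] = np.maximum(resampled, lo)
            s[is_risk] = s_risk
    f = mu_lof / s
    if np.any(2 * f > 0.1):
        worst = f.max()
        raise ValueError(f"rare-variant regime violated: 2f = {2 * worst:.3g} > 0.1")
    loeuf = rng.integers(1, 11, size=n)
    loeuf[is_risk] = 1
    pli = np.where(loeuf <= 2, rng.uniform(0.5, 1.0, n), rng.uniform(0.0, 0.5, n))
    a_risk = rng.uniform(0.0, 1.0, n)
    a_risk[is_risk] = rng.uniform(0.4, 1.0, int(is_risk.sum()))
    genes = [
        GeneModel(
            gene_id=gene_ids[i],
            chrom_class=AUTOSOMAL,
            mu_lof=float(mu_lof[i]),
            mu_dmis=float(mu_lof[i]),  # damaging-missense rate comparable to LoF
            mu_mis=float(5.0 * mu_lof[i]),
            mu_syn=float(3.0 * mu_lof[i]),
            pli=float(pli[i]),
            loeuf_decile=int(loeuf[i]),
            a_risk=float(a_risk[i]),
        )
        for i in range(n)
    ]
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "is_risk": is_risk,
            "gamma": gamma,
            "s": s,
            "mu_lof": mu_lof,
            "f": f,
            "expected_t_nt_ratio": gamma,
        },
        columns=TRUTH_COLUMNS,
    )
    return genes, truth


def _make_families(cfg: SimConfig, rng: np.random.Generator) -> list[Pedigree]:
    """Trios, duos (mother-child) and unaffected comparison trios."""
    peds = []

    def _child_sex() -> str:
        return MALE if rng.random() < MALE_CASE_FRACTION else FEMALE

    for i in range(cfg.n_trios):
        fid = f"T{i:05d}"
        peds.append(
            Pedigree(
                fid,
                [
                    Individual(f"{fid}_F", fid, sex=MALE),
                    Individual(f"{fid}_M", fid, sex=FEMALE),
                    Individual(
                        f"{fid}_C", fid, father_id=f"{fid}_F", mother_id=f"{fid}_M",
                        sex=_child_sex(), affected=True,
                    ),
                ],
            )
        )
    for i in range(cfg.n_duos):
        fid = f"D{i:05d}"
        peds.append(
            Pedigree(
                fid,
                [
                    Individual(f"{fid}_M", fid, sex=FEMALE),
                    Individual(
                        f"{fid}_C", fid, mother_id=f"{fid}_M", sex=_child_sex(), affected=True
                    ),
                ],
            )
        )
    for i in range(cfg.n_control_trios):
        fid = f"U{i:05d}"
        peds.append(
            Pedigree(
                fid,
                [
                    Individual(f"{fid}_F", fid, sex=MALE),
                    Individual(f"{fid}_M", fid, sex=FEMALE),
                    Individual(
                        f"{fid}_C", fid, father_id=f"{fid}_F", mother_id=f"{fid}_M",
                        sex=MALE if rng.random() < 0.5 else FEMALE, affected=False,
                    ),
                ],
            )
        )
    return peds


def simulate_parents_and_transmission(
    panel: Sequence[GeneModel],
    truth: pd.DataFrame,
    cfg: SimConfig,
    rng: Optional[np.random.Generator] = None,
    pedigrees: Optional[list[Pedigree]] = None,
) -> tuple[list[Pedigree], pd.DataFrame]:
    """Parental LoF carriers and their (distorted) transmissions.

    Each parent carries a gene's LoF allele with probability 2 f_g; a
    heterozygous parent transmits to an affected child with probability
    gamma / (1 + gamma) and to an unaffected child with probability
    (1 - gamma pi) / ((1 - gamma pi) + (1 - pi)). Returns the pedigrees and
    a variant-observation table with one row per carrier (parent rows plus
    child rows for transmitted alleles).
    """
    rng = rng or np.random.default_rng(cfg.seed + 1)
    peds = pedigrees if pedigrees is not None else _make_families(cfg, rng)
    parent_rows = []  # (parent_id, family_id, child_id, child_affected)
    for ped in peds:
        for m in ped.members.values():
            kids = ped.offspring(m.id)
            if kids:
                parent_rows.append((m.id, ped.family_id, kids[0].id, kids[0].affected))
    n_par = len(parent_rows)
    pi = cfg.prevalence_pi
    rows = []
    for g, f, gamma in truth[["gene_id", "f", "gamma"]].itertuples(index=False):
        if f <= 0:
            continue
        k = rng.binomial(n_par, min(2.0 * f, 1.0))
        if k == 0:
            continue
        idx = rng.choice(n_par, size=k, replace=False)
        p_aff = gamma / (1.0 + gamma)
        p_unaff = (1.0 - gamma * pi) / ((1.0 - gamma * pi) + (1.0 - pi))
        for j in idx:
            parent_id, fid, child_id, child_affected = parent_rows[j]
            allele = f"{g}:{parent_id}"
            rows.append((parent_id, fid, g, "lof", allele, 1e-6, True, 1.0, "inherited", AUTOSOMAL))
            p_t = p_aff if child_affected else p_unaff
            if rng.random() < p_t:
                rows.append(
                    (child_id, fid, g, "lof", allele, 1e-6, True, 1.0, "inherited", AUTOSOMAL)
                )
    variants = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    return peds, variants


def simulate_dnvs(
    panel: Sequence[GeneModel],
    truth: pd.DataFrame,
    cfg: SimConfig,
    rng: Optional[np.random.Generator] = None,
    pedigrees: Optional[list[Pedigree]] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene de novo records for case and control offspring.

    Control offspring draw Poisson(2 N mu_class) per gene and class; case
    offspring draw Poisson(2 N mu_lof gamma) for the LoF class and the
    neutral rate for the other classes (only LoF de novo risk is enriched;
    synonymous variants are unenriched in both groups).
    """
    rng = rng or np.random.default_rng(cfg.seed + 2)
    case_ids = [f"T{i:05d}_C" for i in range(cfg.n_trios)]
    control_ids = [f"U{i:05d}_C" for i in range(cfg.n_control_trios)]
    gamma_by_gene = dict(zip(truth["gene_id"], truth["gamma"]))

    def _records(offspring: list[str], enriched: bool) -> pd.DataFrame:
        n = len(offspring)
        rows = []
        if n == 0:
            return pd.DataFrame(columns=["individual_id", "gene_id", "variant_class", "position"])
        for gene in panel:
            for klass in ("lof", "dmis", "other_mis", "syn"):
                lam = 2.0 * n * gene.mu(klass)
                if enriched and klass == "lof":
                    lam *= gamma_by_gene.get(gene.gene_id, 1.0)
                k = rng.poisson(lam)
                for _ in range(k):
                    rows.append(
                        (
                            offspring[rng.integers(n)],
                            gene.gene_id,
                            klass,
                            int(rng.integers(1, 100_000)),
                        )
                    )
        return pd.DataFrame(
            rows, columns=["individual_id", "gene_id", "variant_class", "position"]
        )

    return _records(case_ids, enriched=True), _records(control_ids, enriched=False)


def simulate_population_controls(
    panel: Sequence[GeneModel],
    truth: pd.DataFrame,
    n_controls: int,
    rng: Optional[np.random.Generator] = None,
    source: str = "panel",
) -> pd.DataFrame:
    """Population-reference carrier counts: Binomial(n, 2 f) per gene.

    Synonymous carrier counts (neutral, shared rate with cases) are included
    for calibration. callable_fraction defaults to 1.
    """
    rng = rng or np.random.default_rng(0)
    syn_caf = np.array([SYN_CAF_SCALE * g.mu_syn for g in panel])
    f = truth.set_index("gene_id").loc[[g.gene_id for g in panel], "f"].to_numpy()
    carriers = rng.binomial(n_controls, np.minimum(2.0 * f, 1.0))
    syn_carriers = rng.binomial(n_controls, np.minimum(2.0 * syn_caf, 1.0))
    return pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in panel],
            "carriers": carriers,
            "syn_carriers": syn_carriers,
            "sample_size": float(n_controls),
            "callable_fraction": 1.0,
            "source": source,
        }
    )


def simulate_singleton_cases(
    panel: Sequence[GeneModel],
    truth: pd.DataFrame,
    n_cases: int,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Unrelated-case carrier counts enriched by the relative risk.

    Carrier probability per gene is the conditional
    q gamma / (q gamma + 1 - q) with q = 2 (f + mu_lof), folding inherited
    alleles and de novo events of unknown inheritance together. Synonymous
    counts are unenriched.
    """
    rng = rng or np.random.default_rng(0)
    t = truth.set_index("gene_id").loc[[g.gene_id for g in panel]]
    q = 2.0 * (t["f"].to_numpy() + t["mu_lof"].to_numpy())
    gamma = t["gamma"].to_numpy()
    p_case = q * gamma / (q * gamma + 1.0 - q)
    syn_caf = np.array([SYN_CAF_SCALE * g.mu_syn for g in panel])
    return pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in panel],
            "carriers": rng.binomial(n_cases, np.minimum(p_case, 1.0)),
            "syn_carriers": rng.binomial(n_cases, np.minimum(2.0 * syn_caf, 1.0)),
            "sample_size": float(n_cases),
            "callable_fraction": 1.0,
            "source": "singleton_cases",
        }
    )


def simulate_phenotypes(
    pedigrees: Sequence[Pedigree],
    variants: pd.DataFrame,
    truth: pd.DataFrame,
    cfg: SimConfig,
    rng: Optional[np.random.Generator] = None,
) -> None:
    """Assign carrier-dependent cognitive-impairment flags to affected offspring.

    Carriers of a risk-gene LoF get probability ``impairment_carrier_rate``,
    everyone else ``impairment_base_rate``. Flags are written in place.
    """
    rng = rng or np.random.default_rng(cfg.seed + 3)
    risk_genes = set(truth.loc[truth["is_risk"], "gene_id"])
    carriers = set()
    if len(variants):
        m = variants["gene_id"].isin(risk_genes) & (variants["variant_class"] == "lof")
        carriers = set(variants.loc[m, "individual_id"])
    for ped in pedigrees:
        for ind in ped.members.values():
            if not ind.affected:
                continue
            p = cfg.impairment_carrier_rate if ind.id in carriers else cfg.impairment_base_rate
            ind.cognitive_impairment = bool(rng.random() < p)


def pin_risk_gene(
    genes: Sequence[GeneModel],
    truth: pd.DataFrame,
    index: int = 0,
    gamma: float = 8.0,
    s: float = 0.2,
    mu_lof: float = 2e-6,
) -> None:
    """Pin one panel gene to exact (gamma, s, mu) truth values, in place.

    The gene is placed in the most constrained stratum (top LOEUF decile,
    pLI 0.99, high A-risk) so that it is eligible for stage-1 TDT
    prioritization. Used for recovery benchmarks with a known risk gene.
    """
    g = genes[index]
    g.mu_lof = mu_lof
    g.mu_dmis = mu_lof
    g.mu_mis = 5.0 * mu_lof
    g.mu_syn = 3.0 * mu_lof
    g.loeuf_decile, g.pli, g.a_risk = 1, 0.99, 0.8
    truth.loc[index, "is_risk"] = True
    truth.loc[index, "gamma"] = gamma
    truth.loc[index, "s"] = s
    truth.loc[index, "mu_lof"] = mu_lof
    truth.loc[index, "f"] = mu_lof / s
    truth.loc[index, "expected_t_nt_ratio"] = gamma


@dataclass
class SimulatedCohort:
    config: SimConfig
    genes: list[GeneModel]
    truth: pd.DataFrame
    pedigrees: list[Pedigree]
    variants: pd.DataFrame
    dnv_case: pd.DataFrame
    dnv_control: pd.DataFrame
    case_counts: pd.DataFrame
    control_panels: list[pd.DataFrame]


def simulate_cohort(
    cfg: SimConfig,
    panel: Optional[Sequence[GeneModel]] = None,
    truth: Optional[pd.DataFrame] = None,
) -> SimulatedCohort:
    """Generate the complete synthetic study (families, DNVs, references).

    A pre-built (panel, truth) pair — e.g. with specific genes pinned to
    chosen (mu, s, gamma) — can be supplied; otherwise the panel is drawn
    from the configured distributions.
    """
    if (panel is None) != (truth is None):
        raise ValueError("supply panel and truth together")
    if panel is None:
        genes, truth = simulate_gene_panel(cfg)
    else:
        genes = list(panel)
    rng = np.random.default_rng(cfg.seed + 1)
    peds, variants = simulate_parents_and_transmission(genes, truth, cfg, rng)
    dnv_case, dnv_control = simulate_dnvs(genes, truth, cfg, np.random.default_rng(cfg.seed + 2))
    case_counts = simulate_singleton_cases(
        genes, truth, cfg.n_singleton_cases, np.random.default_rng(cfg.seed + 4)
    )
    panels = [
        simulate_population_controls(
            genes, truth, size, np.random.default_rng(cfg.seed + 10 + i), source=f"panel{i + 1}"
        )
        for i, size in enumerate(cfg.control_panel_sizes)
    ]
    simulate_phenotypes(peds, variants, truth, cfg, np.random.default_rng(cfg.seed + 3))
    return SimulatedCohort(cfg, genes, truth, peds, variants, dnv_case, dnv_control, case_counts, panels)


def write_cohort(cohort: SimulatedCohort, outdir) -> None:
    """Write the cohort as plain-text tables (PED + TSVs) with the seed recorded."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_ped(cohort.pedigrees, outdir / "cohort.ped")
    genes_to_frame(cohort.genes).to_csv(outdir / "genes.tsv", sep="\t", index=False)
    truth = cohort.truth.copy()
    truth["seed"] = cohort.config.seed
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    cohort.variants.to_csv(outdir / "variants.tsv", sep="\t", index=False)
    cohort.dnv_case.to_csv(outdir / "dnv_case.tsv", sep="\t", index=False)
    cohort.dnv_control.to_csv(outdir / "dnv_control.tsv", sep="\t", index=False)
    cohort.case_counts.to_csv(outdir / "case_counts.tsv", sep="\t", index=False)
    for i, panel in enumerate(cohort.control_panels):
        panel.to_csv(outdir / f"control_panel{i + 1}.tsv", sep="\t", index=False)
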