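"""Two-stage discovery workflow orchestration.

Stage 1 screens every gene with the severity-weighted de novo enrichment
test and the per-gene TDT, and selects candidates (enrichment P below the
stage-1 threshold, or TDT z > 1 in a constrained/prioritized stratum).
Stage 2 combines, per candidate, the de novo enrichment P, the TDT binomial
P and the conservative (max over two references) case-control P with
Fisher's method, and flags exome-wide (2.5e-6) and study-wide (0.05/5,754)
significance. All stages are deterministic given the config; output tables
are sorted by (meta P, gene id) for reproducible diffs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from rarefam import denovo, tdt as tdt_mod
from rarefam.case_control import AlleleCountSet, dual_control_max_p, poisson_two_rate_test
from rarefam.denovo import NONSYN_CLASSES, preprocess_dnvs, weighted_enrichment_test
from rarefam.meta import EXOME_WIDE_ALPHA, N_CONSTRAINED_GENES, bonferroni_threshold, fisher_combine
from rarefam.mutation import GeneModel, expected_dnv_count, read_gene_table
from rarefam.pedigree import Pedigree, read_ped
from rarefam.simulate import SimConfig, SimulatedCohort, simulate_cohort
from rarefam.tdt import count_trios_duos, prioritize_tdt_genes, tally_transmissions

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    max_af: float = 1e-5
    pext_baseline: float = 0.1
    stage1_dnv_p: float = 1e-3
    exome_wide_alpha: float = EXOME_WIDE_ALPHA
    n_constrained_genes: int = N_CONSTRAINED_GENES
    enrichment_method: str = "exact"
    enrichment_n_sim: int = 20_000
    seed: int = 0
    output_dir: Optional[str] = None

    @property
    def study_wide_alpha(self) -> float:
        return bonferroni_threshold(self.n_constrained_genes)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class Stage1Result:
    table: pd.DataFrame
    weights: denovo.WeightTable
    transmissions: pd.DataFrame
    n_trios: int
    n_duos: int
    config_hash: str

    @property
    def candidates(self) -> list[str]:
        return list(self.table.loc[self.table["selected"], "gene_id"])


def derive_cohort_weights(
    dnv_records: pd.DataFrame, genes: Sequence[GeneModel], n_trios: int
) -> denovo.WeightTable:
    """PPV weights per (constrained, class) stratum from the cohort burden."""
    by_gene = {g.gene_id: g for g in genes}
    observed: dict[tuple[bool, str], float] = {}
    expected: dict[tuple[bool, str], float] = {}
    for constrained in (False, True):
        for klass in NONSYN_CLASSES:
            expected[(constrained, klass)] = max(
                1e-12,
                sum(
                    expected_dnv_count(
                        n_trios, g.mu(klass), g.callable_fraction_case, g.chrom_class
                    )
                    for g in genes
                    if g.constrained == constrained
                ),
            )
            observed[(constrained, klass)] = 0.0
    for row in dnv_records.itertuples(index=False):
        g = by_gene.get(row.gene_id)
        if g is None or row.variant_class not in NONSYN_CLASSES:
            continue
        observed[(g.constrained, row.variant_class)] += 1.0
    return denovo.derive_ppv_weights(observed, expected)


def run_stage1(cohort: SimulatedCohort, cfg: RunConfig) -> Stage1Result:
    """Exome-wide de novo and TDT screen; emits the candidate gene list."""
    dnv = preprocess_dnvs(cohort.dnv_case)
    logger.info("stage1: %d case DNVs after preprocessing (%d in)", len(dnv), len(cohort.dnv_case))
    n_trios_dnv = cohort.config.n_trios
    weights = derive_cohort_weights(dnv, cohort.genes, n_trios_dnv)

    n_var = len(cohort.variants)
    trans = tally_transmissions(
        cohort.variants, cohort.pedigrees, max_af=cfg.max_af, pext_baseline=cfg.pext_baseline
    )
    n_trios, n_duos = count_trios_duos(cohort.pedigrees, affected=True)
    logger.info(
        "stage1: %d variant observations -> %d transmission records (%d trios, %d duos)",
        n_var,
        len(trans),
        n_trios,
        n_duos,
    )
    aff = trans[trans["offspring_affected"]] if len(trans) else trans
    counts_by_gene = (
        aff.groupby("gene_id")["transmitted"].agg(["sum", "count"])
        if len(aff)
        else pd.DataFrame(columns=["sum", "count"])
    )
    dnv_count_map: dict[str, dict[str, int]] = {}
    if len(dnv):
        for (gid, klass), n in dnv.groupby(["gene_id", "variant_class"]).size().items():
            dnv_count_map.setdefault(gid, {})[klass] = int(n)

    rows = []
    for gene in cohort.genes:
        counts = dnv_count_map.get(gene.gene_id, {})
        enr = weighted_enrichment_test(
            gene,
            counts,
            weights,
            n_trios_dnv,
            n_sim=cfg.enrichment_n_sim,
            seed=cfg.seed,
            method=cfg.enrichment_method,
        )
        if gene.gene_id in counts_by_gene.index:
            t = int(counts_by_gene.loc[gene.gene_id, "sum"])
            n = int(counts_by_gene.loc[gene.gene_id, "count"])
        else:
            t, n = 0, 0
        c = tdt_mod.TdtCounts(T=t, NT=n - t, n_trios=n_trios, n_duos=n_duos)
        rows.append(
            {
                "gene_id": gene.gene_id,
                "constrained": gene.constrained,
                "loeuf_decile": gene.loeuf_decile,
                "a_risk": gene.a_risk,
                "dnv_lof": counts.get("lof", 0),
                "dnv_dmis": counts.get("dmis", 0),
                "dnv_score": enr.observed_score,
                "p_enrich": enr.p_value,
                "T": c.T,
                "NT": c.NT,
                "z": tdt_mod.tdt_z(c),
                "p_tdt": tdt_mod.tdt_binomial(c),
            }
        )
    table = pd.DataFrame(rows)
    prioritized = prioritize_tdt_genes(
        table[["gene_id", "z"]],
        pd.DataFrame(
            {
                "gene_id": table["gene_id"],
                "loeuf_decile": table["loeuf_decile"],
                "a_risk": table["a_risk"],
            }
        ),
    )
    denovo_hit = table["p_enrich"] < cfg.stage1_dnv_p
    table["selected"] = denovo_hit | prioritized
    table["reason"] = np.select(
        [denovo_hit & prioritized, denovo_hit, prioritized],
        ["de novo+TDT", "de novo", "TDT"],
        default="",
    )
    logger.info(
        "stage1: selected %d candidates (%d de novo, %d TDT)",
        int(table["selected"].sum()),
        int(denovo_hit.sum()),
        int(prioritized.sum()),
    )
    return Stage1Result(table, weights, trans, n_trios, n_duos, cfg.config_hash())


def run_stage2(
    cohort: SimulatedCohort,
    stage1: Stage1Result,
    cfg: RunConfig,
    candidates: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Fisher meta-analysis of candidates against the population references.

    A candidate lacking case-control data keeps P_CC = 1 (conservative) with
    ``cc_missing`` flagged. The output is one row per candidate with all
    stage P values, the meta P and significance flags, sorted by
    (p_meta, gene_id).
    """
    if candidates is None:
        candidates = stage1.candidates
    s1 = stage1.table.set_index("gene_id")
    case_counts = cohort.case_counts.set_index("gene_id") if len(cohort.case_counts) else None
    panels = [p.set_index("gene_id") for p in cohort.control_panels]
    n_cases = (
        float(case_counts["sample_size"].iloc[0]) if case_counts is not None and len(case_counts) else 0.0
    )
    rows = []
    for gid in candidates:
        if gid not in s1.index:
            raise KeyError(f"candidate {gid!r} missing from stage-1 table")
        p_dnv = float(s1.loc[gid, "p_enrich"])
        p_tdt = float(s1.loc[gid, "p_tdt"])
        cc_missing = case_counts is None or gid not in case_counts.index or not panels
        p_cc_pair = []
        if not cc_missing:
            case = AlleleCountSet(
                gid,
                carriers=float(case_counts.loc[gid, "carriers"]),
                sample_size=n_cases,
                callable_fraction=float(case_counts.loc[gid, "callable_fraction"]),
                source="cases",
            )
            for panel in panels:
                if gid not in panel.index:
                    cc_missing = True
                    break
                ctrl = AlleleCountSet(
                    gid,
                    carriers=float(panel.loc[gid, "carriers"]),
                    sample_size=float(panel.loc[gid, "sample_size"]),
                    callable_fraction=float(panel.loc[gid, "callable_fraction"]),
                    source=str(panel.loc[gid, "source"]),
                )
                p_cc_pair.append(poisson_two_rate_test(case, ctrl).p_one_sided)
        if cc_missing:
            p_cc = 1.0
            p_cc_pair = [1.0, 1.0]
        else:
            p_cc = dual_control_max_p(*p_cc_pair[:2]) if len(p_cc_pair) >= 2 else p_cc_pair[0]
        p_meta = fisher_combine([p_dnv, p_tdt, p_cc])
        rows.append(
            {
                "gene_id": gid,
                "p_dnv": p_dnv,
                "p_tdt": p_tdt,
                "p_cc_ref1": p_cc_pair[0],
                "p_cc_ref2": p_cc_pair[1] if len(p_cc_pair) > 1 else np.nan,
                "p_cc": p_cc,
                "cc_missing": cc_missing,
                "p_meta": p_meta,
                "exome_wide_significant": p_meta < cfg.exome_wide_alpha,
                "study_wide_significant": p_meta < cfg.study_wide_alpha,
            }
        )
    columns = [
        "gene_id",
        "p_dnv",
        "p_tdt",
        "p_cc_ref1",
        "p_cc_ref2",
        "p_cc",
        "cc_missing",
        "p_meta",
        "exome_wide_significant",
        "study_wide_significant",
    ]
    out = pd.DataFrame(rows, columns=columns)
    if len(out):
        out = out.sort_values(["p_meta", "gene_id"]).reset_index(drop=True)
    out.attrs["config_hash"] = cfg.config_hash()
    out.attrs["seed"] = cfg.seed
    return out


@dataclass
class SimulationStudyReport:
    meta_table: pd.DataFrame
    joined: pd.DataFrame
    sensitivity_study_wide: float
    n_risk: int
    n_null: int
    null_false_positives: int
    specificity: float
    gamma_hat_pooled: float


def run_simulation_study(sim_cfg: SimConfig, run_cfg: RunConfig) -> SimulationStudyReport:
    """Simulate a cohort, run both stages on every gene, and score vs truth.

    The meta-analysis is evaluated for all genes (not only stage-1
    candidates) so gene-level type-I error and sensitivity are both
    measurable; the stage-1 ``selected`` flag is carried through.
    """
    cohort = simulate_cohort(sim_cfg)
    s1 = run_stage1(cohort, run_cfg)
    meta = run_stage2(cohort, s1, run_cfg, candidates=list(s1.table["gene_id"]))
    joined = meta.merge(cohort.truth, on="gene_id", how="left").merge(
        s1.table[["gene_id", "selected", "reason", "z", "T", "NT"]], on="gene_id", how="left"
    )
    assert len(joined) == len(cohort.truth), "truth join must not lose genes"
    risk = joined[joined["is_risk"]]
    null = joined[~joined["is_risk"]]
    # detection requires surviving stage-1 selection AND study-wide meta significance
    detected = risk["selected"] & risk["study_wide_significant"]
    fp = int((null["selected"] & null["study_wide_significant"]).sum())
    t_sum, nt_sum = int(risk["T"].sum()), int(risk["NT"].sum())
    gamma_hat = t_sum / nt_sum if nt_sum > 0 else np.nan
    return SimulationStudyReport(
        meta_table=meta,
        joined=joined,
        sensitivity_study_wide=float(detected.mean()) if len(risk) else np.nan,
        n_risk=int(len(risk)),
        n_null=int(len(null)),
        null_false_positives=fp,
        specificity=1.0 - fp / len(null) if len(null) else np.nan,
        gamma_hat_pooled=gamma_hat,
    )


# ---------------------------------------------------------------------------
# File-based cohort loading (CLI support)
# ---------------------------------------------------------------------------

def load_cohort(indir, config: Optional[SimConfig] = None) -> SimulatedCohort:
    """Load a cohort from the plain-text layout written by ``write_cohort``."""
    indir = Path(indir)
    genes = read_gene_table(indir / "genes.tsv")
    truth_path = indir / "truth.tsv"
    truth = (
        pd.read_csv(truth_path, sep="\t")
        if truth_path.exists()
        else pd.DataFrame(columns=["gene_id", "is_risk", "gamma", "s", "mu_lof", "f"])
    )
    peds = read_ped(indir / "cohort.ped")
    n_trios, n_duos = count_trios_duos(peds, affected=True)

    def _read(name: str, required: bool = True) -> pd.DataFrame:
        path = indir / name
        if not path.exists():
            if required:
                raise FileNotFoundError(path)
            return pd.DataFrame()
        return pd.read_csv(path, sep="\t")

    panels = []
    for i in (1, 2, 3, 4):
        path = indir / f"control_panel{i}.tsv"
        if path.exists():
            panels.append(pd.read_csv(path, sep="\t"))
    cfg = config or SimConfig(n_trios=n_trios, n_duos=n_duos, n_genes=len(genes))
    return SimulatedCohort(
        config=cfg,
        genes=genes,
        truth=truth,
        pedigrees=peds,
        variants=_read("variants.tsv"),
        dnv_case=_read("dnv_case.tsv"),
        dnv_control=_read("dnv_control.tsv", required=False),
        case_counts=_read("case_counts.tsv", required=False),
        control_panels=panels,
    )
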