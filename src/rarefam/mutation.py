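"""Gene-level mutation-rate bookkeeping and expected de novo counts.

Per-gene haploid mutation rates by variant class are consumed as an input
table (the sequence-context rate model that produces them is upstream of
this package). Helpers implement the standard adjustments: frameshift rate
as 1.3x the stop-gained SNV rate, callable-fraction exposure scaling, and a
parental-origin split of X-chromosome rates in which spermatogenesis mutates
``sperm_oo_ratio`` times faster than oogenesis while the sex-averaged rate
is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

AUTOSOMAL = "autosomal"
X_NONPAR = "x_nonpar"

FRAMESHIFT_TO_STOP_RATIO = 1.3

VARIANT_CLASSES = ("lof", "dmis", "other_mis", "syn")


@dataclass
class GeneModel:
    """Per-gene rates, constraint and exposure — the unit of association testing."""

    gene_id: str
    chrom_class: str = AUTOSOMAL
    mu_lof: float = 0.0
    mu_dmis: float = 0.0
    mu_mis: float = 0.0
    mu_syn: float = 0.0
    pli: float = 0.0
    loeuf_decile: int = 10
    shet: Optional[float] = None
    a_risk: Optional[float] = None
    callable_fraction_case: float = 1.0
    callable_fraction_control: float = 1.0
    pext_threshold: Optional[float] = None
    known_asd_ndd: bool = False

    def __post_init__(self) -> None:
        for name in ("mu_lof", "mu_dmis", "mu_mis", "mu_syn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0 for gene {self.gene_id}")
        for name in ("callable_fraction_case", "callable_fraction_control"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1] for gene {self.gene_id}")
        if self.chrom_class not in (AUTOSOMAL, X_NONPAR):
            raise ValueError(f"unknown chrom_class {self.chrom_class!r}")

    @property
    def constrained(self) -> bool:
        """ExAC pLI >= 0.5 or top 20% of LOEUF — the meta-analysis universe."""
        return self.pli >= 0.5 or self.loeuf_decile <= 2

    def mu(self, variant_class: str) -> float:
        return {
            "lof": self.mu_lof,
            "dmis": self.mu_dmis,
            "other_mis": self.mu_mis,
            "syn": self.mu_syn,
        }[variant_class]


@dataclass
class SexRateModel:
    """Male:female case ratio and the spermatogenesis:oogenesis rate ratio."""

    male_female_case_ratio: float = 4.2
    sperm_oo_ratio: float = 3.4

    def __post_init__(self) -> None:
        if self.male_female_case_ratio <= 0 or self.sperm_oo_ratio <= 0:
            raise ValueError("sex-model ratios must be positive")

    def offspring_sex_mix(self) -> tuple[float, float]:
        """(male fraction, female fraction) implied by the case sex ratio."""
        r = self.male_female_case_ratio
        return r / (1.0 + r), 1.0 / (1.0 + r)

    def parental_origin_rates(self, mu: float) -> tuple[float, float]:
        """(paternal, maternal) haploid rates preserving the sex-averaged mu."""
        r = self.sperm_oo_ratio
        return 2.0 * r * mu / (1.0 + r), 2.0 * mu / (1.0 + r)


def frameshift_rate(mu_stop_gained: float) -> float:
    """Frameshift mutation rate presumed 1.3x the stop-gained SNV rate."""
    if mu_stop_gained < 0:
        raise ValueError("mutation rate must be >= 0")
    return FRAMESHIFT_TO_STOP_RATIO * mu_stop_gained


def expected_dnv_count(
    n_trios: float,
    mu: float,
    callable_fraction: float = 1.0,
    chrom_class: str = AUTOSOMAL,
    sex_model: Optional[SexRateModel] = None,
    offspring_sex_mix: Optional[Sequence[float]] = None,
) -> float:
    """Expected de novo count in ``n_trios`` offspring for a class with rate mu.

    Autosomes: ``2 * n_trios * mu * callable_fraction`` (two haplotypes at
    risk). X non-PAR: a male offspring carries one maternal X, a female one
    maternal and one paternal X; the haploid rate is split by parental origin
    (spermatogenesis ``sperm_oo_ratio`` times oogenesis, sex-average
    preserved) and weighted by the offspring sex mix. With a 100% female mix
    and sperm_oo_ratio = 1 this reduces to the autosomal formula.
    """
    if n_trios < 0:
        raise ValueError("n_trios must be >= 0")
    if mu < 0:
        raise ValueError("mu must be >= 0")
    if chrom_class == AUTOSOMAL:
        return 2.0 * n_trios * mu * callable_fraction
    if chrom_class != X_NONPAR:
        raise ValueError(f"unknown chrom_class {chrom_class!r}")
    sex_model = sex_model or SexRateModel()
    if offspring_sex_mix is None:
        offspring_sex_mix = sex_model.offspring_sex_mix()
    male_frac, female_frac = offspring_sex_mix
    if abs(male_frac + female_frac - 1.0) > 1e-9:
        raise ValueError("offspring sex mix must sum to 1")
    mu_pat, mu_mat = sex_model.parental_origin_rates(mu)
    per_trio = male_frac * mu_mat + female_frac * (mu_mat + mu_pat)
    return n_trios * per_trio * callable_fraction


# ---------------------------------------------------------------------------
# Gene table IO (TSV, deterministic column order)
# ---------------------------------------------------------------------------

GENE_TABLE_COLUMNS = [
    "gene_id",
    "chrom_class",
    "mu_lof",
    "mu_dmis",
    "mu_mis",
    "mu_syn",
    "pli",
    "loeuf_decile",
    "shet",
    "a_risk",
    "callable_fraction_case",
    "callable_fraction_control",
    "pext_threshold",
    "known_asd_ndd",
]


def genes_to_frame(genes: Sequence[GeneModel]) -> pd.DataFrame:
    rows = [{c: getattr(g, c) for c in GENE_TABLE_COLUMNS} for g in genes]
    return pd.DataFrame(rows, columns=GENE_TABLE_COLUMNS)


def frame_to_genes(df: pd.DataFrame) -> list[GeneModel]:
    genes = []
    for row in df.itertuples(index=False):
        kwargs = {c: getattr(row, c) for c in GENE_TABLE_COLUMNS if hasattr(row, c)}
        for opt in ("shet", "a_risk", "pext_threshold"):
            if opt in kwargs and pd.isna(kwargs[opt]):
                kwargs[opt] = None
        kwargs["known_asd_ndd"] = bool(kwargs.get("known_asd_ndd", False))
        kwargs["loeuf_decile"] = int(kwargs["loeuf_decile"])
        genes.append(GeneModel(**kwargs))
    return genes


def write_gene_table(genes: Sequence[GeneModel], path) -> None:
    genes_to_frame(genes).to_csv(path, sep="\t", index=False)


def read_gene_table(path) -> list[GeneModel]:
    return frame_to_genes(pd.read_csv(path, sep="\t"))
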