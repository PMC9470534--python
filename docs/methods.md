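# Methods

This note documents the statistical models implemented in `rarefam`, the
assumptions behind them, the defaults and why, what the synthetic-data
generator does and does not emulate, and the numerical choices that a
maintainer would otherwise have to reverse-engineer.

## Pedigree model and kinship

Families are explicit directed acyclic graphs of `Individual` records
(PED-style, with optional columns for parent-exclusion flags, twin groups,
cognitive impairment and sequencing status). Kinship uses the standard
recursion over founders, who are assumed non-inbred and mutually unrelated:
φ(x,x) = ½(1 + φ(father, mother)) and, recursing on the deeper individual,
φ(a,b) = ½(φ(father_a, b) + φ(mother_a, b)). Inbred pedigrees are handled
by the recursion itself; the only concession is that contributing sample
sizes (below) are floored at 0, because they are interpreted as sample
sizes. Cryptic relatedness is an *input*: genotype-based kinship estimates
enter as an (id1, id2, kinship) table and, at or above the default
threshold 0.1 (roughly second-degree), add edges to the relatedness graph
alongside declared first/second-degree pairs (pedigree φ ≥ 1/8). Unrelated
subsets take one individual per connected component, preferring affected
individuals (to maximize case yield) and then the lexicographically
smallest id, so selection is deterministic. In X-chromosome mode father-son
pairs contribute no edge (no X sharing). Monozygotic twins are declared in
pedigree metadata and only one twin is used anywhere.

## Pseudocontrols and pseudocases

Pseudocontrols are untransmitted alleles of unaffected, non-excluded,
sequenced parents of affected offspring; each eligible parent contributes
0.5 to the effective sample size whether or not it carries anything. A
case's contributing sample size is 1 − Σφ(case, ancestor) over its *most
recent* sequenced unaffected non-excluded ancestors (the ascent stops at
the first eligible ancestor per lineage): 0.5 for a full trio child, 0.75
for a duo child, 1.0 for a case with no sequenced unaffected ancestors.
The duo weight follows the formula as stated (1 − 0.25), not the
half-haplotype intuition (0.5). Pseudocase alleles exclude anything seen
in those ancestors and anything in the de novo set, so the three evidence
arms stay independent.

## Mutation model

Per-gene class-specific haploid mutation rates are consumed as data; the
sequence-context model that produces them is upstream of this package.
Helpers implement the standard adjustments: frameshift rate = 1.3 × the
stop-gained SNV rate; expected de novo count 2Nμc on autosomes with c the
callable-trio fraction. On the X (non-PAR) the haploid rate is split by
parental origin with spermatogenesis : oogenesis = 3.4 : 1, normalized so
the sex-averaged rate is preserved (μ_pat = 2rμ/(1+r), μ_mat = 2μ/(1+r)),
and male offspring expose one maternal X while females expose both
parental X's; the offspring sex mix defaults to the 4.2 : 1 male : female
case ratio. The normalization convention is a package choice — the
preserved sex-average is the anchor — and is pinned by the invariant that
a 100%-female mix at ratio 1 reproduces the autosomal formula.

## De novo enrichment

After preprocessing (within 100 bp in the same gene and individual, only
the most severe variant is kept, severity LoF > damaging missense > other
missense > synonymous; twin-shared variants counted once; both rules
idempotent), the gene-level test scores counts with
positive-predictive-value weights derived per (constrained × class)
stratum: w = max(0, (O − E)/O), the estimated excess fraction of observed
events. The observed score S = Σ_class w·count is compared with its null,
where each class count is Poisson with mean equal to the expected de novo
count. Two evaluation paths compute the same tail: a seeded Monte Carlo
(P = (1 + #{sim ≥ obs})/(1 + n_sim); the +1 smoothing avoids P = 0 and is
conservative) and an exact enumeration of the compound-Poisson score
distribution (class counts truncated where the residual Poisson mass drops
below 1e-13, scores consolidated on a 1e-9 grid, tail taken with a 1e-9
score tolerance). The pipeline uses the exact path because meta-analysis
needs P values far below any realistic Monte Carlo floor; the simulation
path is retained and cross-checked in tests. Missense spatial clustering
is out of scope, so a gene's de novo P is its enrichment P.

The gene-set test places each observed mutation onto the constrained-gene
universe with probability proportional to the gene's class-specific μ,
holding per-class counts (and the case/control split) fixed — sequence
context is collapsed into the per-gene class rates rather than preserved
per trinucleotide. The statistic is the weighted in-set fraction (ratio of
case over control fractions when controls are supplied); the fold
enrichment CI assumes log FE ~ normal with σ = |log FE|/Φ⁻¹(1 − P).

## Transmission disequilibrium

Records are one per eligible heterozygous parental allele × offspring.
Eligibility: parent unaffected, sequenced, and not flagged as having an
ASD diagnosis or intellectual disability; allele frequency ≤ 1e-5
(ultra-rare) with optional high-confidence and pExt filters (baseline 0.1,
gene-specific thresholds override). On the X non-PAR only maternal
transmissions count. The per-gene test pools trios and duos into a single
exact binomial P(X ≥ T | T+NT, 0.5); z = (T − NT)/√(T + NT); per-trio
overtransmission divides T − NT by trios + duos/2. Gene-set enrichment and
phenotype-group contrasts use 2×2 Pearson χ² without continuity correction
— the intended regime is hundreds of events, where the correction only
biases conservative. Stage-1 prioritization: z > 1 and (top LOEUF decile,
or second decile with A-risk ≥ 0.4).

## Case-control burden

Carrier rates are per effective sample (sample size × per-gene callable
fraction; fractional sizes from pseudo-samples are allowed). The two-rate
"Poisson test" is implemented as the exact conditional binomial on the
combined carrier count, which is the canonical exact comparison of two
Poisson rates with unequal exposures; it is conservative (type-I ≤
nominal) because of discreteness. Against two population references the
larger P is carried into the meta-analysis, making hits robust to the
choice of reference. Synonymous variants calibrate the machinery: per-gene
one-sided P values should be uniform under the null, summarized by Q-Q
points and λ = median(χ²₁ quantile of 1 − P)/0.4549. λ is only
interpretable when per-gene counts are large enough that discreteness does
not dominate (tests use ~20 expected events per gene).

## Meta-analysis, effect sizes, power

Per-gene P values from the three independent arms combine by Fisher's
method (χ², 6 d.f.). Thresholds: exome-wide 2.5e-6 (0.05/20,000) and
study-wide 0.05/5,754 = 8.7e-6 (the constrained-gene universe, pLI ≥ 0.5
or top 20% LOEUF). A candidate lacking case-control data keeps P_CC = 1
with a flag rather than being dropped.

Selection and effect size come from mutation-selection balance: f = μ/s at
equilibrium, ŝ = μ/f̂ capped at 1, γ̂ = case:control carrier-rate ratio
(exact for rare variants to first order), PAR contribution = excess case
carrier rate floored at 0. The noncentrality parameter defaults to the
form λ = 4N[γf ln γ + (1 − γf)ln((1 − γf)/(1 − f))] because its small-f
limit 4Nf[γ ln γ − (γ − 1)] is exactly the denominator of the sample-size
approximation; a variant with (1 − γ) in place of (1 − γf) is selectable
as `form="as_printed"` for comparison. Power is the noncentral χ²₁
survival at the central quantile of 1 − α (α defaults to 9e-6); exact
sample sizes invert that by integer bisection (the approximation is kept
for comparison and agrees within 5% for f ≤ 1e-4). The feasible region is
s ≥ 0.013γ with 0.013 = prevalence (1/54) × sex-averaged fitness reduction
(0.71), both overridable; grids mask infeasible combinations with NaN.

## Synthetic cohorts: what is and is not emulated

The generator works at the carrier level. Per gene it draws μ (log-uniform
1e-7..1e-5 by default), s (log-uniform 0.01..0.5), and γ for risk genes
(log-uniform 2..10 by default; 2% of genes), resampling risk-gene s into
[0.013γ, s_max] when the fitness constraint is on. Companion class rates
are tied to μ_LoF (damaging missense = 1×, other missense = 5×, synonymous
= 3×), a deliberate simplification. Cohort arms default to the scale of
the real study: 5,000 trios, 2,000 duos, 5,764 unaffected comparison
trios, 15,780 singleton cases, and two reference panels of 104,068 and
132,345.

Parents carry a gene's LoF with probability 2f; heterozygous parents
transmit to affected children with probability γ/(1 + γ) and to unaffected
children with the exact conditional (1 − γπ)/((1 − γπ) + (1 − π)), which
produces the undertransmission signal in unaffected offspring. De novo
counts are Poisson(2Nμ) in control offspring and Poisson(2Nμγ) for the LoF
class in cases — the de novo enrichment is tied to the *same* γ as
inherited risk so each gene has one truth parameter; real cohorts show de
novo rate ratios far above the inherited relative risk, so the generator
understates de novo evidence relative to the study it emulates (see
Limitations). Damaging-missense de novo counts are left unenriched.
Population controls draw Binomial(n, 2f) carriers; singleton cases use the
conditional carrier probability qγ/(qγ + 1 − q) with q = 2(f + μ), folding
inherited and de-novo-of-unknown-inheritance alleles together. Synonymous
carrier frequencies use a flat neutral proxy (CAF = 500 × μ_syn, identical
in cases and controls); synonymous alleles are not under selection, so the
equilibrium formula does not apply, and the proxy only needs to give the
calibration surface realistic counts. Cognitive impairment is Bernoulli:
0.88 for risk-gene LoF carriers, 0.50 otherwise.

Not emulated: sequence context and per-site rates, linkage and phasing,
ancestry structure and stratification, genotyping error, recurrent
mutation, and any allele-frequency spectrum beyond the equilibrium point
mass. Passing recovery tests therefore show the statistical machinery is
correct under the stated sampling model, not that the pipeline is robust
to the technical artifacts of real call sets.

## Benchmark problem sizes

Validation workloads were sized to be informative rather than exhaustive:
kinship is checked against a 10⁶-drop gene-dropping oracle on sibling
configurations and 10⁵ drops on randomized three-generation pedigrees
(5σ tolerance); the TDT null calibration uses 10⁴ genes at ~100
informative events each (analytic mixture rejection 0.040 at α = 0.05);
γ recovery pools ~16,000 transmission events from a 20-gene γ = 4 panel;
ŝ recovery uses 50 genes at ~100 expected carriers in 10⁵ controls; the
end-to-end benchmark runs 20 replicate 1,000-gene, 5,000-trio cohorts.

## Known limitations

* The two-stage benchmark with the weakest pinned gene (γ = 8, s = 0.2,
  μ = 2e-6, so f = 1e-5) is below the detection floor of a 5,000-trio
  cohort under this generative model: ~0.24 expected heterozygous parents
  give the TDT arm nothing, the de novo arm expects 0.16 case events, and
  the case-control arm alone carries a noncentrality of ~6-7 where ~33 is
  needed at the study-wide threshold. The corresponding recovery test
  documents this honestly rather than passing; a gene one order of
  magnitude more frequent (f = 1e-4) is recovered at meta P ~ 1e-12.
* Inferred (cryptic) kinship is consumed, never estimated; there is no
  genotype-based IBD machinery.
* The gene-set permutation collapses trinucleotide-context-preserving
  placement to class-specific gene rates; genes with atypical context
  composition will be placed slightly wrong relative to the
  context-preserving scheme.
* Ancestry-stratified case-control analysis is not implemented; references
  are pooled.
* P_CC values from real studies depend on per-gene callable fractions that
  are inputs here; with callable fractions defaulted to 1 the burden P
  values are anti-conservative relative to depth-adjusted ones.
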