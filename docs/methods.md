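# Methods

This note records the statistical models implemented in `craniostats`, the
conventions and numerical choices they embody, what the synthetic-data
generator does and does not emulate, and the known limitations.

## Variant classification and rarity

Coding variants are classed as loss-of-function (nonsense, frameshift,
canonical splice site), damaging missense (explicit ensemble call "D", or
rank score strictly greater than 0.83357 when only a score is available),
tolerated missense, or synonymous.  A missense variant with neither a call
nor a score raises an explicit error rather than defaulting to tolerated —
silent misclassification would deflate damaging-burden tests.

Rarity cutoffs are strict inequalities on population allele frequency:
`pop_af < 2e-5` for the dominant analyses, `< 1e-3` for recessive screens.
Variants absent from the reference database carry `pop_af = 0` (absence
among >10⁵ alleles is the strongest rarity evidence available).  Both
cutoffs and the score threshold live in `RarityPolicy` (YAML-serializable).

## De novo burden

With λ the expected count of a mutation class in the cohort, observed count
X is tested as Poisson:

* enrichment (obs > λ): p = P(X ≥ obs) — the inclusive upper tail;
* depletion (obs < λ): p = P(X < obs) = 1 − P(X ≥ obs), the complement of
  the inclusive upper tail, so the two tails of a test partition unit
  probability and never double-count the observed point mass.  An
  `lower_includes_observed=True` switch gives the inclusive lower tail
  P(X ≤ obs) instead.  When obs = 0 the lower tail is floored at the point
  mass P(X = 0): a realizable outcome never gets p = 0.

Per-gene tests are always upper-tail (one asks about excess in a candidate
gene).  A gene with observed hits but λ = 0 is reported with infinite
enrichment and boundary p = 0, with a warning — such a λ is a rate-table
artifact the caller must resolve.

Fisher's method combines k independent p-values via χ² = −2Σln pᵢ on 2k df.
p = 0 inputs are rejected (callers must use boundary-safe tails).  Note the
classical claim that combining k copies of the same p is monotone
decreasing for p < e⁻¹ is slightly optimistic; monotonicity holds up to
p ≈ 0.285, where the df penalty starts to dominate.

The multi-hit permutation throws n observed de novo events at genes with
probability proportional to each gene's mutability and reports the fraction
of (default 10⁶, seeded) iterations in which any gene is hit twice.  On
uniform weights this converges to the closed-form birthday-collision
probability, which the tests use as an oracle.

The attributable fraction is (observed − expected probands with
protein-altering de novo mutations)/n_trios, clipped at 0.

## Transmitted burden

Conditional on the total number N of rare damaging alleles found in
probands, the count in gene g is Binomial(N, p_g) with p_g the gene's share
of summed coding length.  The test is the upper-tail exact binomial;
enrichment is observed/(N·p_g).  Expected counts are conserved:
Σ_g N·p_g = N exactly.  Q-Q plots pair the i-th smallest observed p with
the (i − 0.5)/m uniform quantile (the convention is a documented choice;
any of the standard plotting positions would do).  Case-control
comparisons operate on carrier counts with the two-sided Fisher exact test
(probability ordering); sample odds ratios use the Haldane–Anscombe 0.5
correction when a cell is zero, flagged in the result.

## Epistasis statistics

Members of kindreds segregating a rare damaging variant are classed S+B+,
S+B−, S−B+ ("risk allele present" collapses dose 1 and 2); individuals with
neither allele fall outside the table, and skipped members (missing
genotype, unknown phenotype) are counted in the result rather than silently
dropped.

The Freeman–Halton test enumerates every r×c table with the observed
margins and sums the multivariate-hypergeometric probabilities of tables no
more probable than the observed one.  Probability-ordering ties are
resolved with a 10⁻¹² relative slack (affecting no fixture).  Full
enumeration is bounded at N ≤ 60 and ≤ 8 cells — comfortably above the
study-scale 3×2/N=48 table and exact there; beyond the bound a seeded
permutation Monte-Carlo fallback (with the +1 never-zero correction) is
provided.  On 2×2 tables the enumeration reduces exactly to the two-sided
Fisher test.

The TDT is χ² = (T − U)²/(T + U) on 1 df for T transmissions and U
non-transmissions of the risk allele from heterozygous parents to affected
offspring; transmissions are only counted where the transmitted allele is
determinate (het×het parents with a dose-1 child are skipped).  The χ²
reference is asymptotic: at small counts the exact level deviates from
nominal by discreteness (0.065 at 50 transmissions, 0.0517 at 2000), which
is why the calibration tests run at 2000 informative transmissions.

Penetrance is affected carriers / carriers; the ascertainment-corrected
variant removes probands from numerator and denominator, since probands
were selected for being affected.

## Two-locus linkage model

Each individual's genotype maps to one of five penetrance classes:

| class | parameter | default |
|---|---|---|
| carrier and ≥1 risk allele | f_both | 1.00 |
| carrier, no risk allele | f_S | 0.09 |
| non-carrier, one risk allele | f_B1 | 0.0008 |
| non-carrier, two risk alleles | f_B2 | 0.0032 |
| neither | f_0 (phenocopy) | 0.0002 |

with SNP risk-allele frequency q_B = 0.34, founder carrier frequency
q_S = 10⁻⁴, and zero recombination between each marker and its trait locus
(so the class is read directly off the markers).  A kindred's likelihood
conditions on observed genotypes: Π f(g)^affected (1−f(g))^unaffected over
members with known phenotype.  The null is genotype-independent phenotypes
at a population prevalence (default 5×10⁻⁴, configurable); "chance" is not
formally defined by descent, so this explicit null is a design choice of
the package.  lod = log₁₀ of the ratio; lods add over kindreds; a zero
numerator (an unaffected member in a fully penetrant class) surfaces as
−inf rather than being clamped — the grid search simply moves off such
models.

**Missing genotypes** are marginalized: the likelihood is summed over all
Mendelian-consistent completions, each weighted by P(completion | observed
genotypes) built from Hardy–Weinberg founder priors (q_B), the carrier
frequency (q_S, carriers modelled heterozygous), and Mendelian transmission
probabilities.  The weights involve genotype frequencies only — never
penetrances — so they are computed once per pedigree and reused across the
whole penetrance grid.  A child flagged as a de novo carrier contributes a
constant (parent-independent) carrier-state factor that cancels after
normalization.  Marginalization is bounded at 6 ungenotyped members
(6 states each); the test suite proves equality with brute-force joint
enumeration on pedigrees up to 8 members.

**Ascertainment.**  By default no correction is applied (the headline lod
of this analysis style is uncorrected); `condition_on_proband=True` divides
the numerator by each proband's penetrance and the null by the prevalence.

**ML search.**  Exhaustive, deterministic grid maximization of the total
lod over the five penetrance parameters; default grids are log₂-spaced
10⁻⁴…0.4096 plus 0.5, with f_both additionally allowed to reach exactly
1.0.  Ties resolve to the first grid point in lexicographic order.  The
single-locus comparison maximizes a carrier/non-carrier two-parameter model
on the same machinery and reports 10^(lod₂ − lod₁).

The study's printed totals (lod 7.37, the 1410-fold two- vs one-locus
ratio) depend on per-member genotypes of the 13 real kindreds, which are
not machine-readable here; the package instead proves the properties that
make such totals meaningful — oracle equality of the likelihood, lod
additivity, the degenerate-model zero, and parameter recovery on synthetic
cohorts — and reproduces every desk-scale statistic exactly.

## Synthetic cohort generator

One root seed fans out to named substreams (genes, de novo variants,
transmitted counts, pedigrees, transmissions), so each artifact regenerates
independently and reproducibly.

* **Trio cohort**: per-offspring de novo counts Poisson with cohort mean
  142.8/132; class mix proportional to the expected class totals
  (40.4 synonymous / 75.2 T-mis / 14.5 D-mis / 12.7 LOF); genes hit in
  proportion to coding length (log-normal lengths, median ≈ 1.5 kb, 500
  genes by default — a scaled-down gene universe that keeps every test
  fast while preserving the length-proportional structure); a spike gene
  receives extra damaging events (defaults: 2 de novo LOF + 1 de novo
  D-mis per cohort, transmitted damaging carriers at 10/191).
* **Kindreds**: founders draw SNP genotypes from HWE(q_B) and carrier
  status from q_S (or a seeded carrier founder, the default for
  variant-segregating kindreds); alleles drop by Mendelian transmission;
  affection is Bernoulli in the member's penetrance class.  Ascertainment
  is rejection sampling on an affected carrier proband.  By default
  kindreds are additionally conditioned on **no parent being affected**,
  emulating purifying selection — in real midline-craniosynostosis
  kindreds no transmitting parent was affected, and without this condition
  the carrier-without-risk-allele class is starved of members and f_S
  recovery is ascertainment-biased upward.  Both conditions can be
  disabled (`ascertain=False`) for raw population draws.
* **Null transmissions**: Binomial(n, ½) per replicate, for TDT size
  checks.

What the generator does **not** emulate: sequencing and calling error,
relatedness beyond the built-in templates (trio/quartet/three-generation),
population stratification, mosaicism, multi-allelic sites, compound
heterozygotes, and linkage disequilibrium between the two loci.  Passing
tests therefore demonstrate the statistics behave correctly on clean,
correctly specified genotype data — not robustness to the failure modes of
real call sets.

## Problem sizes used in validation

Acceptance-style checks run at: 50 replicates of 13 ascertained kindreds
for penetrance recovery (median recovered f_S required within 2× of 0.09;
observed ≈ 0.05–0.11 across seeds); 10⁴ replicates of 2000 fair
transmissions for TDT size; 500-gene null cohorts at the study's allele
totals (1135 and 3156) for binomial-burden size; 10⁵ permutation iterations
against the closed-form collision value.  The whole suite runs in well
under a minute on one CPU.

## Known limitations

* Pedigrees with loops are rejected; enumeration suffices at kindred scale
  and no Elston–Stewart peeling is implemented.
* θ is fixed at 0; recombination-fraction estimation is out of scope.
* Recessive genotypes are simple hom/het flags; compound heterozygotes are
  not modelled.
* The per-gene mutation-rate table is an input; the package does not
  re-derive trinucleotide-context mutabilities.
* The Freeman–Halton exact path is limited to small tables by design; the
  Monte-Carlo fallback is an estimate with the usual +1 conservatism.
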