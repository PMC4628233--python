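# Methods

## Scope and model

`strpopgen` analyzes diploid codominant STR (microsatellite) genotypes in
a closed dog breed: population diversity, individual homozygosity, MHC
(DLA) haplotype structure, case/control homozygosity risk, and pedigree
inbreeding. A forward-time breeding simulator generates cohorts with the
statistical structure these analyses assume, since raw breed genotypes of
this kind are typically not publicly deposited.

## Diversity statistics

Per locus, with allele frequencies `p_i` estimated from non-missing calls
only (each locus carries its own typed count `n_typed`):

- allele count `a` = number of alleles with `p_i > 0`;
- effective alleles `Ae = 1 / Σ p_i²`;
- observed heterozygosity `Ho` = fraction of typed individuals with two
  different alleles;
- expected heterozygosity `He = 1 − Σ p_i²` (the biased, GenAlEx-default
  form; no `2n/(2n−1)` correction);
- fixation index `FIS = (He − Ho) / He`, undefined (and excluded from the
  across-locus mean) at monomorphic loci.

Across-locus summaries are unweighted means with `SE = sd/√L` over the
`L` informative loci — not ratios of mean He to mean Ho. Group contrasts
of FIS use a paired t test over loci with a 99% CI of the mean
difference; contrasts of IR use one-way ANOVA with Tukey HSD. Missing
data are excluded locus-wise, never case-wise.

## Internal relatedness

For an individual typed at `N` loci with `H` homozygous loci,

    IR = (2H − Σ f_i) / (2N − Σ f_i)

where the sum runs over the frequency of each of the individual's `2N`
allele copies (both copies counted at homozygous loci — the standard
published convention). Scored against the individual's own cohort, IR is
relative by construction: the cohort mean sits near zero even in an
inbred population, because the frequencies are estimated from the same
genotypes being scored. Genuine inbreeding relative to an ancestral gene
pool appears only when the frequencies come from elsewhere — either a
base generation (used by the simulator tests) or a diverse reference
panel such as village dogs (IRVD). The reference panel is a pluggable
input; alleles absent from it receive a floor frequency, default
`1/(2·panel_size + 1)`. With the reference equal to the cohort table,
IRVD equals IR to machine precision.

The expectation of IR for an individual with inbreeding coefficient `F`
relative to the frequency source is `F` (numerator per locus has mean
`2F·He`, denominator `2He`), so offspring of full-sibling matings average
0.25 — the calibration point the simulator-based checks use.

Histogram summaries use a default bin width of 0.025 with bins aligned
to multiples of the width, modal-bin midpoint as the peak, and counts
above 0.20 and 0.40.

## Genotypic distance and PCoA

The pairwise distance is the Smouse–Peakall squared codominant genotypic
distance per locus (identical 0; one shared allele 1; disjoint
heterozygotes 2; homozygote vs disjoint heterozygote 3; disjoint
homozygotes 4), summed over loci typed in both individuals
(pairwise-complete; the shared-locus count is recorded, and a flag can
impute the mean distance for pairs with no shared locus, which otherwise
error). PCoA Gower-centers `−D/2`, eigendecomposes, and assigns
coordinates `v·√λ` only to eigenvalues above `1e-9` of the largest;
negative eigenvalues (non-Euclidean input) are reported without
coordinates, and percent variance is taken over positive eigenvalues
only. Axis signs are fixed by making the largest-magnitude loading
positive so plots reproduce. On exactly Euclidean input the embedding
reproduces the distances to machine precision (tested, and cross-checked
against scikit-bio's PCoA).

## DLA haplotype phasing

The four class I and three class II DLA-linked STRs are phased by an
Excoffier–Slatkin-style EM instead of Bayesian phasing — defensible at
this linkage tightness and fully testable. Per region: enumerate the
haplotype pairs compatible with each complete multilocus genotype
(individuals with any missing region call are excluded and listed);
E-step weights pair `(h1, h2)` by `(2 − δ_{h1h2})·f(h1)·f(h2)`; M-step
re-estimates `f`. Settings: convergence `max|Δf| < 1e-6`, at most 1000
iterations, prune threshold `1e-8`, five restarts (uniform start plus
four seeded Dirichlet perturbations) keeping the best likelihood. The
log-likelihood is asserted non-decreasing every iteration, and on small
instances the achieved likelihood matches direct numerical maximization.
Best pairs are maximum-posterior with lexicographic tie-breaking and
canonical (sorted) pair order.

The extended correction runs the same EM over the joint 7-locus system
with the haplotype space restricted to concatenations of region-level
haplotypes, so cross-region linkage — not new within-region phase
solutions — drives the correction; joint assignments override
region-level ones where they disagree. Catalog naming maps allele
vectors to the bundled published IDs (e.g. 1008, 2017); unknown vectors
get `novel-<region>-<k>` in descending-frequency order.

## Case/control association

Exposure is homozygosity at a DLA STR locus or at a region haplotype.
Relative risk is the ratio of within-group exposure proportions,
`RR = (a/n_case)/(c/n_control)` — the definition consistent with the
published per-locus values — with a log-normal (Katz) 95% CI.
Significance uses chi-square without continuity correction, switching to
a two-sided Fisher exact test when any expected cell is below 5 (the
test used is recorded per row). No multiple-testing correction is
applied by default; Bonferroni and Benjamini–Hochberg are available by
flag. Per-row denominators count only individuals typed at that locus or
phased at that region. Sex summaries report F/M ratios to one decimal,
with dogs carrying two disease forms counted once per form, and NA when
a row has no males.

## Pedigree algebra

Kinship uses memoized recursion (tabular-method equivalent), recursing on
the individual later in topological order; founders are unrelated and
non-inbred, and unknown parents behave as founders. `COI = φ(sire, dam)`.
An optional depth cap truncates ancestry at `g` generations (generation
1 = parents) to mirror 10-generation registry analyses. Path counting is
retained in the test suite as an independent oracle.

Ancestor contribution is the expected genome fraction,
`c_A(x) = 1{x = A}` else the parental mean. "Contribution in the
homozygous state" is operationalized as the probability that **both** of
an individual's alleles at a random autosomal locus descend through
ancestor `A` — estimated by seeded Monte Carlo gene dropping (default
100,000 reps, with the Monte Carlo SE reported) after relabeling `A`'s
two allele slots, and computed exactly by enumeration on small pedigrees
(`≤ 10` non-founders) for validation. It is bounded above by the
contribution and equals `(1/4)² = 6.25%` for a great-grandsire reached
once through each parental line.

Occurrence scans count pedigree *positions* occupied by the ancestor
within `g` generations (an ancestor reached via k positions counts k),
plus the cohort percentage with at least one occurrence.

## The simulator

What it emulates: a founder bottleneck; discrete non-overlapping
generations; a popular-sire effect (per-sire log-normal(0, 1) weights
raised to the `sire_concentration` power, so 0 is uniform sire use);
Mendelian gene dropping of unlinked genomic STRs from founder
frequencies (default: 33 loci, 4–8 alleles each, Dirichlet(1)
frequencies on a dinucleotide size ladder); a DLA block transmitted as
intact class I + class II haplotype pairings (default pairings use the
bundled catalog vectors at roughly the USA cohort frequencies) with
interblock recombination per meiosis (default 0.01 — a knob, since no
empirical rate is available); and a logistic liability disease assigned
post hoc from realized genotypes, with log-odds
`β0 + β_hapI·hom(DLA-I) + β_hapII·hom(DLA-II) + β_genome·homFrac +
β_sex·female` and defaults `β0 = logit(0.30)`, `β_hapI = ln 2`,
`β_hapII = ln 2.5`, `β_genome = 2.0`, `β_sex = ln 2`, chosen to echo the
case/control structure of the motivating surveys (class II homozygosity
the strongest DLA effect; females roughly twice as likely affected).

All randomness flows through one generator keyed by the mandatory seed,
consumed in documented order (pedigree, gene dropping, phenotypes), so a
config reproduces its cohort byte for byte.

What it does not emulate: STR mutation, X-linkage, selection during
breeding, overlapping generations, realistic litter-size distributions,
genotyping error or missingness. Tests passing on simulated cohorts
therefore certify the statistical machinery under idealized Mendelian
data, not robustness to real-world artifacts.

One behavior worth knowing: concentrating paternity in few sires
produces the classic *heterozygote excess* of a small parent pool, so
within-cohort FIS (and cohort-frequency IR) can decrease as the
popular-sire effect strengthens, even while inbreeding relative to the
founder gene pool accumulates. Monotonicity properties are therefore
asserted against base-generation frequencies.

## Problem sizes in the checks

The shipped checks use a base population of 500 and 1000 full-sib
offspring for the IR calibration; 2000 founders for logistic parameter
recovery; 2000 replicate 2×2 tables for the type-I error of the
chi-square/Fisher switch; cohorts of 100–600 for phasing-accuracy and
monotonicity properties averaged over up to 20 seeds; and exhaustive
enumeration oracles on instances small enough to enumerate (≤5
individuals for phasing, ≤10 non-founders for gene dropping). These
sizes give Monte Carlo errors comfortably inside the asserted
tolerances.

## Known limitations

- Phasing assumes complete region genotypes; partially missing DLA
  genotypes are excluded rather than imputed.
- The EM can in principle find a local likelihood optimum; restarts
  mitigate but do not eliminate this (no failure observed at the linkage
  tightness simulated here).
- The bundled published frequency tables are printed, rounded values;
  statistics recomputed from them differ slightly from statistics
  computed from the underlying raw genotypes (see the per-table notes in
  `strpopgen.datasets`), and rare alleles below print precision are
  absent.
- "Contribution in the homozygous state" is one reasonable
  operationalization; registry software does not publish its formula,
  and alternatives (e.g. requiring identity by descent through the
  ancestor) give smaller values.
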