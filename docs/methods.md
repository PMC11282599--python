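# Methods

## The analysis in brief

The package quantifies how GWAS-reported risk alleles for a polygenic
disease are distributed across human populations. All statistics operate on
biallelic SNP dosages (counts of the ALT — or, after alignment, the risk —
allele per diploid individual) grouped by a two-level sample panel:
sub-populations nested in super-populations, optionally recoding the
Admixed American group by ancestry (AMR1 = CLM + PUR, European-derived;
AMR2 = MXL + PEL, Latino). The pooled cohort ("global normal") is the
reference throughout.

## Genetic risk score

`GRS = Σᵢ Xᵢ / (2I)` with `Xᵢ ∈ {0,1,2}` risk-allele copies at SNP i and I
risk SNPs: the carried fraction of risk alleles, in [0,1], unweighted by
effect size (odds-ratio weighting would give a polygenic risk score, a
deliberate non-goal). Expectation over a population equals the mean
risk-allele frequency, which is the linearity property the tests exploit.

Missing genotypes: the paper-scale cohorts this emulates are essentially
complete, so the convention was open. Default: the denominator is rescaled
to the sample's non-missing SNP count (2·I_nonmiss), keeping scores
comparable across samples; a strict mode flags incomplete samples as NaN
instead. A sample with no non-missing risk genotype is always NaN.
Quartiles use linear interpolation between order statistics; the convention
is stamped into output so box plots are reproducible.

The bias analysis redraws scores on nested random allele subsets stratified
by discovery ancestry (Set1 = 2 EAS + 8 EUR, Set2 = Set1 + 5 EUR,
Set3 = 10 EUR by default), sampled without replacement, deterministically
from a seed.

## Enrichment and depletion

Per (risk allele, group): a 2×2 table of risk vs non-risk chromosome counts
in the group against the pooled global reference. Two-sided Fisher's exact
p under the point-probability rule (sum of all hypergeometric outcomes no
more probable than the observed table). The implementation evaluates the
hypergeometric pmf in log space (gammaln) over the support with a 1+1e-7
relative tie guard; exhaustive enumeration against exact rational
arithmetic over all tables with margins ≤ 30 bounds the error below 1e-13.

Adjustment: the family is the whole allele × group matrix;
Benjamini-Hochberg by default (standard for large enrichment grids),
Bonferroni available — both recorded in output metadata since either
convention can be matched. Signed score: 0 when p_adj > α (default 0.05),
otherwise ±(−log₁₀ p_adj) with the sign of (group frequency − reference
frequency); |score| capped at 320 if p_adj underflows. Alleles significant
nowhere are reported as "no significant change" and dropped from plots.

Reference definition: by default the global pool *includes* the tested
group (each population is compared against the whole cohort). This makes
the Fisher sampling model conservative — under a truly null cohort the
raw-p ≤ 0.05 rate is ~2%, not 5%, because the "two populations" share
samples. The `exclude_self` option uses the disjoint complement, which is
the configuration the null-calibration checks use; there the rate is
4.3–4.9% on 7 000 cells, the residual shortfall from 5% being ordinary
Fisher discreteness. The calibration test band is [0.03, 0.06].

Clustering: average-linkage agglomerative clustering of the groups'
score-vectors under Euclidean distance (configurable); deterministic. The
"outermost branch" diagnostic reports the group that splits off alone at
the dendrogram root — the qualitative structure expected when one
population is far more differentiated than the rest.

## SNP prioritisation

Three simultaneous gates per variant and population pair:

* **MAF ≥ 0.05** (inclusive), computed from non-missing genotypes; modes:
  all groups, any group, or a single target group.
* **Weir–Cockerham θ̂ ≥ 0.5.** θ̂ = a/(a+b+c) from the 1984
  variance-components estimator (a: among populations, b: among individuals
  within populations, c: within individuals), using *observed* heterozygote
  proportions from genotypes; an HWE fallback (h = 2p(1−p)) exists for
  frequency-only input and is flagged. θ̂ can be slightly negative; a locus
  monomorphic in every population is undefined and flagged. Per-locus θ̂ is
  the gate statistic. For recovering a genome-wide differentiation
  parameter the package uses the multi-locus ratio-of-sums Σa/Σ(a+b+c):
  averaging per-locus ratios is biased downward (measured ≈0.32 at a true
  F of 0.5 on 2000 SNPs) because each locus's denominator is noisy, while
  the ratio-of-sums recovers F to within ±0.02 at F ∈ {0.1, 0.3, 0.5}.
* **χ² + Bonferroni, α = 0.05.** The 1-df test of independence on the 2×2
  allele-count table — expected counts from the margins,
  Σ(Obs−Exp)²/Exp, upper-tail p. The statistic is inherently two-sided in
  the allele-frequency difference, which is the only reading of a
  "two-tailed" test on a 2×2 count table. No Yates correction by default
  (MAF-filtered, cohort-scale counts make it unnecessary; switchable). The
  Bonferroni family is the set of variants with a defined test in the
  current pair scan, recorded in output metadata. On large balanced tables
  (all expected counts ≥ 20, n = 500 per group) the α = 0.05 decisions
  agree with Fisher's exact test for ≥ 99% of simulated tables.

An audit mode emits every tested variant with per-gate flags, so the
prioritised set can be re-derived independently.

## Selection battery

Per (variant, population), against the rest of the cohort as reference:

| test | flag condition | default threshold |
|---|---|---|
| HWE χ² (1 df, genotype counts vs p̂²:2p̂q̂:q̂²) | p ≤ α | α = 0.05 |
| ΔDAF (derived-allele frequency, target − reference) | ≥ τ | τ = 0.3 |
| Weir–Cockerham Fst (pop vs rest) | ≥ τ | τ = 0.25 |
| Tajima's D, window centred on the variant | ≤ τ | τ = −1.5, window 10 kb |

Verdict: flags ≥ k, default k = 3. The thresholds are explicit
configuration recorded in every output — they are conventional screening
values, not claims about any external annotation service's internals.
Undefined tests (unpolarisable site, monomorphic locus, S = 0 window) count
toward neither side and shrink the reported effective panel. Haplotype
statistics (iHS etc.) require phased data and are out of scope; k is
configurable for reduced panels.

Tajima's D: π is computed from per-site allele counts
(2k(n−k)/(n(n−1)) for k alternate copies among n chromosomes — equal to
the mean pairwise Hamming distance between chromosomes, which is what the
independent oracle in the tests computes explicitly), S is the segregating
site count, and the standard constants a₁…e₂ use the window-wide chromosome
count. D is undefined at S = 0 and excluded from votes. A monomorphic
population sample is reported as trivially in HWE (p = 1).

## The simulator

Balding–Nichols: ancestral frequency p per SNP (uniform on a range, or
given explicitly), population frequency ~ Beta(p(1−F)/F, (1−p)(1−F)/F) —
so F *is* the expected Weir–Cockerham Fst, making parameter-recovery tests
well-posed — and genotypes ~ Binomial(2, p_pop), i.e. exact HWE within
populations. F = 0 is handled as the deterministic limit (no drift) rather
than a degenerate Beta. Planted shifts are added to the drawn frequency and
clamped to [0.01, 0.99] so planted loci stay polymorphic; designs needing
*exact* planted frequencies (e.g. 0.9 vs 0.1) simulate the planted block at
F = 0 on a second chromosome and concatenate cohorts. One autosome by
default, positions 1, 1001, 2001, …; a single generator seeded from the
config makes cohorts and their VCFs byte-identical across runs.

The default study layout mirrors a seven-super-population cohort
(AFR, AMR1, AMR2, EAS, EUR, SAS plus an Indian cohort, 100 diploids each)
with a 64-allele risk table split 62 EUR + 2 EAS discovery ancestry and
background F = 0.05–0.1 — the scale at which the power checks run: 2 000
neutral SNPs for calibration scans, shifts of +0.3 for enrichment power
(frequency 0.5 vs 0.2, n = 100 vs 700 pooled) and 0.9-vs-0.1 contrasts
(n = 200 per population) for prioritisation power.

What the simulator does **not** emulate: linkage disequilibrium and
recombination (every SNP is independent), phased haplotypes, admixture and
demographic history, genotyping error and missingness patterns, and allele-
frequency spectra shaped by selection. Consequently, passing tests certify
the estimators and the pipeline plumbing under the generative model — not
robustness to LD-induced correlation between test statistics, nor realistic
window-level Tajima's D distributions, which in real data depend on
haplotype structure.

## Numerical and interface conventions

* VCF positions are 1-based; windows are half-open [start, end); all
  internal indices 0-based. Multiallelic records are excluded with a logged
  count; `./.` and half calls are missing; missing genotypes leave both
  numerator and denominator of any frequency.
* Risk-allele alignment matches by (chrom, pos) with an rsID cross-check;
  risk = ALT copies the dosage, risk = REF flips it (2 − d). No strand
  flipping or A/T-C/G disambiguation is attempted — silently guessing
  strand corrupts risk scores, so mismatches are dropped and reported. The
  odds-ratio / reported-frequency filters that produce a curated risk table
  are assumed upstream; the redundancy (duplicate rsID) and
  absent-from-cohort filters are implemented here.
* Fisher p-values are exact; p_adj = 0 underflow is score-capped at 320.
* All randomness (simulation, subset draws) flows through seeded
  `numpy.random.Generator` instances; outputs embed the thresholds and
  conventions used.

## Known limitations

* Enrichment cells are treated as independent tests by BH/Bonferroni; in
  real data LD correlates them.
* The including-self reference (kept as the default for comparability with
  the analysis design it emulates) is conservative; use `exclude_self` when
  calibrated type-I error matters.
* Tajima's D constants assume the window's full chromosome count; heavy
  missingness would bias D slightly (sites use their own counts for π).
* The selection vote is a screen, not an inference: thresholds are
  conventional, and with four available tests k = 3 is strict.
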