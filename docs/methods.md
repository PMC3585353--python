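# Methods

## The statistical problem

Single-SNP association tests can miss risk variation that is carried by a
specific arrangement of alleles across nearby SNPs. Testing haplotypes
genome-wide raises three problems this package addresses: haplotypes are not
observed in unphased genotype data; windows that slide one SNP at a time
produce hundreds of thousands of strongly dependent tests; and admixture
(two ancestral populations mixing, as in African-American cohorts) can
confound haplotype-disease associations at both the global and the local
scale.

## Haplotype inference by E-M

Within a window of w SNPs, let f be the vector of population haplotype
frequencies. Assuming Hardy-Weinberg equilibrium, an unordered haplotype
pair (h1, h2) has probability f_h1 f_h2 (times 2 when h1 ≠ h2), and the
observed-data likelihood of an unphased genotype G sums that probability
over all pairs compatible with G. The E-step computes each individual's
posterior over compatible pairs at the current f, yielding the expected
dosage E[n_h | G] of every haplotype; the M-step replaces f_h by the mean
dosage over individuals divided by 2. Cases and controls are pooled: the
fit never sees the phenotype, which is what keeps dosage errors
non-differential and the downstream type-I error controlled.

Numerical choices (none of which a user normally needs to touch):

- **Initialization** is the product of observed per-SNP allele frequencies —
  deterministic, so fits are bit-reproducible. A fixed golden-ratio
  perturbation of relative size 1e-3 is applied once at initialization:
  perfectly symmetric configurations (e.g. a window where every sample is a
  double heterozygote) otherwise make the unperturbed product a stationary
  saddle point of the E-M map, and the deterministic jitter lets the
  iteration leave it while preserving reproducibility.
- **Convergence** is max |Δf| < 1e-8 with a cap of 1,000 iterations
  (windows of 5 SNPs typically converge in tens of iterations); dosages are
  computed at the final frequencies, and haplotypes with fitted frequency
  below 1e-12 are pruned.
- **Missing genotypes** at a site are treated as extra ambiguity: the pair
  enumeration expands over all allele completions. A sample whose
  compatible-pair count would exceed 2^20 is dropped from that window and
  recorded, bounding worst-case cost; for w ≤ 10 this cannot trigger
  without missing data.
- The haplotype universe is restricted to haplotypes appearing in some
  compatible pair — identical likelihood, far cheaper than all 2^w.
- Grouping samples by distinct genotype configuration makes the E-M cost
  depend on the number of configurations (≤ 3^w), not the sample size.

Invariants maintained and tested: frequencies sum to 1; each retained
sample's dosage row sums to 2; the observed-data log-likelihood never
decreases across iterations; on small windows the fit attains the global
maximum found by an independent multi-start simplex optimizer to within
1e-4 log-likelihood units.

## Association tests

Expected dosages substitute for the unobserved true counts in ordinary
logistic regressions ("expectation-substitution"). The engine is an
iteratively reweighted least-squares maximum-likelihood fit with step
halving, convergence |Δloglik| < 1e-8 (cap 50 iterations), and
quasi-complete separation reported as non-convergence when any coefficient
exceeds 30 on the logit scale. Rank-deficient designs raise a collinearity
error naming a redundant term.

- **Haplotype-specific test**: 1-df Wald test of a single dosage term,
  covariate-adjusted; per-copy OR = exp(β) with 95% CI exp(β ± 1.96 se).
  An LR variant is available by flag; the two agree closely at the sample
  sizes the pipeline targets (a tested sanity property, not an identity).
- **Global window test**: haplotypes at or below 1% frequency are
  discarded (strict ">" inclusion); among the k survivors the most frequent
  (ties broken by lexicographically smallest allele string) serves as
  reference and its dosage is excluded; the k − 1 remaining dosage terms are
  tested jointly against the covariates-only model by likelihood ratio with
  df = k − 1. The LR statistic was chosen over Wald for stability with
  correlated dosage columns. Windows with k ≤ 1 yield a degrees-of-freedom
  signal rather than a p-value, and per-window failures downgrade to status
  flags without aborting a scan.
- **SNP-adjusted test**: a 1-df LR test of the haplotype dosage with one or
  more additively coded SNP genotypes present in both the full and nested
  model. If the dosage is numerically in the span of the adjustment design
  (residual norm below 1e-8 of its scale), the models coincide and the test
  reports a collinearity signal with statistic 0 — the expected outcome
  when, say, a two-haplotype window makes the dosage equal a constituent
  SNP's genotype.

The default "best SNP" for adjustment is the constituent SNP with the
smallest additive Wald p ("contained best"); a regionally-best variant is
available by flag since either convention is defensible.

## Sliding windows and the scan

Windows hold w = 5 consecutive SNPs, advance one SNP at a time, and never
span chromosomes, so a chromosome with n SNPs yields n − 4 windows. Five
SNPs approximates the average LD-block span of West-African-ancestry
populations at ~1M-SNP genotyping density; the follow-up stage compensates
for the fixed width by searching variable lengths. The scan computes the
E-M once per window, shares the covariates-only null fit across windows,
and is deterministic and invariant to sample order.

## Permutation calibration of the effective number of tests

Adjacent windows share w − 1 SNPs, so global tests are strongly dependent
and Bonferroni over all windows is conservative. The calibration shuffles
the case-control labels B times (case count preserved exactly; covariates
untouched; E-M dosages computed once and reused, since phasing is
phenotype-blind), records each replicate's minimum global-test p, and
estimates the effective number of independent tests n_eff from the law
min of n i.i.d. uniforms ~ Beta(1, n):

- the empirical fifth percentile t of the sorted minima (order statistic at
  ceil(0.05 B)) is the chromosome-wide 0.05 threshold; n_eff = 0.05 / t,
  with the exact inversion log(0.95)/log(1 − t) reported alongside;
- the constrained MLE Beta(1, b): closed form b = −n / Σ log(1 − p_i);
- the half heuristic: round(n_windows / 2), half away from zero.

Goodness of fit of any fixed Beta(a, b) reference is assessed after the
probability-integral transform u = I_p(a, b) with the Kolmogorov-Smirnov,
Cramér-von Mises and Anderson-Darling statistics and fully-specified-null
asymptotic p-values (the Anderson-Darling limit law uses Marsaglia &
Marsaglia's double-precision approximation, since scipy does not expose
this case). The unconstrained beta MLE solves the digamma score equations
numerically (tolerance 1e-10) from a method-of-moments start.

The genome-wide significance level divides 0.05 by the half-of-total count
of windows genome-wide; with ~1.006M SNPs on 22 autosomes that is
0.05 / (1,006,392 / 2) ≈ 9.94×10⁻⁸. Per-replicate random streams are
spawned from one master seed so any replicate can be regenerated
independently.

## Region follow-up

A flagged region is extended by half its width on each side (in base pairs,
so the behaviour is reproducible across SNP densities), then every
contiguous run of 2..min(10, R) SNPs is phased and each haplotype above 1%
frequency tested individually; hits are ranked by unadjusted p with ties
broken by longer haplotype, then lexicographic allele string — a total,
deterministic order. Known-risk regions are scanned the same way in a
±250 kb flank around each index SNP (overridable per region, e.g. ±2 Mb
for a gene desert), with the index SNP added to the adjustment set.

Local ancestry enters as a covariate: per SNP the expected count of
European-origin alleles P1 + 2 P2 from the posterior triple, averaged over
the haplotype's constituent SNPs (several pooling rules are defensible; the
mean is the natural choice for a contiguous run). Reports of
"independent" regions merge extended spans that overlap.

## The synthetic-data generator

The generator is a haplotype-pool model, not a coalescent simulation: each
LD block is a pool of distinct haplotypes with Dirichlet frequencies, each
individual draws two pool haplotypes per block independently (HWE), and
genotypes are allele-count sums. This is the minimal generator consistent
with what the inference assumes — HWE within blocks, block LD, no LD
between blocks — and it keeps the ground truth (the exact haplotype pair
per sample) available for scoring. Disease status follows the logistic
model with an additive per-copy effect of a designated risk haplotype;
rejection sampling continues until the exact case/control counts are
reached, mirroring a fixed case-control design. Covariates are stand-ins
shaped like the motivating cohort: age ~ U(35, 75), a nine-level study
factor weighted by the source-study sizes, and ten standard-normal
eigenvector columns; their true effects default to zero.

The admixture variant draws each chromosome copy as a Markov mosaic over
two ancestral pools (transition probability 1 − exp(−rate·Δbp/10⁶) between
adjacent SNPs, stationary mixing proportion per sample), samples alleles
from the active pool's marginal frequencies, and records known-truth
local-ancestry posteriors as indicator triples plus a per-sample global
ancestry proportion.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: realistic recombination maps and
long-range LD decay, genotyping error, related individuals, more than two
ancestral populations, uncertainty in local-ancestry posteriors (the truth
tracks are degenerate), and covariate-genotype correlation beyond the
explicit admixture channel. In particular, window-to-window correlation in
the synthetic chromosomes comes only from the w − 1 SNP overlap of
adjacent windows, which is weaker than the LD-driven correlation of real
genotype data; the effective-number-of-tests ratio n_eff / n_windows
estimated on synthetic chromosomes therefore sits higher than the ~1/2
observed on real chromosome-scale data, and the half heuristic should be
re-derived by permutation for any new population or genotyping density.

A separate QC fixture reproduces a published cohort's sample-filter
arithmetic exactly: 5,984 samples with disjoint exclusion flags (52 low
DNA concentration, 29 unexpectedly related, 100 with call rate pushed
below 95% by injected missingness, 36 with low African ancestry, 6 of
ambiguous sex), leaving 5,761 survivors; the removal split of 137 cases
and 86 controls is forced by the published margins (3,153/2,831 in,
3,016/2,745 out) though never stated explicitly.

## Quality-control conventions

Sample QC runs before SNP QC. Call rate is the non-missing fraction with
strict "<" removal (a sample or SNP at exactly 95% is kept). MAF is
computed on non-missing calls of the post-sample-QC data, cases and
controls pooled. The HWE exact test conditions on allele counts and sums
conditional probabilities not exceeding that of the observed table (the
standard exact two-sided convention); monomorphic input returns 1. HWE is
reported at a configurable flag threshold (default 1e-6) and never used
for removal. Duplicate-concordance and relatedness exclusions are consumed
as input flags, not computed, since they require pair-level metadata the
package does not model.

## Problem sizes used by the tests and the acceptance script

Simulation-based checks use: 500 null cohorts of n = 2,000 for type-I
error of the global and haplotype-specific tests (binomial 99% acceptance
band around 5%); 100 cohorts of n = 5,700 with a per-copy OR of 1.79
planted at 3% haplotype frequency for CI coverage; 2,000 blocks for
constrained-beta recovery of n ∈ {10, 100, 7,823}; and an end-to-end
chromosome of 400 five-SNP blocks (2,000 SNPs) with n = 1,000 (500/500), a
planted per-copy OR of 2.0 at ~20% frequency, and B = 200 permutations.
The end-to-end sample size and effect were chosen so the planted window
separates cleanly from the null minimum over ~2,000 windows; the
distribution-shape check of the permutation minima uses n = 1,000 samples
so that the chi-squared tail of windows with up to ~20 degrees of freedom
is trustworthy.

## Known limitations

- Expectation-substitution attenuates large effects relative to a joint
  maximum-likelihood treatment of phasing and regression; the bias is
  negligible for the moderate ORs the scan targets but grows with the
  effect size and with haplotype uncertainty.
- Chi-squared asymptotics for high-df global tests degrade at small sample
  sizes; windows with many common haplotypes need n in the thousands.
- The pair-enumeration cost grows as 2^(m−1) in the number m of ambiguous
  sites; the cap (with sample dropping) bounds this but discards
  information in pathologically missing data.
- Fixed-width windows trade coverage for simplicity; haplotypes longer
  than the follow-up maximum of 10 SNPs are not searched.
- p-values are truncated below at the smallest positive double rather than
  reported as 0.
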