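# Methods

This note documents the statistical models behind each stage, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical choices a maintainer would want to know.

## Harmonization model

Two-sample analyses require both studies oriented to one allele frame. The
reference panel fixes that frame (ref/alt per variant, alt frequency,
block-diagonal LD). Filters run in a fixed order and each SNP is counted
under its first failure, so input = output + removals holds exactly:
non-autosomal, missing rsID, non-biallelic, duplicate rsID (the smallest-se
record is kept — it carries the most information), absent from panel,
allele-incompatible, rare, palindromic-ambiguous, frequency-discordant.

Orientation handles the eight allele/strand configurations: direct match,
swapped alleles, strand complement, and complemented-swapped, each with its
flip consequence (beta and Z negated, EAF complemented); anything else is
incompatible. A/T and C/G variants are strand-unresolvable from alleles
alone: those with EAF within 0.15 of 0.5 are removed (default
`palindrome_eaf_halfwidth=0.15`), and the survivors are oriented by
frequency match against the panel. Separately, any variant whose oriented
EAF differs from the panel frequency by more than 0.15 is removed as
discordant (`af_discordance_max=0.15`). Implementing both the
near-0.5-frequency rule and the study-vs-panel discordance rule covers the
two readings of the conventional "palindromic SNPs with allele frequency
differences" exclusion used in cross-study QC; both thresholds are
configurable. MAF threshold 0.01 is the field-standard rare-variant cut.
Coordinates are 1-based closed; the genome build is metadata only (no
liftover). Applying `harmonize` to its own output is a verified no-op.

## Synthetic data

The generator draws, per SNP, a causal state from the four-cell
distribution {neither, trait-1 only, trait-2 only, both} with probabilities
determined by (pi1, pi2, pi12). Causal effects on standardized genotypes
are normal with variance sigma_beta^2 per trait; shared causals are
bivariate normal with correlation rho_beta. A directional effect b_xy adds
b_xy * gamma_1 to every trait-2 joint effect (mediated pleiotropy).
Marginal effects are the within-block LD convolution R gamma; observed
scores are z_i = sqrt(n_i) R gamma_i + eps_i with eps ~ N(0, R) per block
and cross-trait noise correlation r0 — the single number through which
sample overlap enters, because it is exactly the quantity the
overlap-corrected meta-analysis consumes. On this scale se = 1/sqrt(n),
beta = z/sqrt(n), and h2 = M pi sigma_beta^2; closed forms for h2, rg
(= pi12 rho_beta / sqrt(pi1 pi2) when b_xy = 0) and their b_xy extensions
live in `truth_summary` and anchor every recovery test.

The LD panel uses AR(1) correlation blocks. By default each block's AR(1)
parameter is drawn uniformly from (0, 0.9): heterogeneous LD is what gives
LD scores a usable spread (roughly 1–10 here) — with a single global
parameter the LD-score regression design is nearly degenerate. Cross-block
LD is exactly zero. One global seed expands into labelled substreams
(panel / causal-status / effects / noise), so adding a stage never perturbs
earlier draws and all outputs are bit-reproducible.

What the generator does **not** emulate: MAF-dependent effect sizes,
annotation-stratified architectures, long-range LD, population
stratification, and case-control ascertainment beyond its effect on n.
Passing recovery tests therefore demonstrate internal consistency of the
estimators under the assumed polygenic model, not robustness to every
real-data pathology.

Default study conditions: recovery runs use M = 50,000 SNPs and
n = 100,000 per trait with per-trait h2 = 0.3. Architecture estimation uses
the polygenic scenario pi = 0.05 (2,500 causals, n sigma_beta^2 = 12);
Mendelian-randomization scenarios use the sparser pi = 0.01 with
n sigma_beta^2 = 60 so that a few hundred genome-wide significant
instruments exist; the mixture recovery uses pi = 0.01 with
n sigma_beta^2 = 9, a regime where the causal and null components overlap
substantially and the fit is genuinely informative. These sizes keep the
full suite and the acceptance script to a few minutes while leaving
standard errors small relative to the effects being recovered.

## LD-score regressions

`ldsc_h2` fits z^2 on l by weighted least squares with free intercept;
slope * M / n is the heritability, the intercept reports
confounding/overlap inflation (verified: multiplying all z by sqrt(1.2)
under the null moves the intercept to 1.2 and not the slope). Weights are
the single-pass heteroskedasticity weights 1/max(1, l) — deliberately
simpler than the iteratively reweighted scheme of the reference
implementation; recovery and calibration tests show it suffices at these
scales. Standard errors are delete-one-block jackknives over 200 contiguous
genomic blocks (jackknife SEs match replicate SDs within a factor of 1.5 on
null simulations). `ldsc_rg` regresses z1 z2 on l (slope
sqrt(n1 n2) rho_g / M, free intercept absorbing overlap) and jackknifes the
*full* rg functional including both univariate fits, so the error
propagates the h2 uncertainty. rg is not clamped: out-of-range values set a
warning flag instead, because clamping hides diagnostic information. No
large-chi^2 SNP exclusion is applied by default.

## Liability conversion and sign test

The observed-scale case-control heritability converts by
h2_lia = h2_obs K^2(1-K)^2 / (P(1-P) phi(t)^2), t the upper-K normal
quantile. The sign-concordance test is the exact binomial test of
concordant directions among one trait's genome-wide significant,
LD-independent index SNPs evaluated in the other trait, two-sided at
probability 1/2. Two-sided is the convention adopted here (it is also the R
default the analysis chain this package re-implements reports using): both
published worked examples (67/90 → 3.80e-6, 33/51 → 4.89e-2) reproduce
under it, the latter equalling twice the one-sided tail. A Z of exactly
zero in the second trait counts as discordant and is logged.

## Mixture-lite polygenicity model

z_j ~ (1-pi) N(0, 1) + pi N(0, 1 + n sigma_beta^2 l_j), sigma_0^2 fixed at
1. The fit is expectation-conditional-maximization: closed-form pi update,
bounded one-dimensional maximization for sigma_beta^2 in log space;
the observed log-likelihood is asserted non-decreasing (guarded GEM step)
and convergence is a log-likelihood gain below 1e-6. The deliberate
simplification relative to full LD-convolution mixture models is that LD
enters only the causal-component variance, not the spreading of causal
effects onto neighbouring SNPs. Consequently on LD panels pi_hat absorbs
tagging SNPs and is biased upward (about 4x at block LD ~0.6 in our
simulations); recovery is therefore validated in the LD-free regime where
the model is correctly specified, and all outputs carry the label
"mixture-lite" to prevent over-claiming comparability with full-likelihood
estimates of causal-variant counts.

## Overlap-corrected meta-analysis

The null Z correlation is estimated from SNPs with |Z| <= 1 in *both*
studies — truncation removes non-null effects; "either trait exceeds the
threshold" is the exclusion rule, and exclusion (not winsorizing) is the
reading adopted. Restricting a bivariate normal to the central box
attenuates its correlation severely (rho = 0.6 yields a truncated-sample
correlation near 0.25; rho = 0.3 near 0.09). `estimate_overlap` therefore
inverts the exact truncation map — computed by tensor-product
Gauss–Legendre quadrature, strictly monotone in rho, inverted by Brent's
method — and returns the de-attenuated value by default, keeping the raw
truncated-sample correlation alongside and a `deattenuate=False` switch.
This choice is forced by calibration: with the raw value the combined Z is
anti-conservative (type-I error ~2e-3 at alpha = 5e-4 under rho_0 = 0.6),
while the de-attenuated estimate keeps the empirical type-I error within
binomial bounds at one million null SNPs for r0 in {0, 0.3, 0.6}. Omega
keeps a unit diagonal (the combined-Z formula presumes unit null variance);
weights come only from Omega — the optimal-weight formula has no
sample-size term, and an optional sqrt(n) scaling exists for comparison but
is off by default.

Genomic inflation: lambda_GC = median(z^2)/0.454936 (the chi-square(1)
median) and lambda_1000 = 1 + (lambda_GC - 1) * 500 (1/n_cases +
1/n_controls), the standard case-control rescaling.

Clumping is greedy: best-p significant SNP leads a clump, absorbs
unassigned significant SNPs at r^2 >= 0.6; candidate leads at
r^2 >= 0.1 with a retained better lead are demoted and merged; clumps
within 250 kb on one chromosome merge into a locus. Thresholds mirror the
documented defaults of the standard GWAS annotation platform and are fully
configurable, since locus counts are sensitive to them. Ties in p break by
(chrom, pos, snp_id), making output order-independent of input order.

## Mendelian randomization

Instruments are exposure SNPs at p <= 5e-8 (inclusive), greedily LD-pruned
to pairwise r^2 < 0.05 within 1 Mb, intersected with the outcome.
The causal effect is the inverse-variance-weighted mean of Wald ratios
b_zy/b_zx with delta-method SEs. The generalized-least-squares treatment of
LD-correlated instruments used by GSMR-class methods is intentionally
replaced by IVW over pruned instruments: below r^2 = 0.05 the LD correction
is second-order, and the substitution is stated in result metadata. HEIDI
outlier removal is a single pass: each instrument's ratio is compared to
the leave-one-out IVW estimate (symmetric, unlike the original
top-instrument reference, which remains available via
`heidi_reference="top-instrument"`), with two-sided normal p; removal is
strictly below 0.01. Under pure shared pleiotropy filtering demonstrably
shrinks the spurious causal estimate (property-tested). Instruments with
b_zx = 0 are dropped, never imputed. `min_instruments` defaults to 10, the
cited convention for this method family. A known limitation: selecting
instruments on exposure significance induces mild winner's-curse
attenuation of beta_xy (about 3% at the default simulation scale), visible
but within three SEs in the recovery tests.

## Gene-based test and enrichment

SNPs map to genes within a symmetric, strand-agnostic 20 kb window (a SNP
may serve several overlapping genes). The statistic S = sum z_j^2 has null
law sum lambda_i chi2_1 with lambda_i the eigenvalues of the SNPs' LD
matrix; it is evaluated as a * chi2_nu with a = Var/2E, nu = 2E^2/Var,
E = tr(R), Var = 2||R||_F^2 — exact for identity LD (nu = m, a = 1),
verified within a factor of 3 of a million-draw Monte Carlo across
p in [1e-4, 0.5] on AR(1) LD, and uniform on null data by KS. A
`monte_carlo=` mode provides the sampling-based tail for small genes.
Per-trait gene p-values reuse the same assignment and LD submatrices with
each trait's Z vector, so the three-way comparison (trait A, trait B, meta)
is internally consistent. The shared-gene filter is inclusive on all three
thresholds (meta Bonferroni 0.05/#genes; per-trait 1e-4) and monotone in
each. Enrichment is the competitive model: probit-transformed gene p
(clipped to [1e-300, 1-1e-16], clipping logged) regressed on membership
plus log SNP count and log gene length, one-sided for positive enrichment;
constant covariate columns are dropped to keep the membership coefficient
identified; set-level p-values are uniform under random membership (KS-
tested at 10,000 sets).

## Pipeline

The `all` subcommand validates every configured path up front (nothing is
written on failure), runs stages in fixed order, records per-stage status,
and attempts later independent stages after a failure. Identical config and
seed give bit-identical outputs apart from the wall-time line. Exit codes:
2 configuration, 3 data, 4 estimation.

## Known limitations

- No liftover, sex chromosomes, multi-allelic decomposition or INFO
  filtering; inputs are assumed on one build.
- LD is block-diagonal everywhere; long-range LD and cross-block leakage
  are absent by construction in both generator and estimators.
- mixture-lite polygenicity is not comparable to full LD-convolution
  causal-count estimates (see above).
- IVW-over-pruned-instruments approximates the GLS treatment of instrument
  LD; with aggressive pruning thresholds the difference is second-order.
- Locus counts depend on unprinted clumping conventions; they are
  config-exposed rather than asserted against any published count.
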