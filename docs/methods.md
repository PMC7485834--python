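# Methods

This note documents the statistical models implemented in `mrkit`, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical conventions that matter for
reproducing results.

## Two-sample MR model

All analyses operate on GWAS summary statistics only.  For instrument j,
let b_Xj (SE se_Xj) be its estimated effect on the exposure (SD units for
quantitative traits) and b_Yj (SE se_Yj) its estimated effect on the
outcome (log odds ratio for binary traits), estimated in non-overlapping
samples (two-sample design).  Under the instrumental-variable assumptions
each Wald ratio r_j = b_Yj/b_Xj estimates the causal effect; the
first-order SE is se_Yj/|b_Xj| and the IVW weight w_j = b²_Xj/se²_Yj.

**IVW.**  β̂ = Σw_j r_j/Σw_j; fixed-effects SE (Σw_j)^(−1/2).  The default
is the multiplicative random-effects model, which scales the fixed SE by
max(1, √(Q/(k−1))) where Q = Σw_j(r_j − β̂)² is Cochran's statistic.  The
dispersion is floored at 1 so chance underdispersion never narrows the CI;
the practical consequence is a mildly conservative type-I error under the
null (≈0.04 at nominal 0.05 in the calibration benchmark).  k = 1 is
served by a separate Wald-ratio function rather than silently degrading
IVW.

**MR-Egger.**  Weighted least squares of b_Yj on b_Xj with an intercept,
weights 1/se²_Yj, after orienting every instrument so b_Xj > 0 (flipping
b_Xj and b_Yj jointly).  The intercept estimates the mean directional
pleiotropic effect; its z-test is the pleiotropy diagnostic.  Both SEs
carry the dispersion factor max(1, √(Q_egger/(k−2))).

**Weighted median.**  Ratios ordered ascending; with normalized weights
p_j ∝ 1/se²_rj and cumulative midpoints s_j = cum(p)_j − p_j/2, the
estimate linearly interpolates r at s = 0.5.  SE by parametric bootstrap:
b_Xj and b_Yj are redrawn from normal(b̂, se) (default 1,000 replicates,
seeded; bit-reproducible given the seed).

**Mode.**  The argmax of a normal-kernel density over the ratios with
modified-Silverman bandwidth 0.9·min(sd, IQR/1.349)·k^(−1/5) times a
user bandwidth factor, weighted (default) or unweighted.  The maximum is
located on a 2,001-point grid and polished by bounded scalar optimization
(tolerance 1e-13); identical ratios short-circuit to the common value.
SE by the same parametric bootstrap.

**Steiger directionality.**  Per-instrument variance explained via the
t-statistic transform r²_j = t²_j/(t²_j + n − 2), summed over instruments
for exposure and outcome; the outcome uses the effective case-control
size n_eff = 4/(1/n_case + 1/n_control).  The reported p-value compares
the two aggregate correlations by Fisher's z at their respective sample
sizes.  Sample sizes must be supplied; nothing is imputed.

**Power.**  For a binary outcome with N = n_case + n_control and case
fraction φ, the IVW z statistic under OR_alt has mean
d = |ln OR_alt|·√(N·r²·φ(1−φ)); two-sided power at level α is
Φ(d − z_{1−α/2}) + Φ(−d − z_{1−α/2}), which correctly degenerates to α at
OR_alt = 1.  The self-consistency benchmark confirms the formula tracks
the Monte-Carlo rejection rate of the actual IVW estimator within one
percentage point at the default sample sizes.

## Instrument construction

Significance filtering is strict (P < threshold).  LD clumping is greedy:
instruments are ranked by ascending p-value (ties broken
lexicographically by rsID for determinism); the best remaining SNP is
accepted and all remaining SNPs with r² ≥ 0.001 to it are discarded, so
the result is pairwise independent at the threshold.  SNPs absent from
the LD matrix are dropped, not assumed independent.  Cross-trait pruning
removes instruments with P < 10⁻³ in any other supplied trait; SNPs
missing from another trait's table count as not associated.

Heterogeneity pruning iterates: compute IVW and Q; stop when the Q test
p-value ≥ 0.05 (configurable); otherwise remove the instrument with the
largest contribution w_j(r_j − β̂)² and repeat, never shrinking below 3
instruments.  Each removal strictly decreases Q, so termination is
guaranteed.  The same scheme applies to multivariable sets via the global
Q_A with a floor of K+2 instruments.

## Harmonization

Tables are aligned to the first exposure's effect allele.  Identical
allele pairs are kept or sign-flipped; reverse-complement pairs are
strand-corrected first; palindromic SNPs (A/T, C/G) are resolved through
allele frequencies only when every table's effect-allele frequency is
outside 0.5 ± 0.08 (the window mirrors the common default of the
reference harmonization tooling), otherwise dropped; anything else is an
allele mismatch.  Every decision is recorded so kept + flipped + dropped
counts exactly partition the rsID intersection.  SNP identity is
rsID-based; chromosome/position are used only for locus windows (1-based
inclusive).  Multi-allelic rsIDs are rejected at read time.

## Multivariable MR

With m instruments and K exposures, β̂ = (BᵀWB)⁻¹BᵀWy,
W = diag(1/se²_Yj), no intercept.  The covariance is (BᵀWB)⁻¹ scaled by
max(1, Q_A/(m−K)) under multiplicative random effects.  Conditional
instrument strength per exposure follows the Q-based (Sanderson–
Windmeijer) construction: regress that exposure's effect column on the
others (same weights), then F_cond = Σ(resid²_j/se²_Xjk)/(m−K+1).
F < 10 raises a weak-instrument flag but is never auto-enforced.
Instrument assembly is union-first: per-exposure significant-and-clumped
sets are united, restricted to SNPs present everywhere, then re-clumped
jointly with SNPs ranked by their best p-value across exposures.
Rank-deficient designs raise an error naming the collinear exposures.

## Locus-level MR and meta-analysis

Conditionally independent association statistics (from prior stepwise
conditional analysis) are trusted as independent — no clumping inside
loci.  A locus's instruments are the conditional SNPs within the gene
span ± 100 kb (inclusive); loci with fewer than two surviving instruments
are excluded, not errored.  Per-locus estimates use fixed-effects IVW;
cross-locus pooling is fixed-effects inverse-variance meta-analysis
(pooled variance 1/Σ(1/var_i), heterogeneity Q with n−1 df).  The same
pooling kernel applied SNP-wise gives the two-study GWAS meta-analysis,
with allele harmonization first and unpooled SNPs passed through under a
status flag.  A 16-locus HDL/LDL pathway table (approximate hg19 RefSeq
spans) ships as package data; it is ordinary user input, not a hard-coded
dependency.

## Cross-trait LD-score regression

Univariate model E[z²_j] = a + (n·h²/M)·ℓ_j; cross-trait model
E[z1_j·z2_j] = a_ct + (√(n1·n2)·ρ_g/M)·ℓ_j; r_g = ρ_g/√(h²₁·h²₂).
Weights are the standard heteroskedasticity/overcounting weights
1/(ℓ_j·2(1 + b̂ℓ_j)²) frozen from a pilot slope.  Intercepts are
estimated by the two-step scheme (intercept on the χ² < 30 subset, slope
on all SNPs with the intercept fixed); when that cutoff would truncate
more than 5% of SNPs — which happens whenever the polygenic signal is
strong enough that mean χ² approaches the cutoff — the fit falls back to
a single-step free-intercept regression, which is unbiased without the
truncation.  Sample overlap is absorbed by the estimated cross-trait
intercept; it is never fixed.  All SEs are delete-one-block jackknife
estimates over 200 contiguous SNP blocks (reduced with a warning if
fewer than 3 SNPs per block), computed exactly from per-block sufficient
statistics, so they are bit-reproducible.  r_g's jackknife propagates all
three fits per deleted block.  Local (region-level) genetic correlation
estimation is out of scope; only the Bonferroni arithmetic over genome
partitions (α/n_tests) is provided, with the partition count supplied by
the caller.

## Synthetic-data generator

The generator works at the summary level — no individual genotypes — which
is sufficient for every method in the package and orders of magnitude
faster.  Per-SNP true effects on K exposures use a correlated
spike-and-slab: one causal SNP set shared across exposures (exposure-
specific extras when causal proportions differ) with slab effects drawn
multivariate normal under the configured K×K correlation matrix; sharing
the spike makes the realized correlation of the effect vectors equal the
configured one in expectation.  Effects are rescaled so the variance
explained per exposure, Σ 2f(1−f)β², equals h²_x exactly.  The outcome's
true per-SNP log-OR is Σ_k θ_k β_jk plus an optional direct (pleiotropic)
effect on a fraction of causal SNPs.  Directional pleiotropy is defined
relative to the exposure-raising allele of the first exposure: a
fixed-sign mean direct effect under arbitrary allele orientation would
cancel in any orientation-invariant analysis and be undetectable by
design.  Optionally, direct effects correlate with instrument strength
(violating the InSIDE assumption).

Sampling noise is independent between exposure and outcome tables
(two-sample design): se_X = 1/√(2f(1−f)·n) for SD-unit exposures and
se_Y = 1/√(2f(1−f)·N·φ(1−φ)) for the log-OR scale of a case-control GWAS
with N total samples and case fraction φ (the standard logistic-GWAS
approximation; note N·φ(1−φ) = n_eff/4).  Optional LD is block-structured
with constant r² inside consecutive blocks: marginal effects are
R·β and sampling noise is equicorrelated within blocks.

Defaults mirror a five-exposure lipid-style study: exposures hdl, ldl,
tg, bmi, menarche with direct log-OR effects (0.06, 0.04, −0.02, −0.10,
−0.04); HDL–TG effect correlation −0.5 (HDL and triglycerides are
strongly inversely correlated), BMI negatively correlated with HDL and
age at menarche; m = 2,000 SNPs, 5% causal, h² captured per exposure
0.05, exposure GWASs of 200,000 and an outcome of 120,000 cases /
100,000 controls.  The LDSC test bed draws LD scores from 1 + Gamma(2, 15)
and simulates z-scores directly under the regression model.

What the generator does **not** emulate: realistic LD from reference
haplotypes, population stratification, MAF-dependent genetic
architecture, assortative mating, or sample overlap between exposure and
outcome GWASs.  Passing recovery tests therefore demonstrates the
estimators' correctness under the stated model, not robustness to those
real-data complications.

Everything derives from one seeded generator per configuration; rerunning
with the same configuration yields byte-identical output tables.

## Estimands under correlated exposures

With correlated exposure effects, single-trait MR converges to the
exposure's *total* genetically proxied effect (the correlation-weighted
combination of all direct effects), not its direct effect — on the default
fixture the hdl total effect is ≈0.10 versus a direct 0.06.  That is the
phenomenon motivating multivariable MR, whose estimand is the direct
effect θ_k.  Accordingly, the recovery benchmarks check single-trait IVW
coverage on a single-exposure study (where total and direct coincide) and
check multivariable coverage of each θ_k on the five-exposure fixture.

## Benchmark problem sizes

The acceptance script and tests use: 100 replicates for single-trait
coverage (m = 500 SNPs, K = 1, θ = 0.1); 100 replicates of the
five-exposure fixture for multivariable coverage; 1,000 replicates each
for Egger intercept size and null calibration; 100 seeds of 50,000-SNP
panels for genetic-correlation recovery; 2,000 noise replicates × 3
odds-ratio settings for power self-consistency.  These sizes put
Monte-Carlo error well inside the asserted bands while keeping the whole
suite under a minute on one CPU.

## Known limitations

* Correlated-instrument (generalized) IVW, MR-PRESSO, contamination
  mixture and MVMR-Egger are not implemented.
* First-order Wald-ratio SEs ignore the exposure-side variance term; at
  the instrument strengths enforced by genome-wide significance the
  neglected term is second-order.
* The mode estimator's bandwidth rule is the conventional plug-in; no
  cross-validation.
* LDSC here is the plain (non-partitioned) estimator; annotation-
  stratified heritability is out of scope.
* p-values are normal-theory throughout (appropriate for the large-k,
  large-n summary-statistics regime); no multiple-testing correction is
  applied across MR methods, which are strongly correlated.
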