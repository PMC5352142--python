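# Methods

This note documents the models behind each `pairedqtl` module, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical conventions.

## Synthetic cohorts (`pairedqtl.simulate`)

Genotypes are Hardy–Weinberg: the dosage of SNP *j* is the sum of two
independent Bernoulli(maf_j) draws, so hard calls follow (1−q)², 2q(1−q),
q². SNPs sit every 1 kb on one synthetic chromosome with probe midpoints
interleaved, which keeps the 1 Mb cis window meaningful at toy scale; an
architecture may assign selected probes to a second chromosome
(`distal_probe_indices`) because the toy chromosome is far shorter than
the 5 Mb trans exclusion — without it no trans pair could exist.

Expression of probe *k* in cell type *c* is
Σ β_{j,k,c}·g_j + u_i + covariate effects + ε, with a per-individual
intercept u_i ~ N(0, 0.5²) **shared between the two cell types** (paired
donors), small additive sex/age/batch effects (loading SD 0.1, so
residualization is testable and non-trivial), and ε ~ N(0, 1). Methylation
for coupled CpGs is a negative-slope linear transform of the probe's
genetic component plus noise, emulating promoter methylation inversely
correlated with expression. What the generator does **not** emulate:
linkage disequilibrium (SNPs are independent), imputation dosage
uncertainty, array-intensity artefacts, and cell-composition effects —
so passing tests demonstrate estimator correctness under the assumed
model, not robustness to those real-data features. In particular, without
LD the "significant pair" lists contain no correlated proxies, which is
why pair-level significance uses the τ\* rule below.

The mediation generator draws, per replicate, snp = B(1, 0.37) + B(1, 0.37),
g1 = 0.903 − 1.237·snp + N(0, 1), g2 = 0.031 − 0.534·g1 + N(0, 1), with
1000 replicates of n = 1000 as the default study settings. The g1→g2 slope
sign is configurable; published renderings differ in sign between
presentations and all downstream summaries use magnitudes, so the default
follows the primary (negative) statement.

Randomness: one root seed per cohort; child streams (MAFs, genotypes,
individual intercepts, per-cell noise, methylation, covariates) are spawned
from `numpy.random.SeedSequence` in a fixed order, so identical seed +
config reproduces byte-identical cohorts and single streams can be
re-drawn independently.

## Association scans (`pairedqtl.mapping`)

Coordinates are 1-based; the cis window is inclusive (≤ 1 Mb between SNP
position and probe midpoint), the trans exclusion strict (> 5 Mb, or any
pair on different chromosomes). SNP QC removes MAF ≤ 0.05 (MAF = mean
dosage/2 folded to [0, 0.5]), call rate ≤ 0.95, and HWE p ≤ 0.001 by a
1-df chi-square on dosages rounded to hard calls; SNPs whose dosages are
too far from integers (> 5 % of samples beyond 0.1) skip the HWE filter
with a logged note, since a hard-call chi-square is meaningless for
strongly imputed dosages.

The statistic is Spearman's ρ with midrank ties, p from the t
approximation with n − 2 df; an exact permutation p is available for
n ≤ 8 as a testing hook. Missing dosages are handled pairwise-complete
(`n_used` recorded); scans are deterministic in input order (SNPs and
probes are sorted by coordinates before testing). Quantile normalization
replaces each sample's sorted intensities by the across-sample mean order
statistics (ties get the mean of their span) before log2.

**Probe-level FDR.** Per probe the observed minimum p over its tested
SNPs; the null permutes expression sample labels with genotypes fixed
(preserving any LD), recording each probe's min-p per permutation. For
each observed threshold τ, FDR(τ) = (mean permuted count of probes with
min p ≤ τ)/(observed count ≤ τ), capped at 1 and monotonized
(non-decreasing in τ by a right-to-left cumulative minimum, the step-up
convention). A probe's q is FDR at its own min-p. Pair-level reporting
uses τ\*, the largest threshold whose FDR is still ≤ the level: a pair is
`significant` iff its probe's q ≤ level **and** its own nominal p ≤ τ\*.
Without this second condition every unassociated SNP of a significant
probe would enter downstream pair lists, which (absent LD) dilutes
replication estimates toward the null. Default 100 permutations for
pipelines; calibration and π0 tests use more because the permutation
p-values are discrete — p = (1 + c)/(1 + B) shifts mass upward by ~1/B,
which matters in the π0 tail (below).

Cis correction before the trans scan residualizes each probe with a
significant cis hit on its top cis SNP (lowest p, ties broken by smallest
position — the tie rule is our choice).

## π1 replication (`pairedqtl.pi1`)

π̂₀(λ) = #{p > λ}/(m(1 − λ)) on λ = 0.05…0.95 (step 0.05). The final π0
is the 3-df cubic smoother of π̂₀(λ) evaluated at max λ and clipped to
[0, 1]; we realize the smoother as a degree-3 polynomial least-squares
fit over the 19 grid points, which is the natural 3-df choice and behaves
like the customary smoothing spline on this short, smooth curve. For
m < 100 the tail is too sparse and a fixed λ = 0.5 estimate is used
(logged). Replication π1 applies the estimator to the replication
p-values of the discovery-significant pair list.

## Two-tissue Bayesian model averaging (`pairedqtl.bma`)

Per-pair, per-tissue summary statistics are simple-regression β̂ and SE of
residualized expression on dosage (an SE floor of 1e-8 guards exact-fit
degeneracies). For configuration γ the prior covariance of true effects
has φ² + ω² on the diagonal and ω² off it (ω² shared scale, φ²
heterogeneity), and

  BF(γ) = N(β̂_γ; 0, V_γ + Σ_γ) / N(β̂_γ; 0, V_γ),  V_γ = diag(SE²),

averaged arithmetically (in log space) over the default grid: total prior
SD ∈ {0.1, 0.2, 0.4, 0.8} × heterogeneity fraction ∈ {0, ¼, ½, ¾, 1}. The
framework's published grid is not printed, so this standard scale/
heterogeneity cross is used and is configurable. The probe-level BF per
configuration averages over the probe's SNPs (uniform prior on which SNP
is the eQTL; averaging vs maximizing is an open choice — we use the
average and record it in the fit JSON as `snp_bf_pooling`).

EM maximizes Σ_probes log[π0 + (1 − π0) Σ_γ η_γ BF̄_γ] over η with π0 held
fixed; the log-likelihood is non-decreasing by construction and asserted
on every trace. π0 comes from probe-level permutation p-values: the joint
min-p across both tissues under **simultaneous** permutation — the same
draw permutes the samples shared by both tissues identically (their
statistics are correlated through shared individuals; independent
per-tissue permutations would make the null min stochastically too small
and bias π0 upward), with tissue-specific extras permuted among
themselves. Posteriors follow by model averaging; the declared set at an
FDR level is the largest posterior-ranked prefix whose mean (1 −
posterior) stays ≤ the level.

## Colocalization (`pairedqtl.coloc`)

Single causal variant per trait per region. Per-SNP log-ABFs from
(β, se) when available, otherwise |z| is reconstructed from p and the SE
approximated from the variance explained under HWE
(se² ≈ 1/(2·MAF·(1−MAF)·N), with a case-fraction factor for case-control
traits) — an approximation, documented as such. Default prior effect SD:
0.15 for case-control log-odds, 0.20 for quantitative traits (the cited
framework's convention; configurable). Hypothesis sums L1, L2,
L3 = L1·L2 − L4, L4 are carried in log-sum-exp arithmetic; posteriors are
proportional to {1, p1·L1, p2·L2, p1p2·L3, p12·L4} with defaults
p1 = 10⁻⁴, p2 = 10⁻⁵, p12 = 10⁻⁶ and a 2 × 2 sensitivity sweep of p2 and
p12.

## Mediation and path models (`pairedqtl.mediation`)

Candidate models over (SNP, G1, G2): the chain SNP→G1→G2, the reversed
chain SNP→G2→G1, and the fork SNP→G1, SNP→G2 with independent errors.
Recursive models with uncorrelated errors are fitted by per-equation OLS,
which coincides with ML (asserted against the covariance-ML oracle in
tests); the implied covariance is (I − B)⁻¹Ψ(I − B)⁻ᵀ. Fit: χ² =
(n − 1)·F_ML against the saturated model with df = 6 − #free parameters
(3 variances + 1 per edge; means saturated), baseline = mutual
independence; CFI, TLI, RMSEA by their standard formulas and AIC =
−2ℓ + 2k. Sample covariances use the n − 1 denominator consistently; no
robust corrections. The Sobel statistic is the first-order form
z = ab/√(b²s_a² + a²s_b²) (the limit a = b = 0 is defined as z = 0,
p = 1). `run_mediation_study` refits, per replicate, the two comparison
regressions G1 ~ G2 + SNP and G2 ~ G1 + SNP and the direct generative
regressions, summarizing coefficients by mean and percentile 95%
intervals. Note that in the noiseless limit G1 is an exact function of
the SNP and the comparison regressions become collinear; only the direct
regressions are well posed there.

## Paired contrasts (`pairedqtl.contrasts`)

A REML linear mixed model with one random intercept per subject (no
random slopes) and fixed condition + covariate effects; the contrast is
the fixed condition coefficient with a Wald p. Subjects observed in only
one condition cannot identify a within-subject difference, so a purely
between-subject table is rejected. In balanced designs the estimate
equals the mean of within-subject differences exactly, regardless of the
variance estimates. Across features, Benjamini–Hochberg FDR is reported.

## Pipeline (`pairedqtl.pipeline`)

Stage order: load/align (samples intersected by ID across all inputs;
extras dropped with a logged count) → SNP QC → optional quantile
normalization + covariate residualization → cis scan + probe-level FDR
per cell type → cis correction → trans scan on the configured candidate
SNPs + FDR → cross-cell-type π1 → joint BMA → optional colocalization,
methylation correlation and mediation. Every stage writes TSV/JSON
artifacts under `out/<stage>/`; the manifest (config snapshot, stage
statuses, artifact SHA-256 checksums) is written even on failure, and a
failed stage stops everything downstream. TSV dialect: tab separator,
mandatory header, sample IDs first, `.` for missing.

## Problem sizes used in tests

The suite exercises cohorts of 50–1000 probes, 10–500 SNPs and 50–500
samples, 20–1000 permutations, and the full 1000 × 1000 mediation study;
these sizes keep each estimator in the regime where its Monte-Carlo error
is small relative to the assertion tolerances (e.g. the π0 tail estimator
needs ~10³ probes and ~10³ permutations before ±0.1 recovery is reliable,
because permutation reuse across probes inflates the tail variance and
the discrete p-values shift it by ~1/B).

## Known limitations

No LD simulation or LD-aware fine-mapping; two cell types only in the BMA
configuration set; single-causal-variant colocalization; no latent-factor
expression correction beyond explicit covariates and optional expression
PCs; HWE on strongly imputed dosages is skipped rather than tested
exactly; X-chromosome conventions are out of scope (autosomal analysis).
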