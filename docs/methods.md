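# Methods

## The estimand and the generative model

The package estimates the joint genetic architecture of T traits from
GWAS summary statistics alone. The objects of interest are the T×T
genetic covariance matrix S (heritabilities on the diagonal, genetic
covariances off it, cross-ancestry cells on the effect-correlation
scale times √(h²_t h²_u)), its sampling covariance V, and a latent
factor decomposition of the standardized S.

The synthetic generator defines the study conditions and draws
Z-scores directly from the LD score regression moment conditions: for
variant j, independently across variants,

    Cov[z_t, z_u] = √(N_t N_u) · ℓ_j(t,u) · S[t,u] / M + δ(t,u)

with δ = 1 on the diagonal, ρ_ph·N_s/√(N_t N_u) for overlapping
within-population pairs, 0 across populations. S itself comes from a
latent factor model S_corr = ΛΨΛᵀ + Θ (unit diagonal enforced), scaled
by per-trait h², with cross-ancestry cells attenuated by ρ_ge.

Sampling the moment model directly — rather than simulating genotypes
— makes LDSC consistent by construction, so parameter-recovery tests
are sharp. What this deliberately does *not* emulate: dependence of
Z-scores *between* variants (real LD induces it; here variants are
independent across and within blocks given the scores), minor-allele
frequency structure, imputation error, selection or stratification.
Consequently, passing recovery tests demonstrates correctness of the
estimators under the moment model, not robustness to every
real-data pathology; the jackknife coverage tests should be read the
same way.

## LD block design

The reference genome is n_blocks independent blocks of m variants with
intra-block genotype correlation r per population, giving closed-form
LD scores 1 + (m−1)r² within and 1 + (m−1)r1·r2 across populations. A
*uniform* r would make every LD score identical — a design in which a
free-intercept LDSC regression is unidentifiable — so r may be (and in
the presets is) a per-block array: the default grid spans r1 ∈
[0.05, 0.50] and r2 ∈ [0.10, 0.45] over 200 blocks of 100 variants
(M = 20,000), giving LD scores from ~1 to ~26 and a well-conditioned
regression. Blocks double as jackknife resampling units, which is
exact here because variants are independent across blocks.

Default study conditions (the `fourfactor9` preset): nine traits in
two ancestries, four correlated factors including one small negative
cross-loading (−0.25), h² = 0.4 and N = 50,000 per trait, no sample
overlap, ρ_ge = 1. The h²/rg/ρ_ge recovery scenarios use the same
M, N, h² with one or two traits, 30% overlap with ρ_ph = 0.3 where
overlap is the point, and ρ_ge ∈ {0, 0.6, 1}.

## LDSC estimation

Univariate: χ² on ℓ with a free intercept (constrainable to 1).
Bivariate: z_t z_u on ℓ with the intercept free within a population
(it absorbs overlap, expectation ρ_ph·N_s/√(N_t N_u)) and fixed to 0
across populations. Weights follow standard two-step practice: an
unweighted pass gives provisional estimates, then one reweighting with
1/(ℓ_j μ_j²) where μ_j is the provisional regression mean (for pairs,
1/(ℓ_j(μ_t μ_u + μ_tu²))); the provisional means are cached so that a
trait paired with itself reproduces the univariate regression exactly
(self-rg = 1 to machine precision). Denominators are floored (μ ≥
0.05, ℓ ≥ 1) for numerical safety. No maximum-ℓ truncation is applied
by default.

Standard errors come from a delete-one-block jackknife with the final
weights held fixed; delete-one estimates of every cell are retained.
rg and ρ_ge jackknives normalize each deletion's ρ_g by that
deletion's own h² values, so ratio noise propagates into the SE.

## S, V and standardization

All t* = T(T+1)/2 cells are estimated on one common block map; V is
the jackknife covariance of the delete-one cell vector, capturing
cross-cell sampling dependence (shared samples, shared variants).
vech ordering is column-major over the lower triangle. With T = 1 the
construction reduces exactly to the squared univariate jackknife SE.

Standardization divides cell (i,j) by √(S_ii S_jj). Two V rescalings
are provided. `v_method="fixed"` treats the scale factors as known and
multiplies V entries by the corresponding factors — simple, but it
ignores that h² noise partially cancels in the ratio rg = ρ_g/√(h²h²);
in calibration runs it overstated some loading SEs by ~25%.
`v_method="jackknife"` (the pipeline default) instead re-standardizes
every delete-one S by its own diagonal and takes the jackknife
covariance of that vector; diagonal cells — identically 1 in every
deletion — are given the fixed-factor scaling of the h² deletions so
DWLS weights stay finite. Being a genuine jackknife covariance this V
is positive semidefinite by construction, and it brings the empirical
SD / mean-SE ratio of every fitted loading into [0.92, 1.08] over 200
replicates.

PSD smoothing (`smooth_to_psd`) clips eigenvalues below ε = 1e−6 up to
ε, reconstructs, and re-normalizes the diagonal when the input was a
correlation matrix; it is applied to S_corr immediately before factor
analysis only, and the maximum elementwise change is logged.

## Exploratory factor analysis

Principal-axis factoring with iterated communalities (SMC start,
tolerance 1e−6, ≤100 iterations) followed by varimax and a power-4
promax oblique rotation. Maximum-likelihood EFA is avoided on purpose:
no sample size is well defined for a jackknifed genetic correlation
matrix, and principal-axis factoring needs only the matrix. Rotational
indeterminacy is resolved canonically (factors ordered by descending
squared pattern loadings; each factor's largest-|loading| made
positive). Heywood cases (communality > 1) are flagged, not fatal.

The k-scan reports, per k, the fraction of genetic variance explained
(mean communality under the oblique solution), cross-loading counts
above 0.3, Heywood flags and a parsimony score: variance explained
minus 0.02 per factor. The penalty sits between the measured
communality gain of adding a genuine factor (~0.03 on the preset) and
that of an overfactored solution (~0.007); an earlier score based on
pattern-loading sums of squares with a cross-loading penalty did not
discriminate (pattern SS barely grows with k under promax, and true
structures may legitimately contain cross-loadings). The scan is
advisory; nothing auto-commits to a k. Reports display loadings at
|λ| ≥ 0.25; estimation is unthresholded.

## Confirmatory SEM

Models are declared in a small text grammar (factors with indicator
lists, free factor covariances via `covary`, fixed loadings via `fix`,
plus a `saturated` keyword); identification fixes factor variances at
1, residual variances are free. DWLS minimizes the
diag(V)⁻¹-weighted discrepancy using trust-region least squares with
internally normalized weights (the objective is scale-invariant in the
weights; normalization keeps it O(1)). Multi-start: an EFA-informed
start (EFA columns matched to declared factors through the loading
pattern) plus jittered restarts with fixed seeds; the minimum-objective
solution is returned and non-convergence of all starts is an error
carrying best-so-far diagnostics. Tolerances: xtol/ftol 1e−14, gtol
1e−12; on noiseless inputs the generating parameters are recovered to
machine precision, and the optimizer's first-order optimality is
recorded on every fit.

Negative residual variances are allowed and flagged by default (small
non-significant negative residuals are routine for genetic correlation
matrices); a bound-at-zero option exists. Standard errors use the
sandwich with the full V and a central finite-difference Jacobian
(step 1e−6, cross-checked against forward differences; rank deficiency
reports the aliased parameters). P-values are two-sided normal; a
one-sided report option exists for directional loading hypotheses.

Fit: χ² = (s−σ̂)ᵀV⁺(s−σ̂) with df = t*−q (V⁺ is the Moore–Penrose
pseudo-inverse; condition numbers above 1e12 are warned about — the
quadratic form is asymptotically χ²_df because V is the sampling
covariance of s; the residual-space projection subtlety is accepted
as in standard practice). The independence baseline frees only the
diagonal, so its DWLS solution matches the diagonal moments exactly.
CFI is clamped to [0,1]; SRMR averages squared residuals over the
lower triangle including the diagonal; AIC = χ² + 2q, and model
comparison sorts by AIC with ties broken toward fewer parameters.

## Harmonization and QC

Effect alleles are aligned to a declared reference: swapped alleles
negate Z, strand flips are complemented, strand-ambiguous variants
(A/T, C/G) are always dropped — no allele-frequency reference is
assumed — and irreconcilable records are removed; every removal is
counted. Harmonization is idempotent. QC defaults are conventional
(MAF ≥ 0.01 and INFO ≥ 0.9 when the columns exist, χ² ≤
max(80, 0.001·N)), all configurable. One scale caveat: the χ² cap is
calibrated to genome-scale variant counts (~10⁶); at the preset's
M = 20,000 the same total heritability concentrates ~50× more
association per variant and the cap would truncate genuine signal
(measured: h² biased from 0.40 to 0.33). Pipeline runs on synthetic
scenarios therefore default to no cap, while external-input runs keep
the conventional default.

Variant ordering is lexicographic by id everywhere (the generator
zero-pads ids so lexicographic order is genomic order); jackknife
blocks are contiguous runs in that ordering unless a block map is
supplied.

## Problem sizes and determinism

Recovery and calibration runs use the study conditions above with 50
seeds (means), 200 replicates (coverage and SE calibration) and 20
replicates (model selection); one full nine-trait replicate — 20,000
variants, 45 jackknifed cells, DWLS fit with sandwich SEs — takes on
the order of 0.1 s, the complete acceptance script about half a
minute. All randomness flows from named integer seeds; regenerating
with the same seed is bit-identical, and the pipeline manifest hashes
every artifact so identical configurations reproduce identical hashes.

## Known limitations

- Summary statistics are simulated at the moment level; between-variant
  dependence, MAF/imputation structure and stratification are out of
  scope, as are genotype-level simulation and liability-scale h².
- The trans-ancestry estimator is a method-of-moments regression (the
  effect-correlation estimand); a full likelihood treatment and the
  allele-frequency-weighted (impact) variant are not implemented.
- Partitioned (annotation-stratified) LDSC, latent-factor GWAS,
  SNP-level heterogeneity statistics and multi-group SEM are not
  implemented.
- Standardization treats the correlation-scale diagonal as having the
  fixed-factor sampling variance; the exact sampling law of "exactly 1
  by construction" cells is degenerate and any finite weight for them
  is a modeling choice.
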