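# Methods

## The estimand and the instrumental-variable design

`cismr` implements two-sample summary-data Mendelian randomization restricted
to a cis gene region. The exposure X is a continuous biomarker (standardized
CRP in the motivating analysis), the outcome Y a binary disease analysed on
the log-odds scale. For a set of m variants the inputs are marginal
association estimates βX ± σX (variant → exposure) and βY ± σY
(variant → outcome) from two non-overlapping GWAS, plus the signed LD
correlation matrix R among the variants from a reference panel.

Under the three IV assumptions (relevance, exchangeability, exclusion
restriction), each valid instrument identifies the same causal effect θ
(outcome log-odds per unit exposure) through the ratio βY_j = θ·βX_j.
Restricting instruments to the window around the target-encoding gene makes
the exposure association biologically proximal and lowers the risk of
horizontal pleiotropy; it also concentrates instruments in one LD block, so
correlation between instruments must be modelled explicitly.

## Estimators

**Wald ratio** (single instrument): θ̂ = βY/βX. The default first-order
delta-method SE is σY/|βX|, the convention in two-sample MR, which ignores
the (here comparatively tiny) exposure-side uncertainty; a second-order SE
sqrt(σY²/βX² + βY²σX²/βX⁴) is available via `se_order="second"`.

**Correlated-instrument fixed-effects IVW (GLS).** The model βY = θ·βX + ε,
cov(ε) = Ω with Ω_kl = σY_k σY_l R_kl, gives the generalized least-squares
estimator through the origin:

θ̂ = (βXᵀ Ω⁻¹ βY) / (βXᵀ Ω⁻¹ βX),  se(θ̂) = (βXᵀ Ω⁻¹ βX)^(−1/2).

This is the fixed-effects form (no overdispersion multiplier). With R = I it
reduces algebraically to classical IVW, Σ(βX βY/σY²)/Σ(βX²/σY²); with m = 1
it collapses to the Wald ratio with first-order SE. Ω⁻¹ is never formed:
both quadratic forms come from one linear solve. If Ω's smallest eigenvalue
is ≤ 1e−10 of its largest the estimator aborts with the condition number and
points to PCA-IVW, since near-collinear instruments make the dense GLS
numerically meaningless.

**PCA-IVW.** Build the weighted correlation matrix
Ψ_kl = βX_k βX_l R_kl/(σY_k σY_l), take its eigendecomposition, and retain
the smallest k whose cumulative eigenvalue fraction reaches the variance
threshold (default 0.99). Project W = first k eigenvectors: β̃X = WᵀβX,
β̃Y = WᵀβY, Ω̃ = WᵀΩW, then apply the GLS above in the projected space.
Components with eigenvalue below 1e−10 of the largest are never retained
regardless of the threshold — they carry no signal and amplify noise. At
threshold 1 on a full-rank Ψ the estimator equals the GLS exactly; on an
exactly duplicated instrument it reproduces the deduplicated analysis, which
the test suite checks against a dense-inverse oracle.

**Reporting.** All estimates are exponentiated to an odds ratio with a
normal-theory CI, exp(θ̂ ± z·se), and a two-sided normal p-value. The default
direction is per SD *increment* of the exposure; `invert_direction` reports
the inhibition (decrement) framing as 1/OR with the CI bounds swapped.

A noteworthy qualitative behaviour, exercised in the tests: with strongly
positively correlated instruments the GLS point estimate can land on the
opposite side of the null from every per-variant Wald ratio. This is not a
bug — GLS weights contrasts between correlated instruments, and those
contrasts can dominate when the ratios differ — but it means multi-instrument
results in tight LD blocks are sensitive to the signed LD values used.

## Harmonization

The exposure table's effect allele is the reference orientation. Outcome
records with swapped ea/nea (directly, or after strand complementation) have
β negated and eaf complemented; palindromic variants (A/T, C/G) are aligned
by allele frequency when both minor-allele frequencies are below 0.42
(configurable) and dropped as uninformative otherwise; irreconcilable allele
pairs and variants absent from the LD matrix are dropped. Every shared
variant receives exactly one logged action (kept / flipped / dropped +
reason), so the log partitions the shared set and silent drops cannot occur.

The LD matrix is taken to be aligned with the exposure's allele coding
(`ld_aligned_to="exposure"`), the natural convention when the panel alleles
were matched to the exposure GWAS; `ld_aligned_to="outcome"` instead negates
the signed r of flipped variants' rows and columns. Harmonization is
idempotent, and flipping an input record's alleles (with β negated and eaf
complemented) leaves the harmonized vectors unchanged.

## Instrument selection

Selection applies, in order: cis-window restriction (1-based inclusive
[start − flank, end + flank]; default window chr12:6,437,923–6,451,280 with
flank 1,000 bp), p < 5×10⁻⁵ (strict), greedy LD clumping at r² < 0.001
(strict), and F = (β/se)² > 10 (strict). Clumping ranks by ascending p-value
with ties broken by smaller position then lexicographic rsid, so the result
is deterministic and invariant to input row order. Literature-based
instrument sets (such as the three-variant secondary set rs767455,
rs4149570, rs4149577, chosen for precedent rather than by the algorithm) are
expressed as an explicit `instrument_list` override, not as a selection
rule.

## The synthetic-data generator

`synth_gwas` adopts the standard two-sample summary-statistics model — the
model under which the implemented estimators are derived:

- joint variant → exposure effects γ ~ N(0, gamma_sd²) i.i.d.;
- marginal exposure effects βX = R·γ (LD convolution);
- direct variant → outcome effects α ~ N(0, pleiotropy_sd²), zero spread
  meaning valid instruments;
- marginal outcome effects βY = θ·βX + R·α, generated directly on the
  log-odds scale (no individual-level logistic simulation — the estimators
  consume log-odds betas, and direct generation keeps the noise model exact);
- reported SEs follow the standardized-trait large-sample law
  se = 1/sqrt(2·n·p·(1−p)); for the binary outcome an optional case fraction
  φ multiplies the denominator by φ(1−φ) (logistic score variance), which at
  the default n = 45,563 and φ = 17,353/45,563 reproduces outcome SEs of
  ~0.014, the order observed at these study sizes;
- observed effects add noise_scale × MVN(0, D·R·D) noise with D = diag(se),
  the covariance of marginal estimates computed on one sample.

Defaults are the motivating study's conditions: n_exposure = 575,531,
n_outcome = 45,563 with the case fraction above, eaf ~ U(0.1, 0.9),
gamma_sd = 0.02 (the order of the strongest cis associations with CRP,
giving mostly strong instruments at these sample sizes), pleiotropy_sd = 0,
noise_scale = 1. The exposure is treated as an arbitrary standardized trait;
whether the source betas are in SD units of raw or log-transformed CRP is
immaterial to the machinery and left unspecified.

The genotype-panel sampler draws two latent Gaussian haplotype vectors per
individual and thresholds them at Φ⁻¹(eaf). The latent correlation is
calibrated per pair by inverting the tetrachoric relationship so the
*genotype* correlation matches the requested signed r (raw latent-r
thresholding attenuates correlations); targets beyond the frequency-imposed
bound on allele-count correlation saturate with a warning. The calibrated
matrix is eigenvalue-clipped back to a correlation matrix before sampling.

What the generator does **not** emulate: the real CRP/periodontitis genetic
architecture, case-control ascertainment, sample overlap between studies,
population stratification, or allele-frequency differences between the two
samples. Passing tests therefore demonstrate correctness of the statistical
machinery under the model's assumptions, not robustness to those real-data
complications.

## Validation design and problem sizes

Deterministic algebraic identities (GLS vs closed-form IVW, PCA-IVW at full
variance, single-instrument collapse) are checked to 1e−12/1e−8 relative.
Brute-force oracles — explicit-inverse GLS and an exhaustive simulation of
the greedy clumping rule — are compared on 200 random problems each (m ≤ 6
and ≤ 10 respectively). Monte-Carlo calibration uses 500 replicates of a
3-instrument study (uniform r = 0.84, θ = 0.3, defaults otherwise): the mean
estimate must fall within 3 Monte-Carlo SE of θ and empirical 95% CI
coverage within [0.93, 0.97], the binomial band at 500 replicates. These
sizes keep the whole suite in seconds while leaving the checks sharp.

## Numerical and design choices

- Thresholds are strict inequalities exactly as configured.
- p-values from the normal approximation are floored at 1e−300 to stay in
  (0, 1].
- The published-table fixture uses placeholder positions and alleles inside
  the gene window and a placeholder LD matrix (rs1800693 uncorrelated with
  the trio; uniform signed r = +0.84 within the trio, the positive square
  root of the reported r² ≈ 0.7), because none of these are published. The
  secondary analysis is therefore validated structurally (oracle agreement,
  estimator equivalences, calibration), never against the published
  secondary odds ratios, which depend on the exact signed panel LD.
- On the fixture's placeholder LD, purely statistical selection retains two
  variants (the lead variant plus the best trio member); the published
  single-variant retention relied on the true panel LD. The primary and
  secondary layouts are therefore two `instrument_list` configs sharing
  inputs.
- If only r² is available, `LdMatrix.from_tsv(..., assume_positive_ld=True)`
  converts via the positive square root with a prominent warning — sign
  errors in LD change GLS estimates, so supplying true signed r is strongly
  preferred.

## Limitations

- Fixed-effects only; no overdispersion/random-effects multiplier, and no
  MR-Egger, weighted-median, or colocalization-style sensitivity analyses.
- First-order Wald SEs understate uncertainty when the instrument is weak;
  the F > 10 screen is the guard, and the second-order SE is available.
- No VCF/GWAS-VCF input, no genome-build liftover, no multi-allelic
  variants.
- CI coverage statements assume the supplied LD matrix is the truth; a
  mis-specified or unsigned LD matrix propagates directly into the GLS
  estimate and its SE.
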