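# Methods

## Relatedness

Genotypes are integer codes — diploid 0/1/2 copies of the reference
allele, haploid 0/1 reference-homozygote indicators.  Reference-allele
frequencies are estimated from the sample (`p̂ₗ = Σzᵢₗ/(kn)`, k the allele
copies per locus), and markers are standardized to zero mean and unit
variance in the GCTA/VanRaden coding,
`wᵢₗ = (zᵢₗ − kp̂ₗ)/√(kp̂ₗ(1−p̂ₗ))`.  Monomorphic markers have no defined
scale and are dropped with a logged warning rather than imputed; missing
genotypes are a read-time error (the intended datasets are complete; a
silent mean-impute would bias the pair indexes).  The marker GRM is
`Θ̂ = WW′/m`, symmetrized by averaging with its transpose to remove
floating-point asymmetry.  The theoretical AR1 matrix has
`θᵢⱼ = θₐ^|i−j|` and is positive definite for |θₐ| < 1.

Agreement between a marker GRM and a theoretical one is summarized by the
Pearson correlation of their strict lower triangles.  The diagonal is
excluded: the theoretical diagonal is the constant 1 and would contribute
zero-variance points.  The correlation is accumulated in one row-wise
pass so no n(n−1)/2 index arrays are materialized (n = 10⁴ remains cheap).

## Pair indexes

Pairs are ordered by stacking the columns of the strict lower triangle
(Vech order).  With grand-mean centering, three identities hold exactly
and are asserted in tests: `Σs = −(n−1)S²/2`, `Σd = n(n−1)S²/2`, and
`mean(d) + mean(s) = S²(n−1)/n`, with `S²` the divisor-(n−1) sample
variance.  `d` is the **half** squared difference so that its expectation
is `σ²ₚ − θσ²ₐ` with slope exactly −σ²ₐ; the raw squared difference used
in some of the older literature is available through
`pair_table(..., half_difference=False)`, under which the intercept
estimates 2σ²ₚ.  The standardized similarity divides by the plug-in
divisor-(n−1) phenotypic variance and is undefined (None) for a constant
trait.  Centering uses the grand mean only — no other fixed effects occur
in any in-scope analysis — and is redone inside every bootstrap resample.

## Binned regression

The relatedness range is split into equal-width bins (default 1000).  The
default range is data-driven `[min θ̂, max θ̂]` because standardized GRMs
routinely contain negative and >1 entries; a `unit` mode covers the
conventional [0, 1] with outliers clipped into the end bins.  Interior
edge ties are assigned upward; the global maximum falls into the last bin
(half-open intervals, final bin closed).  Bin means are computed from the
actual (unclipped) values.  Empty bins are excluded from the fit, which
is plain unweighted OLS with a free intercept — the intercept is reported
as a diagnostic of the "no shared environment" assumption rather than
forced to zero.  Weighted least squares over bins was considered and
rejected: the pair distribution is strongly concentrated near zero
relatedness, and count-weighting hands those bins almost all the
influence, reproducing the un-binned fit's drawbacks.

Binning leaves an exactly affine index/relatedness relationship invariant
(any bin count, either range mode — a property test), but on noisy data
the equal weighting of sparse tail bins adds replicate-level noise
relative to the un-binned fit: at n = 2000 the two differ by ±0.1 on
single replicates while sharing the same center.  The un-binned
(classical) estimator is retained both as a reference and because on the
raw pair scatter the covariance-model and difference-model slopes agree
essentially exactly; the package asserts their agreement within
0.05·σ²ₚ at n = 2000.

Heritability for the covariance model is taken from the standardized-index
regression; because the bins depend only on θ̂, it must equal the
σ̂²ₐ/σ̂²ₚ route to round-off, and the implementation asserts the two routes
agree to 1e−10.  Estimates are never clamped: at small n and high h²,
individual replicates legitimately exceed 1.

## REML baseline

The single-GRM mixed model is fitted by profiling the restricted
likelihood: one symmetric eigendecomposition `Θ̂ = UΛU′`, rotation of the
trait and intercept column, closed-form generalized-least-squares
intercept and total-variance profiles, and bounded scalar optimization of
h² on [0, 1] (tolerance 1e−8).  This has the same optimum as the
average-information iterations used by the standard GREML tools for the
one-component model, without their iteration schedule.  Eigenvalues below
1e−8 are clipped (rank-deficient marker GRMs with m < n always carry
round-off negatives of order 1e−14; only a materially negative spectrum
logs a visible warning).  A flat spectrum (e.g. Θ̂ = I) makes the
genetic/residual split unidentifiable; the fit is then reported at the
zero boundary with `identifiable=False`, never at an arbitrary interior
point.  Boundary solutions set `at_boundary`; components are non-negative
by construction.  A dense-matrix oracle (explicit inverses, `slogdet`,
grid search plus refinement, n ≤ 200) exists for cross-validation and
agrees with the spectral route to 1e−6 in both optimum and likelihood.

## Simulator

The population covers the full relatedness spectrum through a stationary
AR1 model over ordered individuals.  Latent marker vectors follow
`z₁ ~ N(0, I)`, `zᵢ = θₐ zᵢ₋₁ + √(1−θₐ²) εᵢ` — the unique linear
recursion with standard-normal marginals and nearest-neighbour
correlation θₐ (default 0.95, emulating closed breeding populations with
a handful of founders).  Latents are trichotomized at ±0.67449 (the
standard-normal quartiles) into 0/1/2 with expected frequencies 1:2:1;
boundary values, a measure-zero event, go upward.  A fraction (default
10%) of markers is causal, drawn uniformly without replacement.

Genetic effects are `a = √h² · W_c u_c/√m_c` on the standardized causal
genotypes.  The default scaling (`effect_scaling="norm"`) rescales the
i.i.d. standard-normal `u_c` to unit mean square.  This choice is
deliberate: it fixes σ²ₐ = h² over the genotype distribution while
letting the realized genetic variance vary only through genotype
sampling, so the realized-heritability spread is independent of the
causal count and shrinks with n — at small n the realized mean sits a few
percent *below* h², because the sample variance of positively correlated
effects is shrunk by E[S²] = σ²(1−ρ̄).  Leaving `u_c` i.i.d.
(`"expectation"`) adds a χ²(m_c) fluctuation of ‖u_c‖² that dominates at
small causal counts; forcing the realized variance to h² exactly
(`"exact"`) removes genetic sampling variation altogether.  Both
alternatives are available behind the same flag.  Residuals are i.i.d.
N(0, 1−h²); the phenotypic variance is 1 by design, h² = 0 zeroes the
genetic vector and h² = 1 the residuals.  Realized heritability is
`var(a)/(var(a)+var(e))`, divisor n−1 throughout.

Estimation always uses the all-marker GRM (causal plus irrelevant) —
mirroring practice, where causal variants are unknown.  One consequence,
visible in replicate summaries, is that heritability estimates at small n
run slightly above the realized values: the causal markers are part of
the GRM, so GRM noise is partially shared with the trait's genetic
structure.  A second, distinct gap separates latent and genotype scales:
thresholding attenuates the latent correlation (≈0.95 → ≈0.89 between
neighbours), so quantities defined on the genotype scale (realized
heritability, GRM elements) are systematically a few percent closer to
zero than their latent counterparts.

Replicated cells (`run_sim_cell`) report, per estimator: mean, SD, the
90% range as the 5th–95th percentiles (linear interpolation), and a
two-sided one-sample t-test of the replicate mean against the true h² at
α = 0.05.  Replicates are seeded by spawning a `SeedSequence`, making
cells bit-reproducible; a fixed `SimConfig` seed makes a single replicate
bit-reproducible end to end.

## Bootstrap

Resamples draw n individuals with replacement and keep the unique ones
(expected fraction 1−e⁻¹), so a resampled GRM is never singular for the
likelihood baseline; the GRM is sub-set, not recomputed from genotypes.
Regression estimates are not truncated at zero — negative CI bounds are
meaningful for weak signals — while REML estimates remain
boundary-constrained.  Failing resamples are skipped with a warning; more
than 50% failures aborts.  Defaults: B = 1000, percentile 95% CI.

## Problem sizes and what the tests show

The validation suite replicates heritability-recovery cells at
(h², n, m) up to (0.5, 1000, 2000) and (0.8, 5000, 200) with 100 and 25
replicates respectively, single-population GRM-accuracy checks up to
n = 10⁴ at m = 200 and n = 2000 at m = 2×10⁴, and GRM-concentration at
n = 5000, m = 2000 — sizes chosen so the whole suite completes in a few
minutes on one core.  The generator emulates AR1-structured relatedness
with independent, equifrequent markers; it does not model linkage
disequilibrium, allele-frequency spectra, selection, non-additive
(dominance/epistatic) variance, or shared-environment covariance, so
passing tests demonstrate correct recovery under the stated additive
model, not robustness to those realities.  Known limitations: the pair
table materializes n(n−1)/2 vectors (the binned fit itself is O(bins),
but table construction is the memory bound — fine to n ≈ 2×10⁴ in 8 GB);
the bootstrap's duplicate-exclusion makes resample sizes ≈ 0.63n, which
slightly widens its intervals relative to a classical bootstrap.
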