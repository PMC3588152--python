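# Methods

## Model and assumptions

The package treats species abundances as jointly stationary random
variables: each species fluctuates around a fixed temporal mean with a
fixed variance, and each pair has a fixed covariance. A community is
therefore fully described for our purposes by the pair (**m**, **V**) —
the mean-abundance vector and the variance–covariance matrix — and every
statistic is a function of these moments. No dynamical model (density
dependence, interactions, environmental forcing) is assumed; conversely,
any community-dynamic model that reaches a stochastic equilibrium can be
analysed through its long-run moments with the same estimators.

Three layers build on the moments:

1. **Estimators.** The synchrony index φ = v_c/(Σ√vᵢᵢ)² with
   v_c = ΣΣvᵢⱼ; the community CV √v_c/M; the abundance-weighted mean
   species CV Σ√vᵢᵢ/M; the unweighted mean pairwise correlation ρ̄; the
   Smith–Wilson evenness E_var = 1 − (2/π)·arctan(var(ln m)) (population
   1/n variance, natural logs); and an OLS log–log fit of Taylor's power
   law v = a·mᵇ. The identity CV_c = √φ·CV̄_s is algebraically exact and
   is enforced in tests at 1e−12 relative tolerance.
2. **Closed-form theory.** With v = a·mᵇ and m = m₁/nˣ the weighted CV
   factorises as n^{x(2−b)/2}·√a Σm₁^{b/2}/Σm₁; the first factor (the
   mean-abundance effect) carries all diversity dependence of population
   variability. With equal variances, φ = (1 + (n−1)ρ̄)/n. Both identities
   are verified as round-trip property tests: moments constructed from the
   scaling laws reproduce the closed-form community CV to 1e−10 relative
   over randomised sweeps up to n = 32.
3. **Simulator.** Synthetic communities for studying evenness effects,
   described below.

## Parameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| a | Taylor coefficient (abundance^(2−b)) | 1 | scale-free baseline; only rescales CVs |
| b | Taylor exponent | 2 | CV independent of mean; the pivot between stabilising/destabilising regimes |
| x | overyielding exponent | 0 | species means independent of richness; x<1 = overyielding, x>1 = underyielding |
| μ | mean of log abundance | 1 | lognormal pool location (units of log abundance) |
| σ | SD of log abundance | 1 (experiments sweep 0–3) | controls unevenness; σ=0 is a perfectly even pool |
| pool_size | species pool | 256 | comfortably exceeds the largest richness (64) so random subsets stay diverse |
| replicates | gradient replicates | 200 | smooth mean curves at desk scale |
| richness grid | n values | 1,2,4,8,16,32,64 | log-spaced, matching the log axis on which DSRs are conventionally drawn |

## Simulator design

Mean abundances are drawn lognormal, exp(Normal(μ, σ)). Variances follow
Taylor's law. Correlation matrices are drawn by giving each of the
n(n−1)/2 angles of the hyperspherical (Cholesky-angle) parameterisation an
independent uniform value on [0, π]; the resulting lower-triangular factor
has unit-norm rows, so the product is a valid correlation matrix for *any*
angles, and by symmetry the expected mean pairwise correlation is zero at
every richness and evenness. (This is not the uniform distribution over
the elliptope of correlation matrices; it is the construction whose
zero-mean-correlation property the evenness experiments rely on.)

Gradient summaries are computed *analytically* from the constructed
moments — the experiment questions concern population-level quantities,
so adding finite-series noise would only blur them. An optional
`timeseries_length` switches to plug-in estimation from simulated series.
Time series are i.i.d. multivariate Gaussian across time: the framework
constrains only the stationary first and second moments, and temporal
autocorrelation is a documented extension point, not implemented.
Gaussian marginals can go negative at individual time points; values are
not clipped by default because truncation biases the moments (a
`clip_zero` flag exists for display purposes). Sample *means* must still
be positive or moment estimation refuses the series.

Assembly of an n-species community from the pool is, by default, a fresh
uniform random subset per (replicate, richness) — richness levels are not
nested within a replicate, since either convention is defensible; a
`nested=True` flag gives nested subsets. Ordered assembly
(`ordered_increasing` / `ordered_decreasing`) adds species by rank of mean
abundance, mimicking successional gradients. Seeding uses one master
`SeedSequence` that spawns an independent stream per (replicate,
richness), so results are reproducible and independent of evaluation
order.

What the generator does *not* emulate: temporal autocorrelation and
non-stationarity (transient dynamics following assembly), non-Gaussian
abundance fluctuations, species-specific Taylor exponents or overyielding
responses, and any mechanistic interaction structure. Passing tests
therefore demonstrate the internal consistency of the statistical
framework and the behaviour of its estimators under the stated sampling
models — not that real communities obey the scaling laws.

## Numerical choices

- Covariance matrices are accepted as PSD when the smallest eigenvalue is
  ≥ −1e−8 × the largest; asymmetry below 1e−10 relative is averaged away,
  larger asymmetry is an error naming the offending quantity.
- φ values overshooting [0, 1] by ≤ 1e−9 (floating-point rounding of the
  ratio) are clamped; larger overshoot raises, since it indicates an
  invalid matrix rather than rounding.
- The mean pairwise correlation is bounded by the equicorrelation PSD
  constraint −1/(n−1) ≤ ρ̄ ≤ 1; the closed form and the equicorrelation
  constructor both enforce it.
- Sample covariance uses denominator T − 1 (unbiased); at least 3 time
  points are required.
- Taylor fitting drops zero-variance species with a warning when at least
  3 positive pairs remain, and is OLS on natural-log axes via
  `scipy.stats.linregress`.
- Gaussian series use an eigendecomposition square root with tiny negative
  eigenvalues floored at zero, so exactly singular covariances (perfect
  synchrony or asynchrony, zero variance) simulate without jitter.

## Open design choices

- The monoculture means used by the CV decomposition are explicit inputs:
  inverting the overyielding law from mixture data is not well posed
  without knowing x, so no inference is attempted.
- ρ̄ is the plain unweighted mean of the distinct pairwise correlations —
  deliberately the naive estimator that φ is designed to improve upon.
- Experiment drivers default to ρ̄ curves {perfect synchrony, 0.7, 0.1, 0,
  perfect asynchrony}, Taylor exponents {1.5, 2, 2.5}, overyielding
  exponents {−0.5, 0, 0.5, 1, 1.5}, σ levels {0, 0.5, 1, 2} for the
  synchrony panel and the (x, b) cross {0, 0.5, 1} × {1.5, 2.5} at σ = 2
  for the interaction panel — one representative value in every
  qualitatively distinct regime.

## Problem sizes

Property tests sweep randomised communities up to n = 32 (round-trip
identity) and n = 12 (sampler validity); the sampler's zero-mean check
uses 2000 draws at n ∈ {3, 5, 10}; direction checks use 200 replicates
over the grid {2, 4, 8, 16, 32} at σ = 2; parameter recovery uses 30
series of length T = 2000 from a 12-species community. These sizes give
stable Monte-Carlo decisions while keeping the full suite to a few
seconds.

## Known limitations

- φ estimated from finite series is a ratio estimator with O(1/T) bias;
  no bias correction or uncertainty (bootstrap) is provided.
- E_var is reported for the *mean* abundances, not per-time-point
  evenness.
- The closed-form φ applies only under equal variances; for heterogeneous
  variances it is a heuristic, and the package always offers the exact
  moment-based estimator instead.
- Missing data, detrending and non-stationarity diagnostics are out of
  scope; series must be complete.
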