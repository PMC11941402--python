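# Methods

This note documents the models, numerical procedures and design choices
behind `lamldiag`, and what the test suite's green checks do and do not
establish.

## Models and synthetic data

All six families have one scalar latent per observation, so every marginal
likelihood is a product of one-dimensional integrals and every inner
(latent) optimization decouples into scalar problems.

**Errors-in-variables (EIV) regressions through the origin.** The latent
covariate is `x_i ~ T(df)` — a *unit-scale* Student-T; df is 2 for the
normal/Poisson demonstrations and 10 for the binary links, where a T2
latent makes the likelihood too ill-behaved to study.  The measurement is
`w_i | x_i ~ N(x_i, σ₁²)` and the response is Normal(x·β, σ₂²),
Poisson(exp(x·β)), Bernoulli(logistic(x·β)) or Bernoulli(Φ(x·β)).  The
demonstration parameters are β = −1, σ₁ = 3, σ₂ = 2 (the "disagreement
regime") and β = −1, σ₁ = σ₂ = 1 (the "agreement regime").  The latent
scale is taken as 1 because nothing in the model description fixes it
otherwise; the qualitative phenomena do not depend on it, but effect
magnitudes (e.g. how far the Laplace maximizer moves) do.

**Non-identifiable models.** (a) `y_i | x_i ~ Poisson(x_i²)`,
`x_i ~ N(β, 5)` (variance 5): the data identify |β| only, so the exact
likelihood is bimodal at ±β; the demonstration uses β = 2, which puts the
two modes ~1.8 latent SDs apart.  (b) `y_i | μ_i ~ N(μ_i, σ²)`,
`μ_i ~ N(μ, τ²)`: only σ² + τ² is identifiable and the likelihood has a
flat ridge; the demonstration uses μ = 0, σ² = τ² = 1, n = 50.

Simulation is seeded and bit-reproducible; experiment replicate `r` uses a
`SeedSequence(root, spawn_key=(r,))` child seed, so any replicate can be
re-run alone.  One guard in the Poisson simulator: T2 tails occasionally
give means exp(x·β) beyond the integer sampler's range (> 1e12); such
observations are drawn from N(λ, λ), which is indistinguishable from the
Poisson at that scale, with λ capped at exp(700) to stay finite.

## Exact marginal likelihood (the oracle)

Each observation's integral
`∫ f(y_i|x) f(w_i|x) g(x) dx` is computed in log space after locating the
integrand's local maxima by safeguarded Newton ascent from dispersed
starts (the measurement `w_i`, a response-informed point, and — for the
quadratic-mean model — the mirrored start, so both branches of a bimodal
conditional are found).  Panels of `mode ± 12` conditional SDs, plus a
guard region where the observation-level evidence concentrates, are
merged; a panel much narrower than its surroundings (a conditional spike,
e.g. a Poisson observation with a huge count) is kept as its own
subinterval so Gauss–Legendre nodes are never starved.  Default 201 nodes;
the adaptive QUADPACK route over the same windows is the cross-check, and
closed forms (bivariate normal for the all-Gaussian variant, N(μ, σ²+τ²)
for the variance-partition model) pin both to ≤ 1e-8.

The **simple Monte Carlo** estimator averages the conditional density over
draws from the latent prior, with common random numbers across θ so curves
are smooth, and a delta-method SE.  It is only a usable gold standard
where the prior overlaps the conditional mass: for count responses with
|β| well above 1, T2 tails produce observations whose conditional spike
the prior sample misses entirely, and the estimator (including its SE)
breaks down.  Property tests therefore draw |β| ≤ 1.25 — the magnitude of
all demonstrations — for MC-vs-quadrature comparisons.

## The Laplace approximation

`log L* = log f(y, û; θ) + (n/2)·log 2π − ½ Σ log(−H_i(û_i))`, with the
`(2π)^{n/2}` constant included and the determinant taken of −H, so the
approximation is *exact*, not merely proportional, when the conditional
latent law is Gaussian.  Constants cancel in relative likelihoods; the
Gaussian-exactness test and the bias-factor identity need them.

Inner optimization: per-observation safeguarded Newton (backtracking
halving, damped gradient fallback in non-concave regions, escape restarts
if a stationary point with non-negative curvature is reached).  The
acceptance slack of the ascent scales with |f| because the evaluation's
rounding noise does (counts of order 1e6 put ~1e-9 of cancellation noise
into the log joint).  Start policies: `observed_w` (default; latents start
at their measurements, or at moment estimates for the models without w),
`zero`, `custom`, and `multistart` (several dispersed starts, best local
maximum kept, distinct optima counted — the practical red flag for a
multimodal conditional).

Outer MLE: scalar problems use a 25-point grid scan over ±4 on the
unconstrained scale followed by bounded Brent refinement — "multiple
starts, best kept" semantics that deliberately finds the *global* maximum
of the Laplace objective; multiparameter problems use Nelder–Mead from
jittered restarts on log-transformed dispersions.  Wald SEs come from the
central-difference Hessian of log L* at the optimum on the natural scale,
the convention of curvature-based software intervals.

**A consequence worth stating explicitly**: for the Poisson EIV model at
the demonstration parameters, log L*(β) is bimodal in β on essentially
every replicate — global maximum near the true −1, spurious local maximum
near +1.3 to +2.2 (relative likelihood < 1e-3).  Our global-scan fit lands
on the dominant mode, and its Wald intervals then cover at roughly 0.91.
A *local* gradient optimizer started in the spurious basin (e.g. at
β = +0.5) converges there with high confidence and covers the truth 0% of
the time.  Which behaviour a practitioner gets from off-the-shelf Laplace
software depends entirely on starting values and optimizer internals —
the failure mode is real, but whether a given run exhibits it is an
optimizer artifact, not a property of the approximation alone.  The
package demonstrates both regimes; the coverage driver records the fitted
sign per replicate for exactly this reason.

## Bias factor

`b_i = f(û_i | y_i, w_i; θ) · √(2π) · (−H_i)^{−1/2}` is computed two ways.
The exact route evaluates the conditional density through the quadrature
marginal, which turns the definition into the identity
`Σ log b_i = log L* − log L`, asserted to 1e-6.  The MCMC route mimics
what is possible without an oracle: a kernel density estimate of the
conditional latent law (normal-reference bandwidth — no Sheather–Jones
plug-in exists in the installed stack), mode and curvature from a local
quadratic fit to the log-KDE over `mode ± max(bw, 0.35·SD)` with one
vertex-refinement pass, and a block-bootstrap SE.  A LOESS smoother
(statsmodels lowess) is available for plotting the noisy MCMC estimates
against β.

## MCMC, importance ratios, data cloning

All samplers are adaptive random-walk Metropolis: proposal scales tuned
toward ~40% acceptance during burn-in (Robbins–Monro on the log scale) and
frozen afterwards; ≥ 2 chains with dispersed starts; split-R̂ and an
autocorrelation ESS per dimension.  The conditional-latent sampler runs
all n observations as parallel scalar chains.  The data-cloning sampler is
Metropolis-within-Gibbs over (θ, K latent copies), targeting the K-clone
posterior, with N(0, 10²) priors on unconstrained coordinates by default.

The importance-ratio (reference-point) likelihood uses log-sum-exp
throughout and reports `ESS = (Σw)²/Σw²`; curves from multiple references
are anchored at a common grid point and ESS-weight averaged (the averaging
rule is this package's choice; nothing canonical exists).

Identifiability verdicts regress posterior variance on 1/K over the clone
schedule (default K ∈ {1, 5, 20}): fitted asymptote < 10% of the K=1
variance → identifiable; > 50% → non-identifiable; otherwise inconclusive.
The cutoffs are ours; theory supplies only the limits.

## The variance-partition start-sensitivity demonstration

In model (b) the conditional latent law is exactly Gaussian, so the inner
Newton is exact from any start and inner-start pathology cannot arise
here.  The start sensitivity that plagues Laplace software on this model
is reproduced through the genuine ridge mechanism instead: outer fits
started at different variance splits stop at different points of the flat
ridge (all with equal log-likelihood), and the τ² likelihood curves drawn
at those start-dependent fitted nuisance values differ materially — one
looks flat, another looks like a sharp quadratic at the total variance.
None of the fits flags anything wrong, which is the point.

## Coverage study

Per replicate: simulate n = 50, build the 95% interval for β with the
dispersions fixed at truth — likelihood-ratio inversion of the quadrature
likelihood (endpoints by bisection to 1e-4) for the exact-likelihood
column, Wald from the Laplace fit for the LAML column — and record
estimate, endpoints, coverage of β = −1, fitted sign, and failures
(never silently dropped; hits + misses + failures = reps).  Defaults: 500
replicates, with 200 used by the acceptance layer for desk-scale runtime.
A `use_mc_likelihood` switch replaces the quadrature by the literal Monte
Carlo likelihood; at the default M = 20000 its sampling noise visibly
degrades the intervals for the Poisson/T2 configuration (coverage drops
from ~0.94 to ~0.65 in our runs), so results under that switch measure the
MC sample size as much as the model.

## What green tests establish — and what they do not

The generator produces exactly the stated worlds, so green acceptance
checks establish: Laplace exactness in the Gaussian regime; the bias
decomposition; oracle agreement between two independent evaluators; the
parameter-dependence of the bias (agreement at σ₁=σ₂=1, displaced
maximizer at σ₁=3, σ₂=2); calibration of exact-likelihood intervals and
undercoverage of Laplace–Wald intervals for the normal and binary-link
configurations; both non-identifiability pathologies; and data-cloning
recovery of MLE and Fisher information.  They do not establish anything
about real data (no model misspecification, no covariate structure beyond
regression through the origin), and they deliberately do not reproduce
optimizer-artifact failures of specific third-party software: where a
published Laplace failure depends on which local optimum a particular
optimizer finds, this package reports the landscape (both optima, their
relative heights, the 0%-coverage trap) rather than hard-coding one
trajectory through it.

## Known limitations

- Scalar latents only; no random-effect vectors, no sparse-Hessian
  machinery.
- The MC gold standard is prior-sampling; it is kept because it is the
  classical comparator, but the quadrature oracle is the reference.
- The KDE curvature at the mode is noisy at practical chain lengths; its
  bootstrap SE is honest about that (relative errors of ~30-50%).
- Clone-schedule verdicts depend on documented but arbitrary cutoffs;
  "inconclusive" absorbs the boundary.
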