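# lamldiag

Diagnostics for the bias of the **Laplace approximation to the marginal
likelihood (LAML)** in hierarchical models, demonstrated on
errors-in-variables (EIV) regression.

## The problem

Hierarchical models carry a latent variable `u` behind every observation.
Their likelihood is the integral

    L(θ; y) = ∫ f(y | u; θ) g(u; θ) du,

which software such as TMB/glmmTMB replaces by the Laplace approximation

    L*(θ; y) = f(y, û; θ) · (2π)^{n/2} · det(−H(û))^{−1/2},
    û = argmax_u log f(y, u; θ),  H = ∂²/∂u² log f(y, u; θ) |_{û}.

Writing L* = L · b(θ, y), the **bias factor**
`b = f(û | y; θ) (2π)^{n/2} det(−H)^{−1/2}` equals 1 exactly when the
conditional law of the latents is Gaussian.  Whenever `b` *varies with θ*,
the approximation distorts the shape of the likelihood: the maximizer moves,
profile likelihoods are off-centre, and Wald intervals built from the L*
curvature can cover far below their nominal level.  This package measures
those consequences directly, against gold-standard evaluations of the exact
likelihood.

## What is in the box

| module | contents |
|---|---|
| `lamldiag.models` | six model families (Normal/Poisson/logit/probit EIV regression through the origin with a latent Student-T covariate; a sign-non-identifiable quadratic-mean Poisson model; a non-identifiable variance-partition model), their joint log densities, analytic latent derivatives, and seeded simulators |
| `lamldiag.oracles` | exact marginal likelihood by adaptive/fixed-node quadrature, the simple Monte Carlo estimator with common random numbers, likelihood curves, likelihood-ratio intervals, quadrature profile likelihood |
| `lamldiag.laml` | the Laplace approximation (per-observation inner Newton with selectable starting policy), outer MLE with Wald SEs, LAML profile likelihood |
| `lamldiag.mcmc_engine` | adaptive random-walk Metropolis samplers for the conditional latent law and the data-cloning posterior, with split-R̂/ESS diagnostics |
| `lamldiag.geyer_thompson` | importance-ratio likelihood from conditional-latent draws at a reference parameter |
| `lamldiag.data_cloning` | data-cloning MLE and the clone-scaling identifiability diagnostic |
| `lamldiag.bias_diagnostic` | the bias factor per observation — exact, and nonparametrically from MCMC draws (KDE mode density + local-quadratic curvature) |
| `lamldiag.experiments` | end-to-end drivers: likelihood-curve comparison, profile comparison, non-identifiability studies, the confidence-interval coverage study |

A thin CLI (`lamldiag curves|profile|coverage|nonident-quadratic|...`) wraps
the drivers.

## Worked example

```python
import numpy as np
from lamldiag import (ModelSpec, Theta, simulate_dataset,
                      quadrature_loglik, laml_loglik, lr_confidence_interval)

spec  = ModelSpec("normal_eiv", latent_df=2, free_parameters=("beta",))
truth = Theta(beta=-1.0, sigma1=3.0, sigma2=2.0)   # x ~ T2, w = x + N(0,9)
data  = simulate_dataset(spec, truth, n=50, seed=7)

grid  = np.linspace(-2.0, 0.0, 41)
exact = [quadrature_loglik(spec, truth.replace(beta=b), data) for b in grid]
lap   = [laml_loglik(spec, truth.replace(beta=b), data) for b in grid]
print("exact argmax:", grid[np.argmax(exact)])
print("Laplace argmax:", grid[np.argmax(lap)])
iv = lr_confidence_interval(
    lambda b: quadrature_loglik(spec, truth.replace(beta=b), data),
    search_range=(-4, 2))
print("exact 95% CI: (%.3f, %.3f)" % (iv.lower, iv.upper))
```

Output:

```
exact argmax: -0.8999999999999999
Laplace argmax: -1.25
exact 95% CI: (-1.393, -0.545)
```

The Laplace curve peaks at −1.25 while the exact likelihood peaks at −0.90:
at these parameters the approximation relocates the MLE by more than a
third of the exact interval's width.  Re-running with `sigma1=1, sigma2=1`
makes the two curves nearly indistinguishable — the bias depends on the
parameter point, not on the model structure, which is exactly what makes it
dangerous in practice.

## Acceptance script

`scripts/acceptance.py` re-runs the coverage simulation from scratch: for
each model configuration it simulates 200 replicate datasets of size n=50,
builds a 95% confidence interval for β per replicate (likelihood-ratio
inversion of the exact likelihood, or the Wald interval of the Laplace
fit), and writes the observed coverages as JSON:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

Runtime is roughly 10 minutes on one CPU.
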