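"""Random-walk Metropolis machinery shared by the MCMC-based methods.

Two samplers are provided:

* :func:`sample_conditional_latent` targets the conditional law of each
  observation's scalar latent given the data at a fixed parameter value,
  f(x_i | y_i, w_i; theta) — the ingredient of both the importance-ratio
  likelihood and the nonparametric bias-factor estimate;
* :func:`sample_dc_posterior` targets the data-cloning posterior, i.e. the
  Bayesian posterior computed as if the data were observed K independent
  times, pi_K(theta | y) ~ [L(theta; y)]^K pi(theta), sampled jointly with
  the K copies of the latent vector by Metropolis-within-Gibbs.

Proposals are Gaussian random walks whose scales adapt during burn-in
(Robbins-Monro on the log scale, targeting ~40% acceptance) and are frozen
afterwards so the invariant law is untouched.  At least two chains with
dispersed starts are always run: the identifiability diagnostics downstream
rely on cross-chain disagreement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from ._inner import default_starts, newton_ascent
from ._param import from_unconstrained, to_unconstrained
from .models import Dataset, ModelSpec, Theta, log_joint, obs_log_joint

__all__ = ["ChainConfig", "ChainOutput", "sample_conditional_latent",
           "sample_dc_posterior"]

_TARGET_ACC = 0.4


@dataclass(frozen=True)
class ChainConfig:
    iterations: int = 6000
    burn_in: int = 2000
    thin: int = 1
    proposal_sd: float | str = "adaptive"
    seed: int = 0
    n_chains: int = 2

    def __post_init__(self):
        if not (0 <= self.burn_in < self.iterations):
            raise ValueError("need 0 <= burn_in < iterations")
        if self.n_chains < 2:
            raise ValueError("n_chains must be >= 2 (diagnostics need it)")
        if (self.iterations - self.burn_in) // self.thin < 500:
            warnings.warn("fewer than 500 retained draws per chain",
                          RuntimeWarning)


@dataclass
class ChainOutput:
    """Retained draws (n_chains, kept, dim) plus convergence diagnostics."""

    draws: np.ndarray
    acceptance_rate: float
    rhat: np.ndarray
    ess: np.ndarray
    dim_names: tuple[str, ...] = ()
    warnings: list[str] = field(default_factory=list)

    @property
    def flat(self) -> np.ndarray:
        """Draws pooled across chains, shape (n_chains*kept, dim)."""
        return self.draws.reshape(-1, self.draws.shape[-1])

    def mean(self) -> np.ndarray:
        return self.flat.mean(axis=0)

    def var(self) -> np.ndarray:
        return self.flat.var(axis=0, ddof=1)


def _split_rhat(draws: np.ndarray) -> np.ndarray:
    """Potential scale reduction on split chains; draws (C, N, D)."""
    C, N, D = draws.shape
    half = N // 2
    seqs = np.concatenate([draws[:, :half], draws[:, half : 2 * half]], axis=0)
    m, n = seqs.shape[0], seqs.shape[1]
    means = seqs.mean(axis=1)
    W = seqs.var(axis=1, ddof=1).mean(axis=0)
    B = n * means.var(axis=0, ddof=1)
    var_plus = (n - 1) / n * W + B / n
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.sqrt(var_plus / W)
    return np.where(W > 0, out, 1.0)


def _ess_1d(x: np.ndarray) -> float:
    """Effective sample size of one sequence via initial positive-pair
    autocorrelation truncation."""
    n = x.size
    x = x - x.mean()
    v = np.dot(x, x) / n
    if v == 0:
        return float(n)
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[:n].real / n
    rho = acov / v
    s = 0.0
    for k in range(1, n // 2):
        pair = rho[2 * k - 1] + rho[2 * k] if 2 * k < n else rho[2 * k - 1]
        if pair < 0:
            break
        s += pair
    return float(n / (1.0 + 2.0 * s))


def _ess(draws: np.ndarray) -> np.ndarray:
    C, N, D = draws.shape
    return np.array([sum(_ess_1d(draws[c, :, d]) for c in range(C))
                     for d in range(D)])


def _diagnose(draws, acc, names) -> ChainOutput:
    rhat = _split_rhat(draws)
    ess = _ess(draws)
    out = ChainOutput(draws=draws, acceptance_rate=float(acc), rhat=rhat,
                      ess=ess, dim_names=tuple(names))
    bad = np.flatnonzero(rhat > 1.05)
    if bad.size:
        msg = f"rhat > 1.05 on dimensions {bad.tolist()} (max {rhat.max():.3f})"
        out.warnings.append(msg)
        warnings.warn(msg, RuntimeWarning)
    return out


# ---------------------------------------------------------------------------
# conditional latent sampler


def sample_conditional_latent(
    spec: ModelSpec, theta: Theta, data: Dataset, cfg: ChainConfig = ChainConfig()
) -> ChainOutput:
    """Sample f(x_i | y_i, w_i; theta) for every observation at once.

    Each observation gets an independent scalar chain; chains are vectorized
    across observations and replicated ``n_chains`` times from dispersed
    starts.  Proposal scales start at the Laplace conditional SD and adapt
    during burn-in.
    """
    theta.validate_for(spec)
    rng = np.random.default_rng(cfg.seed)
    n = data.n
    mode, h, _ = newton_ascent(spec, theta, data,
                               default_starts(spec, data, "observed_w"))
    base_sd = 1.0 / np.sqrt(-h)

    starts = np.empty((cfg.n_chains, n))
    starts[0] = mode
    for c in range(1, cfg.n_chains):
        starts[c] = mode + (3.0 if c % 2 else -3.0) * base_sd * (1 + c // 2)

    x = starts.copy()
    logf = np.stack([obs_log_joint(spec, theta, x[c], data.y, data.w)
                     for c in range(cfg.n_chains)])
    adaptive = cfg.proposal_sd == "adaptive"
    log_sd = np.log(np.broadcast_to(
        base_sd if adaptive else float(cfg.proposal_sd), (cfg.n_chains, n)
    ).copy())

    kept = (cfg.iterations - cfg.burn_in) // cfg.thin
    draws = np.empty((cfg.n_chains, kept, n))
    n_acc = 0
    n_tot = 0
    k = 0
    for t in range(cfg.iterations):
        prop = x + np.exp(log_sd) * rng.standard_normal((cfg.n_chains, n))
        logf_prop = np.stack([
            obs_log_joint(spec, theta, prop[c], data.y, data.w)
            for c in range(cfg.n_chains)
        ])
        accept = np.log(rng.random((cfg.n_chains, n))) < logf_prop - logf
        x = np.where(accept, prop, x)
        logf = np.where(accept, logf_prop, logf)
        if adaptive and t < cfg.burn_in:
            gamma = 1.0 / np.sqrt(t + 10.0)
            log_sd += gamma * (accept.astype(float) - _TARGET_ACC)
        if t >= cfg.burn_in:
            n_acc += accept.sum()
            n_tot += accept.size
            if (t - cfg.burn_in) % cfg.thin == 0 and k < kept:
                draws[:, k] = x
                k += 1
    names = tuple(f"x[{i}]" for i in range(n))
    return _diagnose(draws[:, :k], n_acc / max(n_tot, 1), names)


# ---------------------------------------------------------------------------
# data-cloning posterior


def _default_log_prior(z: np.ndarray) -> float:
    # Normal(0, 10^2) on each unconstrained coordinate
    return float(-0.5 * np.sum((z / 10.0) ** 2))


def sample_dc_posterior(
    spec: ModelSpec,
    data: Dataset,
    K: int,
    prior: Callable[[np.ndarray], float] | None = None,
    cfg: ChainConfig = ChainConfig(),
    free: Sequence[str] | None = None,
    theta_init: Theta | None = None,
) -> ChainOutput:
    """Metropolis-within-Gibbs on the K-clone posterior over (theta, latents).

    The target is proportional to ``prod_k f(y, x^{(k)}; theta) pi(theta)``
    with K independent latent copies.  Returns the theta-marginal draws on
    the natural scale.  ``prior`` is a log-density on the unconstrained
    parameter scale; the default is Normal(0, 10^2) per coordinate.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if theta_init is None:
        if data.true_theta is None:
            raise ValueError("theta_init required when dataset has no true_theta")
        theta_init = data.true_theta
    theta_init.validate_for(spec)
    names = list(free if free is not None else spec.free_parameters)
    log_prior = prior if prior is not None else _default_log_prior
    rng = np.random.default_rng(cfg.seed)
    n, p = data.n, len(names)

    kept = (cfg.iterations - cfg.burn_in) // cfg.thin
    draws = np.empty((cfg.n_chains, kept, p))
    acc_total = 0
    acc_count = 0

    z_center = to_unconstrained(theta_init, names)
    for c in range(cfg.n_chains):
        z = z_center + (0.0 if c == 0 else rng.normal(scale=0.5, size=p))
        theta = from_unconstrained(z, names, theta_init)
        x = np.stack([default_starts(spec, data, "observed_w")
                      for _ in range(K)])
        x += rng.normal(scale=0.1, size=x.shape)
        obs_ll = np.stack([obs_log_joint(spec, theta, x[k], data.y, data.w)
                           for k in range(K)])
        z_sd = np.full(p, 0.1 / np.sqrt(K))
        x_sd = np.full((K, n), 0.5)
        k_keep = 0
        for t in range(cfg.iterations):
            # latent block: componentwise RW over all K x n sites
            prop = x + x_sd * rng.standard_normal((K, n))
            prop_ll = np.stack([
                obs_log_joint(spec, theta, prop[k], data.y, data.w)
                for k in range(K)
            ])
            acc_x = np.log(rng.random((K, n))) < prop_ll - obs_ll
            x = np.where(acc_x, prop, x)
            obs_ll = np.where(acc_x, prop_ll, obs_ll)
            # theta block: joint RW on the unconstrained scale
            z_prop = z + z_sd * rng.standard_normal(p)
            theta_prop = from_unconstrained(z_prop, names, theta_init)
            try:
                prop_obs = np.stack([
                    obs_log_joint(spec, theta_prop, x[k], data.y, data.w)
                    for k in range(K)
                ])
                delta = (prop_obs.sum() + log_prior(z_prop)
                         - obs_ll.sum() - log_prior(z))
            except Exception:
                delta = -np.inf
                prop_obs = None
            accept_theta = np.log(rng.random()) < delta
            if accept_theta:
                z, theta, obs_ll = z_prop, theta_prop, prop_obs
            if cfg.proposal_sd == "adaptive" and t < cfg.burn_in:
                gamma = 1.0 / np.sqrt(t + 10.0)
                z_sd *= np.exp(gamma * (float(accept_theta) - _TARGET_ACC))
                x_sd *= np.exp(gamma * (acc_x.astype(float) - _TARGET_ACC))
            if t >= cfg.burn_in:
                acc_total += int(accept_theta)
                acc_count += 1
                if (t - cfg.burn_in) % cfg.thin == 0 and k_keep < kept:
                    th_nat = from_unconstrained(z, names, theta_init)
                    draws[c, k_keep] = [th_nat[nm] for nm in names]
                    k_keep += 1
    return _diagnose(draws[:, :k_keep], acc_total / max(acc_count, 1),
                     tuple(names))
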