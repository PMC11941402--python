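"""Per-observation bias factor of the Laplace approximation.

Writing the Laplace approximation as L*(theta; y) = L(theta; y) x b(theta, y)
with

    b = f(u_hat | y; theta) * sqrt(2 pi) * (-H(u_hat))^{-1/2},

the factor b equals 1 exactly when the conditional law of the latent is
Gaussian, and the approximation preserves the shape of the likelihood in
theta iff b is constant in theta.  For the models here the latents are
conditionally independent, so b factorizes over observations and each
per-observation factor b_i can be studied on its own.

Two routes are provided.  The exact route evaluates the conditional
density at the mode through the quadrature marginal likelihood, turning
the definition into the assertable identity

    sum_i log b_i = log L*(theta) - log L(theta).

The MCMC route estimates the same quantity nonparametrically from draws of
the conditional latent chain: a kernel density estimate supplies the
density at its mode, a local quadratic fit to the log-density around the
mode supplies the curvature, and a block bootstrap supplies the standard
error.  The exact route is the reference; the MCMC route reproduces the
procedure available when no quadrature oracle exists.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .laml import InnerConfig, laml_obs_loglik
from .mcmc_engine import ChainConfig, sample_conditional_latent
from .models import Dataset, ModelSpec, Theta
from .oracles import QuadConfig, quadrature_obs_loglik

__all__ = ["BiasProfile", "bias_factor_exact", "bias_factor_mcmc",
           "bias_profile", "kde_mode_density_curvature"]


def _sub_dataset(data: Dataset, i: int) -> Dataset:
    return Dataset(y=data.y[i : i + 1],
                   w=None if data.w is None else data.w[i : i + 1])


def bias_factor_exact(
    spec: ModelSpec,
    theta: Theta,
    data: Dataset,
    i: int,
    quad_cfg: QuadConfig = QuadConfig(),
    inner_cfg: InnerConfig = InnerConfig(),
) -> float:
    """Exact bias factor b_i: ratio of the observation's Laplace term to
    its quadrature marginal term."""
    sub = _sub_dataset(data, i)
    log_laml = laml_obs_loglik(spec, theta, sub, inner_cfg)[0]
    log_true = quadrature_obs_loglik(spec, theta, sub, quad_cfg)[0]
    return float(np.exp(log_laml - log_true))


def kde_mode_density_curvature(
    draws: np.ndarray, bw: str | float = "normal_reference"
) -> tuple[float, float, float]:
    """Mode, density at the mode, and log-density curvature from a KDE.

    The curvature comes from a quadratic fit to the log kernel density on
    mode +- one bandwidth, mirroring how one reads a Hessian off a
    nonparametric estimate.
    """
    draws = np.asarray(draws, dtype=float).ravel()
    if np.std(draws) < 1e-12:
        raise ValueError("degenerate (near point-mass) draws; KDE bandwidth ~ 0")
    kde = sm.nonparametric.KDEUnivariate(draws)
    kde.fit(bw=bw, fft=True, gridsize=1024)
    mode = float(kde.support[int(np.argmax(kde.density))])
    # fit window wide enough to average out KDE wiggle at the empirical
    # argmax, then re-center on the fitted vertex and fit once more
    half = max(float(kde.bw), 0.35 * float(np.std(draws)))
    coef = None
    for _ in range(2):
        window = (np.abs(kde.support - mode) <= half) & (kde.density > 0)
        if window.sum() < 5:
            raise ValueError("too few KDE grid points around the mode")
        xs = kde.support[window] - mode
        ys = np.log(kde.density[window])
        coef = np.polyfit(xs, ys, 2)
        if coef[0] >= 0:
            break
        vertex = -coef[1] / (2.0 * coef[0])
        mode = float(np.clip(mode + vertex, kde.support[0], kde.support[-1]))
    window = np.abs(kde.support - mode) <= half
    xs = kde.support[window] - mode
    ys = np.log(np.maximum(kde.density[window], 1e-300))
    coef = np.polyfit(xs, ys, 2)
    curvature = 2.0 * float(coef[0])
    density = float(np.exp(np.polyval(coef, 0.0)))
    return mode, density, curvature


def bias_factor_mcmc(
    spec: ModelSpec,
    theta: Theta,
    data: Dataset,
    i: int,
    cfg: ChainConfig = ChainConfig(),
    n_boot: int = 40,
    n_blocks: int = 20,
) -> tuple[float, float]:
    """Nonparametric estimate of b_i from conditional-latent MCMC draws,
    with a block-bootstrap standard error."""
    sub = _sub_dataset(data, i)
    chain = sample_conditional_latent(spec, theta, sub, cfg)
    draws = chain.flat[:, 0]

    def estimate(d):
        _, dens, curv = kde_mode_density_curvature(d)
        if curv >= 0:
            raise ArithmeticError("non-negative curvature at KDE mode")
        return dens * math.sqrt(2.0 * math.pi) / math.sqrt(-curv)

    value = estimate(draws)
    blocks = np.array_split(draws, n_blocks)
    rng = np.random.default_rng(cfg.seed + 10_007)
    boots = []
    for _ in range(n_boot):
        idx = rng.integers(0, n_blocks, size=n_blocks)
        try:
            boots.append(estimate(np.concatenate([blocks[b] for b in idx])))
        except (ArithmeticError, ValueError):
            continue
    se = float(np.std(boots, ddof=1)) if len(boots) > 2 else float("nan")
    return float(value), se


@dataclass
class BiasProfile:
    """Bias factors for one observation along a parameter grid."""

    observation_index: int
    parameter_name: str
    grid: np.ndarray
    bias_exact: np.ndarray
    bias_mcmc: np.ndarray | None = None
    mcmc_se: np.ndarray | None = None
    smoother_fit: np.ndarray | None = None
    extras: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        cols = {self.parameter_name: self.grid, "bias_exact": self.bias_exact}
        if self.bias_mcmc is not None:
            cols["bias_mcmc"] = self.bias_mcmc
            cols["mcmc_se"] = self.mcmc_se
        if self.smoother_fit is not None:
            cols["smoother_fit"] = self.smoother_fit
        return pd.DataFrame(cols)


def bias_profile(
    spec: ModelSpec,
    data: Dataset,
    i: int,
    grid: Sequence[float],
    theta_fixed: Theta,
    parameter_name: str = "beta",
    with_mcmc: bool = False,
    cfg: ChainConfig = ChainConfig(),
    quad_cfg: QuadConfig = QuadConfig(),
    lowess_frac: float = 0.5,
) -> BiasProfile:
    """Bias factor of one observation swept along a parameter grid, with an
    optional locally weighted (LOESS) smoother over the noisy MCMC route."""
    grid = np.asarray(grid, dtype=float)
    exact = np.full(grid.size, np.nan)
    mcmc = np.full(grid.size, np.nan) if with_mcmc else None
    mcmc_se = np.full(grid.size, np.nan) if with_mcmc else None
    for j, v in enumerate(grid):
        theta = theta_fixed.replace(**{parameter_name: v})
        try:
            exact[j] = bias_factor_exact(spec, theta, data, i, quad_cfg)
        except Exception as exc:
            warnings.warn(f"exact bias factor failed at {v}: {exc}",
                          RuntimeWarning)
        if with_mcmc:
            try:
                cfg_j = ChainConfig(iterations=cfg.iterations,
                                    burn_in=cfg.burn_in, thin=cfg.thin,
                                    proposal_sd=cfg.proposal_sd,
                                    seed=cfg.seed + j, n_chains=cfg.n_chains)
                mcmc[j], mcmc_se[j] = bias_factor_mcmc(spec, theta, data, i,
                                                       cfg_j)
            except Exception as exc:
                warnings.warn(f"MCMC bias factor failed at {v}: {exc}",
                              RuntimeWarning)
    smoother = None
    if with_mcmc and np.isfinite(mcmc).sum() >= 5:
        ok = np.isfinite(mcmc)
        fit = sm.nonparametric.lowess(mcmc[ok], grid[ok], frac=lowess_frac,
                                      return_sorted=False)
        smoother = np.full(grid.size, np.nan)
        smoother[ok] = fit
    return BiasProfile(observation_index=i, parameter_name=parameter_name,
                       grid=grid, bias_exact=exact, bias_mcmc=mcmc,
                       mcmc_se=mcmc_se, smoother_fit=smoother)
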