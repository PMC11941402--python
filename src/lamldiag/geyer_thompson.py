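"""Importance-ratio (Geyer-Thompson) approximation to the likelihood.

With latent draws x_j ~ f(x | y, w; theta_ref) from the conditional chain
at a reference parameter, the log-likelihood ratio against the reference is

    log L(theta) - log L(theta_ref)
        = log E_ref[ f(y, x; theta) / f(y, x; theta_ref) ]
        ~ log mean_j exp( log f(y, x_j; theta) - log f(y, x_j; theta_ref) )

All averaging is done in log space; the importance weights span hundreds
of log units across a likelihood-curve grid, so natural-scale ratios are
never formed.  The effective sample size (sum w)^2 / sum w^2 quantifies
how far from the reference the ratio can be trusted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special

from .mcmc_engine import ChainConfig, ChainOutput, sample_conditional_latent
from .models import Dataset, ModelSpec, Theta, obs_log_joint

__all__ = ["GtEstimate", "gt_log_ratio", "gt_curve"]

_MIN_ESS = 30.0


@dataclass
class GtEstimate:
    """Importance-ratio likelihood curve relative to a reference point."""

    theta_ref: Theta
    parameter_name: str
    grid: np.ndarray
    log_ratio: np.ndarray
    ess_at_theta: np.ndarray
    references: list[Theta] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rel = np.exp(self.log_ratio - np.nanmax(self.log_ratio))
        return pd.DataFrame({
            self.parameter_name: self.grid,
            "method": "gt",
            "loglik": self.log_ratio,
            "relative": rel,
            "ess": self.ess_at_theta,
        })


def _sum_log_joint(spec, theta, data, x):
    """log f(y, x; theta) for a batch of latent vectors x, shape (J, n)."""
    w = None if data.w is None else data.w[None, :]
    return obs_log_joint(spec, theta, x, data.y[None, :], w).sum(axis=1)


def gt_log_ratio(
    spec: ModelSpec,
    theta: Theta,
    theta_ref: Theta,
    data: Dataset,
    latent_draws: ChainOutput | np.ndarray,
) -> tuple[float, float]:
    """One-point importance-ratio estimate and its effective sample size.

    ``latent_draws`` must come from the conditional latent chain at
    ``theta_ref``.  Returns exactly 0 at ``theta == theta_ref``.
    """
    x = latent_draws.flat if isinstance(latent_draws, ChainOutput) else np.asarray(latent_draws)
    if dict(theta) == dict(theta_ref):
        return 0.0, float(x.shape[0])
    delta = _sum_log_joint(spec, theta, data, x) - _sum_log_joint(spec, theta_ref, data, x)
    J = delta.size
    value = float(special.logsumexp(delta) - np.log(J))
    ess = float(np.exp(2.0 * special.logsumexp(delta) - special.logsumexp(2.0 * delta)))
    if ess < _MIN_ESS:
        warnings.warn(f"GT effective sample size {ess:.1f} < {_MIN_ESS:.0f}; "
                      "ratio unreliable this far from the reference",
                      RuntimeWarning)
    return value, ess


def gt_curve(
    spec: ModelSpec,
    data: Dataset,
    parameter_name: str,
    grid: Sequence[float],
    references: Sequence[Theta],
    cfg: ChainConfig = ChainConfig(),
) -> GtEstimate:
    """Importance-ratio likelihood curve, averaged over reference points.

    One conditional-latent chain is run per reference; the per-reference
    curves are aligned by their value at a common anchor (the grid point
    closest to the first reference) and combined by ESS-weighted averaging.
    References whose chains fail the split-Rhat diagnostic are dropped.
    """
    grid = np.asarray(grid, dtype=float)
    if len(references) == 0:
        raise ValueError("at least one reference required")
    anchor = int(np.argmin(np.abs(grid - references[0][parameter_name])))
    curves, esss, used = [], [], []
    for r, ref in enumerate(references):
        chain_cfg = ChainConfig(iterations=cfg.iterations, burn_in=cfg.burn_in,
                                thin=cfg.thin, proposal_sd=cfg.proposal_sd,
                                seed=cfg.seed + r, n_chains=cfg.n_chains)
        chain = sample_conditional_latent(spec, ref, data, chain_cfg)
        if np.any(chain.rhat > 1.1):
            warnings.warn(f"reference {r} excluded: rhat up to "
                          f"{chain.rhat.max():.3f}", RuntimeWarning)
            continue
        lr = np.empty(grid.size)
        ess = np.empty(grid.size)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            for j, v in enumerate(grid):
                theta = ref.replace(**{parameter_name: v})
                lr[j], ess[j] = gt_log_ratio(spec, theta, ref, data, chain)
        curves.append(lr - lr[anchor])
        esss.append(ess)
        used.append(ref)
    if not curves:
        raise RuntimeError("all GT reference chains failed diagnostics")
    curves = np.stack(curves)
    esss = np.stack(esss)
    wts = esss / esss.sum(axis=0, keepdims=True)
    log_ratio = (wts * curves).sum(axis=0)
    return GtEstimate(theta_ref=used[0], parameter_name=parameter_name,
                      grid=grid, log_ratio=log_ratio,
                      ess_at_theta=esss.sum(axis=0), references=list(used))
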