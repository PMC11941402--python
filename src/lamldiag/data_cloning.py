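"""Data-cloning MLE and the clone-scaling identifiability diagnostic.

Data cloning samples the Bayesian posterior computed from K imaginary
independent replicates of the observed data.  As K grows the posterior
concentrates at the maximum-likelihood estimate, its mean converges to the
MLE, and K times its variance converges to the inverse Fisher information
— provided the parameters are identifiable (more precisely, estimable).
When they are not, the K-clone posterior variance flattens out at a
positive asymptote instead of decaying like 1/K; tracking the variance
along an increasing clone schedule therefore doubles as an
identifiability diagnostic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .mcmc_engine import ChainConfig, sample_dc_posterior
from .models import Dataset, ModelSpec, Theta

__all__ = ["CloneRun", "dc_mle", "identifiability_diagnostic"]

# fitted variance asymptote relative to the K=1 variance
_IDENTIFIABLE_FRAC = 0.10
_NONIDENTIFIABLE_FRAC = 0.50


@dataclass
class CloneRun:
    """Posterior summary at one clone count K."""

    K: int
    posterior_mean: dict[str, float]
    posterior_var: dict[str, float]
    diagnostics: dict = field(default_factory=dict)

    @property
    def scaled_var(self) -> dict[str, float]:
        return {k: self.K * v for k, v in self.posterior_var.items()}


def runs_to_frame(runs: Sequence[CloneRun]) -> pd.DataFrame:
    rows = []
    for run in runs:
        for p in run.posterior_mean:
            rows.append({"K": run.K, "parameter": p,
                         "mean": run.posterior_mean[p],
                         "var": run.posterior_var[p],
                         "scaled_var": run.scaled_var[p]})
    return pd.DataFrame(rows)


def dc_mle(
    spec: ModelSpec,
    data: Dataset,
    K_schedule: Sequence[int] = (1, 5, 20),
    prior: Callable | None = None,
    cfg: ChainConfig = ChainConfig(),
    free: Sequence[str] | None = None,
    theta_init: Theta | None = None,
) -> tuple[Theta, dict[str, float], list[CloneRun]]:
    """Data-cloning MLE along an increasing clone schedule.

    Returns ``(theta_hat, fisher_var, runs)``: the posterior mean at the
    largest successful K, K times the posterior variance there (the
    asymptotic variance estimate), and the per-K summaries.
    """
    K_schedule = list(K_schedule)
    if not K_schedule or any(b <= a for a, b in zip(K_schedule, K_schedule[1:])):
        raise ValueError("K_schedule must be nonempty and increasing")
    names = list(free if free is not None else spec.free_parameters)
    runs: list[CloneRun] = []
    for K in K_schedule:
        try:
            chain = sample_dc_posterior(spec, data, K, prior=prior, cfg=cfg,
                                        free=names, theta_init=theta_init)
        except Exception as exc:
            warnings.warn(f"data-cloning chain failed at K={K}: {exc}",
                          RuntimeWarning)
            continue
        mean = chain.mean()
        var = chain.var()
        runs.append(CloneRun(
            K=K,
            posterior_mean={p: float(m) for p, m in zip(names, mean)},
            posterior_var={p: float(v) for p, v in zip(names, var)},
            diagnostics={"rhat_max": float(chain.rhat.max()),
                         "ess_min": float(chain.ess.min()),
                         "acceptance": chain.acceptance_rate,
                         "warnings": list(chain.warnings)},
        ))
    if not runs:
        raise RuntimeError("every clone level failed")
    last = runs[-1]
    base = theta_init if theta_init is not None else data.true_theta
    theta_hat = base.replace(**last.posterior_mean)
    fisher_var = dict(last.scaled_var)
    return theta_hat, fisher_var, runs


def identifiability_diagnostic(runs: Sequence[CloneRun]) -> dict[str, str]:
    """Classify each parameter from the decay of posterior variance in K.

    A regression of variance on 1/K gives a fitted asymptote (the variance
    at K -> infinity).  An asymptote below 10% of the K=1 variance reads as
    ``identifiable`` (variance tracks c/K); above 50% as
    ``nonidentifiable`` (variance flattens at a positive level); anything
    in between, or pathological fits, as ``inconclusive``.
    """
    if len(runs) < 3:
        raise ValueError("need at least 3 clone levels")
    runs = sorted(runs, key=lambda r: r.K)
    Ks = np.array([r.K for r in runs], dtype=float)
    verdicts: dict[str, str] = {}
    for p in runs[0].posterior_mean:
        v = np.array([r.posterior_var[p] for r in runs])
        v1 = v[0]
        if v1 <= 0:
            verdicts[p] = "inconclusive"
            continue
        A = np.column_stack([np.ones_like(Ks), 1.0 / Ks])
        coef, *_ = np.linalg.lstsq(A, v, rcond=None)
        asymptote = max(float(coef[0]), 0.0)
        frac = asymptote / v1
        if frac < _IDENTIFIABLE_FRAC:
            verdicts[p] = "identifiable"
        elif frac > _NONIDENTIFIABLE_FRAC:
            verdicts[p] = "nonidentifiable"
        else:
            verdicts[p] = "inconclusive"
    return verdicts
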