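"""Laplace approximation to the marginal likelihood (LAML).

For each observation the latent is maximized out of the joint density and
the curvature at the mode supplies the Gaussian-integral correction:

    log L*(theta; y) = log f(y, u_hat; theta) + (n/2) log(2 pi)
                       - (1/2) sum_i log(-H_i(u_hat_i))

The (2 pi)^{n/2} constant is included (and the determinant is taken of
the *negative* Hessian) so that the approximation is exact — not merely
proportional — whenever the conditional law of the latents is Gaussian.
Constants cancel in relative likelihoods, so curve comparisons are
unaffected, but the Gaussian-exactness identity and the bias-factor
decomposition both rely on the full constant.

The quality of the approximation hinges on the conditional density
f(u | y; theta) being close to Gaussian; where it is not, L* acquires a
theta-dependent multiplicative bias (see :mod:`lamldiag.bias_diagnostic`)
that can relocate the maximizer and distort curvature-based intervals.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize

from ._inner import default_starts, newton_ascent
from ._param import from_unconstrained, to_unconstrained
from .models import Dataset, ModelSpec, Theta, obs_log_joint
from .oracles import LikelihoodCurve, profile_loglik_oracle

__all__ = ["InnerConfig", "LamlFit", "inner_modes", "laml_obs_loglik",
           "laml_loglik", "laml_mle", "profile_laml"]

_LOG2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class InnerConfig:
    """Controls the inner (latent-mode) optimization.

    ``start_policy``: ``observed_w`` starts each latent at its measurement
    (the default; y-informed moment starts for the models without a w),
    ``zero`` at the origin, ``multistart`` tries several dispersed starts
    per observation and keeps the best local maximum while recording
    whether distinct optima were found — the practical red flag for a
    multimodal conditional density.
    """

    start_policy: str = "observed_w"
    multistart_count: int = 4
    newton_tol: float = 1e-10
    max_iter: int = 200
    custom_starts: tuple[float, ...] | None = None


@dataclass
class LamlFit:
    """Result of a Laplace fit: outer MLE, latent modes and curvatures."""

    theta_hat: Theta
    latent_modes: np.ndarray
    inner_curvatures: np.ndarray
    loglik: float
    wald_se: dict[str, float] | None
    inner_converged: bool
    outer_converged: bool
    start_policy: str
    distinct_inner_modes: int = 0

    def to_json(self) -> str:
        return json.dumps({
            "theta_hat": dict(self.theta_hat),
            "wald_se": self.wald_se,
            "loglik": self.loglik,
            "inner_converged": self.inner_converged,
            "outer_converged": self.outer_converged,
            "start_policy": self.start_policy,
            "distinct_inner_modes": self.distinct_inner_modes,
        }, indent=1)


def _start_list(spec, data, cfg):
    if cfg.start_policy == "custom":
        if cfg.custom_starts is None:
            raise ValueError("custom start_policy needs custom_starts")
        return [np.full(data.n, s) for s in cfg.custom_starts]
    if cfg.start_policy in ("zero", "observed_w"):
        return [default_starts(spec, data, cfg.start_policy)]
    if cfg.start_policy == "multistart":
        base = default_starts(spec, data, "observed_w")
        starts = [base, default_starts(spec, data, "zero"), -base]
        rng = np.random.default_rng(1234)  # fixed: determinism contract
        for _ in range(max(0, cfg.multistart_count - len(starts))):
            starts.append(base + rng.normal(scale=1.0 + np.abs(base)))
        return starts[: max(cfg.multistart_count, 1)]
    raise ValueError(f"unknown start_policy {cfg.start_policy!r}")


def inner_modes(
    spec: ModelSpec, theta: Theta, data: Dataset, cfg: InnerConfig = InnerConfig()
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Per-observation latent modes and curvatures of the log joint.

    Returns ``(u_hat, H_diag, info)`` where ``info`` records convergence
    and, under multistart, how many observations exhibited distinct local
    maxima.
    """
    theta.validate_for(spec)
    best_x = best_f = best_h = None
    all_modes = []
    conv_any = np.zeros(data.n, dtype=bool)
    for x0 in _start_list(spec, data, cfg):
        x, h, conv = newton_ascent(spec, theta, data, x0,
                                   tol=cfg.newton_tol, max_iter=cfg.max_iter)
        f = obs_log_joint(spec, theta, x, data.y, data.w)
        all_modes.append((x, conv))
        conv_any |= conv
        if best_f is None:
            best_x, best_f, best_h = x, f, h
        else:
            better = f > best_f
            best_x = np.where(better, x, best_x)
            best_f = np.where(better, f, best_f)
            best_h = np.where(better, h, best_h)
    # escape saddle points / local minima: a stationary point with
    # non-negative curvature is not a maximum, so push off it and re-ascend
    if np.any(best_h >= 0):
        for offset in (0.5, -0.5, 2.0, -2.0):
            bad = best_h >= 0
            if not bad.any():
                break
            x, h, conv = newton_ascent(spec, theta, data, best_x + offset,
                                       tol=cfg.newton_tol, max_iter=cfg.max_iter)
            f = obs_log_joint(spec, theta, x, data.y, data.w)
            better = (f > best_f + 1e-12) | (bad & (h < 0) & (f >= best_f - 1e-9))
            best_x = np.where(better, x, best_x)
            best_f = np.where(better, f, best_f)
            best_h = np.where(better, h, best_h)
            conv_any |= better & conv
    distinct = 0
    if len(all_modes) > 1:
        ref_x, ref_c = all_modes[0]
        mask = np.zeros(data.n, dtype=bool)
        for x, c in all_modes[1:]:
            mask |= ref_c & c & (np.abs(x - ref_x) > 1e-4 * (1 + np.abs(ref_x)))
        distinct = int(mask.sum())
    if np.any(best_h >= 0):
        bad = np.flatnonzero(best_h >= 0)
        raise ArithmeticError(
            f"non-negative curvature at reported inner optimum, obs {bad.tolist()}"
        )
    info = {
        "converged": bool(conv_any.all()),
        "converged_mask": conv_any,
        "distinct_inner_modes": distinct,
    }
    return best_x, best_h, info


def laml_obs_loglik(
    spec: ModelSpec, theta: Theta, data: Dataset, cfg: InnerConfig = InnerConfig()
) -> np.ndarray:
    """Per-observation Laplace terms: joint at the mode + Gaussian correction."""
    u, h, _ = inner_modes(spec, theta, data, cfg)
    f = obs_log_joint(spec, theta, u, data.y, data.w)
    return f + 0.5 * _LOG2PI - 0.5 * np.log(-h)


def laml_loglik(
    spec: ModelSpec, theta: Theta, data: Dataset, cfg: InnerConfig = InnerConfig()
) -> float:
    """Laplace-approximated log marginal likelihood log L*(theta; y)."""
    return float(np.sum(laml_obs_loglik(spec, theta, data, cfg)))


def _numerical_hessian(fn, z0, step=1e-4):
    z0 = np.asarray(z0, dtype=float)
    k = z0.size
    H = np.empty((k, k))
    hs = step * np.maximum(1.0, np.abs(z0))
    f0 = fn(z0)
    for i in range(k):
        ei = np.zeros(k); ei[i] = hs[i]
        H[i, i] = (fn(z0 + ei) - 2.0 * f0 + fn(z0 - ei)) / hs[i] ** 2
        for j in range(i):
            ej = np.zeros(k); ej[j] = hs[j]
            H[i, j] = H[j, i] = (
                fn(z0 + ei + ej) - fn(z0 + ei - ej)
                - fn(z0 - ei + ej) + fn(z0 - ei - ej)
            ) / (4.0 * hs[i] * hs[j])
    return H


def laml_mle(
    spec: ModelSpec,
    data: Dataset,
    start: Theta,
    cfg: InnerConfig = InnerConfig(),
    free: Sequence[str] | None = None,
    n_restarts: int = 3,
    jitter: float = 0.3,
) -> LamlFit:
    """Maximize the Laplace log-likelihood over the free parameters.

    Optimization runs on the transformed scale (log for dispersions) via
    Nelder-Mead from ``n_restarts`` deterministically jittered starts; the
    best optimum is kept.  Wald standard errors come from the inverse of
    the negative numerical Hessian of the LAML at the optimum, on the
    natural scale — the convention of curvature-based software intervals.
    """
    start.validate_for(spec)
    names = list(free if free is not None else spec.free_parameters)

    def neg(z):
        try:
            return -laml_loglik(spec, from_unconstrained(z, names, start), data, cfg)
        except Exception:
            return np.inf

    z0 = to_unconstrained(start, names)
    if len(names) == 1:
        # scalar outer problem: coarse scan, then bounded refinement around
        # the best grid point (robust to multimodal Laplace objectives)
        zs = np.concatenate([z0 + np.linspace(-4.0, 4.0, 25), z0])
        vals = np.array([neg(np.array([z])) for z in zs])
        j = int(np.argmin(vals))
        step = 8.0 / 24.0
        res = optimize.minimize_scalar(
            lambda z: neg(np.array([z])),
            bounds=(zs[j] - step, zs[j] + step), method="bounded",
            options={"xatol": 1e-6})
        best = optimize.OptimizeResult(x=np.array([res.x]), fun=res.fun,
                                       success=True)
    else:
        rng = np.random.default_rng(20)  # fixed: determinism contract
        best = None
        for r in range(max(1, n_restarts)):
            z_init = z0 if r == 0 else z0 + rng.normal(scale=jitter, size=z0.size)
            res = optimize.minimize(neg, z_init, method="Nelder-Mead",
                                    options={"xatol": 1e-6, "fatol": 1e-8,
                                             "maxiter": 400 * len(names)})
            if best is None or res.fun < best.fun:
                best = res
    theta_hat = from_unconstrained(best.x, names, start)
    u, h, info = inner_modes(spec, theta_hat, data, cfg)
    loglik = float(-best.fun)

    # Wald SEs on the natural scale
    th0 = np.array([theta_hat[p] for p in names])

    def natural(vec):
        th = theta_hat.replace(**{p: max(v, 1e-10) if p != "beta" and p != "mu" else v
                                  for p, v in zip(names, vec)})
        try:
            return laml_loglik(spec, th, data, cfg)
        except Exception:
            return -np.inf
    wald = None
    try:
        H = _numerical_hessian(natural, th0)
        cov = np.linalg.inv(-H)
        d = np.diag(cov)
        if np.all(d > 0):
            wald = {p: float(np.sqrt(v)) for p, v in zip(names, d)}
    except Exception:
        wald = None
    if wald is None:
        warnings.warn("non-positive-definite outer Hessian; Wald SEs absent",
                      RuntimeWarning)
    return LamlFit(
        theta_hat=theta_hat,
        latent_modes=u,
        inner_curvatures=h,
        loglik=loglik,
        wald_se=wald,
        inner_converged=info["converged"],
        outer_converged=bool(best.success),
        start_policy=cfg.start_policy,
        distinct_inner_modes=info["distinct_inner_modes"],
    )


def profile_laml(
    spec: ModelSpec,
    data: Dataset,
    psi_name: str,
    psi_grid: Sequence[float],
    theta_init: Theta,
    cfg: InnerConfig = InnerConfig(),
) -> LikelihoodCurve:
    """LAML profile likelihood for ``psi`` by constrained maximization of
    the Laplace objective over the nuisance parameters."""

    def objective(th):
        return laml_loglik(spec, th, data, cfg)

    return profile_loglik_oracle(
        spec, data, psi_name, psi_grid, theta_init,
        objective=objective, method_label="laml_profile",
    )
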