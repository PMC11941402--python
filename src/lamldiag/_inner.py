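"""Vectorized 1-D Newton ascent on the per-observation log joint.

Latents are conditionally independent given the data, so the inner
optimization over the latent vector decouples into n scalar problems that
are solved simultaneously with array arithmetic.
"""

from __future__ import annotations

import numpy as np

from .models import ModelSpec, Theta, Dataset, obs_log_joint, dlog_joint_dx, d2log_joint_dx2

__all__ = ["newton_ascent", "default_starts"]


def default_starts(spec: ModelSpec, data: Dataset, policy: str = "observed_w") -> np.ndarray:
    """Per-observation starting values for the inner optimization.

    ``observed_w`` starts each latent at its noisy measurement ``w_i``
    (for the models without a ``w``, at a y-informed moment estimate);
    ``zero`` starts at 0 everywhere.
    """
    n = data.n
    if policy == "zero":
        x0 = np.zeros(n)
        if spec.family == "poisson_quadratic":
            # exact zero is a pole of the Poisson(x^2) term when y > 0
            x0 = np.where(data.y > 0, 1e-6, 0.0)
        return x0
    if policy == "observed_w":
        if spec.has_covariate_observation:
            return data.w.copy()
        if spec.family == "poisson_quadratic":
            return np.sqrt(data.y + 0.25)
        return data.y.copy()  # variance_partition: latent mean near y_i
    raise ValueError(f"unknown start policy {policy!r}")


def newton_ascent(
    spec: ModelSpec,
    theta: Theta,
    data: Dataset,
    x0: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 200,
):
    """Safeguarded Newton maximization of each observation's log joint.

    Returns ``(x, curvature, converged)``.  Steps that fail to increase the
    objective are halved; non-concave regions fall back to a damped
    gradient step.  The accepted-step sequence is therefore monotone
    ascending per observation.
    """
    x = np.asarray(x0, dtype=float).copy()
    f = obs_log_joint(spec, theta, x, data.y, data.w)
    converged = np.zeros(data.n, dtype=bool)
    for _ in range(max_iter):
        g = dlog_joint_dx(spec, theta, x, data)
        h = d2log_joint_dx2(spec, theta, x, data)
        h_safe = np.where(h < 0, h, -1.0)
        # small gradient, or Newton step below float resolution of x
        newly = (np.abs(g) < tol * (1.0 + np.abs(x))) | (
            np.abs(g / h_safe) < 1e-12 * (1.0 + np.abs(x)))
        converged |= newly
        if converged.all():
            break
        step = np.where(h < 0, -g / np.where(h < 0, h, -1.0), g / (np.abs(h) + 1.0))
        step = np.clip(step, -50.0, 50.0)
        step[converged] = 0.0
        # backtracking: halve until the objective does not decrease; the
        # slack scales with |f| because evaluation noise does too
        slack = 1e-9 * (1.0 + np.abs(f))
        active = ~converged
        for _ in range(60):
            x_new = x + step
            f_new = obs_log_joint(spec, theta, x_new, data.y, data.w)
            bad = active & ~(f_new >= f - slack)
            if not bad.any():
                break
            step[bad] *= 0.5
        accept = active & (f_new >= f - slack)
        x[accept] = x_new[accept]
        f[accept] = f_new[accept]
    h = d2log_joint_dx2(spec, theta, x, data)
    return x, h, converged
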