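"""Gold-standard marginal likelihoods and likelihood-based intervals.

The marginal likelihood of every model here is a product of n independent
one-dimensional integrals over the scalar latent of each observation:

    L(theta; y) = prod_i  int f(y_i | x; theta) f(w_i | x; theta) g(x; theta) dx

Two interchangeable evaluators are provided: a deterministic quadrature
(per-observation Gauss-Legendre on a safe window around the integrand mode,
or scipy's adaptive QUADPACK rule) and the simple Monte Carlo estimator
that averages the conditional density over draws from the latent law.
The quadrature route is the package's reference; the Monte Carlo route
reproduces the classical "gold standard" and carries a delta-method
standard error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from numpy.polynomial.legendre import leggauss
from scipy import integrate, optimize, special, stats

from ._inner import default_starts, newton_ascent
from ._param import from_unconstrained, to_unconstrained
from .models import Dataset, ModelSpec, Theta, obs_log_joint

__all__ = [
    "QuadConfig",
    "LikelihoodCurve",
    "quadrature_loglik",
    "quadrature_obs_loglik",
    "mc_loglik",
    "likelihood_curve",
    "lr_confidence_interval",
    "LrInterval",
    "profile_loglik_oracle",
]


@dataclass(frozen=True)
class QuadConfig:
    """Settings for the deterministic marginal-likelihood quadrature.

    ``fixed_node`` lays ``node_count`` Gauss-Legendre nodes on a window
    covering every integrand mode +- ``span`` conditional SDs (and, for the
    EIV families, the measurement window ``w_i +- span*sigma1``, which
    bounds the integrand tail regardless of the latent law's heavy tails).
    ``adaptive`` feeds the same window to QUADPACK with the modes as
    break points.
    """

    rule: str = "fixed_node"
    node_count: int = 201
    rel_tol: float = 1e-9
    span: float = 12.0

    def __post_init__(self):
        if self.rule not in ("fixed_node", "adaptive"):
            raise ValueError(f"unknown quadrature rule {self.rule!r}")
        if self.rule == "fixed_node" and self.node_count < 21:
            raise ValueError("node_count must be >= 21")


@lru_cache(maxsize=8)
def _leggauss_cached(node_count: int):
    return leggauss(node_count)


def _candidate_modes(spec, theta, data):
    """Local maxima of each observation's integrand from dispersed starts.

    Returns ``(modes, sds)`` of shape (k, n): Newton ascent from the
    measurement-informed start, a response-informed start, and (for the
    quadratic-mean model) the mirrored and prior-mean starts — so both
    branches of a bimodal conditional are located.
    """
    starts = [default_starts(spec, data, "observed_w")]
    beta = theta.get("beta", 0.0)
    fam = spec.family
    if fam == "poisson_eiv" and abs(beta) > 1e-6:
        starts.append(np.log(data.y + 0.5) / beta)
    elif fam == "normal_eiv" and abs(beta) > 0.3:
        starts.append(data.y / beta)
    elif fam in ("logit_eiv", "probit_eiv"):
        starts.append(np.zeros(data.n))
    elif fam == "poisson_quadratic":
        starts.append(-starts[0])
        starts.append(np.full(data.n, beta))
    modes, sds = [], []
    for x0 in starts:
        # panels only need modes to a few digits
        x, h, _ = newton_ascent(spec, theta, data, x0, tol=1e-6, max_iter=80)
        modes.append(x)
        sds.append(1.0 / np.sqrt(np.maximum(-h, 1e-12)))
    return np.stack(modes), np.stack(sds)


def _guard_interval(spec, theta, data, i):
    """A region that must always be examined: where the observation-level
    evidence (w, or the latent prior) concentrates."""
    if spec.has_covariate_observation:
        s1 = theta["sigma1"]
        return data.w[i] - 4.0 * s1, data.w[i] + 4.0 * s1
    if spec.family == "poisson_quadratic":
        from .models import QUADRATIC_LATENT_VAR

        half = 4.0 * np.sqrt(QUADRATIC_LATENT_VAR)
        return theta["beta"] - half, theta["beta"] + half
    half = 4.0 * np.sqrt(max(theta["tau2"], 1e-12))
    return theta["mu"] - half, theta["mu"] + half


def _obs_atoms(modes_i, sds_i, guard, span):
    """Disjoint integration subintervals ('atoms') for one observation.

    Mode windows (mode +- span*SD) and the guard region are merged where
    they overlap.  A merged stretch is kept as a single panel unless it
    contains a window much narrower than itself (a conditional spike):
    then it is partitioned at that window's boundaries so the spike keeps
    enough nodes and is not starved by the wide surroundings.
    """
    ivals = [(m - span * s, m + span * s) for m, s in zip(modes_i, sds_i)]
    ivals.append(guard)
    ivals.sort()
    clusters = []
    for lo, hi in ivals:
        if clusters and lo <= clusters[-1][0][1]:
            chi = max(clusters[-1][0][1], hi)
            clusters[-1] = ((clusters[-1][0][0], chi), clusters[-1][1] + [(lo, hi)])
        else:
            clusters.append(((lo, hi), [(lo, hi)]))
    atoms = []
    for (lo, hi), members in clusters:
        width = hi - lo
        narrow = [m for m in members if m[1] - m[0] < 0.25 * width]
        if not narrow:
            atoms.append((lo, hi))
            continue
        cuts = sorted({lo, hi} | {float(np.clip(e, lo, hi))
                                  for m in narrow for e in m})
        for a, b in zip(cuts[:-1], cuts[1:]):
            if b - a > 1e-12:
                atoms.append((a, b))
    return atoms


def quadrature_obs_loglik(
    spec: ModelSpec, theta: Theta, data: Dataset, cfg: QuadConfig = QuadConfig()
) -> np.ndarray:
    """Length-n vector of per-observation log marginal likelihoods."""
    theta.validate_for(spec)
    modes, sds = _candidate_modes(spec, theta, data)
    w = data.w
    out = np.empty(data.n)
    if cfg.rule == "fixed_node":
        nodes_full, wts_full = _leggauss_cached(cfg.node_count)
        small = max(101, cfg.node_count // 2 * 2 + 1)
        nodes_small, wts_small = _leggauss_cached(small)
        log_wts_full = np.log(wts_full)
        log_wts_small = np.log(wts_small)
        all_atoms = [
            _obs_atoms(modes[:, i], sds[:, i],
                       _guard_interval(spec, theta, data, i), cfg.span)
            for i in range(data.n)
        ]
        single = np.array([len(a) == 1 for a in all_atoms])
        if single.any():
            idx = np.flatnonzero(single)
            lo = np.array([all_atoms[i][0][0] for i in idx])
            hi = np.array([all_atoms[i][0][1] for i in idx])
            half = 0.5 * (hi - lo)
            x = lo[:, None] + half[:, None] * (nodes_full[None, :] + 1.0)
            logint = obs_log_joint(spec, theta, x, data.y[idx, None],
                                   None if w is None else w[idx, None])
            out[idx] = special.logsumexp(
                logint + log_wts_full[None, :], axis=1) + np.log(half)
        for i in np.flatnonzero(~single):
            xs, lw = [], []
            for a, b in all_atoms[i]:
                half = 0.5 * (b - a)
                xs.append(a + half * (nodes_small + 1.0))
                lw.append(log_wts_small + np.log(half))
            logint = obs_log_joint(spec, theta, np.concatenate(xs),
                                   data.y[i], None if w is None else w[i])
            out[i] = special.logsumexp(logint + np.concatenate(lw))
        return out
    for i in range(data.n):
        atoms = _obs_atoms(modes[:, i], sds[:, i],
                           _guard_interval(spec, theta, data, i), cfg.span)
        lo, hi = atoms[0][0], atoms[-1][1]
        shift = float(np.max(obs_log_joint(spec, theta, modes[:, i],
                                           data.y[i],
                                           None if w is None else w[i])))

        def f(x, _i=i, _s=shift):
            return np.exp(obs_log_joint(spec, theta, np.asarray(x),
                                        data.y[_i],
                                        None if w is None else w[_i]) - _s)

        pts = sorted({float(np.clip(m, lo, hi)) for m in modes[:, i]}
                     | {e for ab in atoms for e in ab if lo < e < hi})
        val, _ = integrate.quad(f, lo, hi, points=pts or None,
                                epsrel=cfg.rel_tol, epsabs=0.0, limit=300)
        if val <= 0:
            raise ArithmeticError(f"quadrature failed for observation {i}")
        out[i] = shift + np.log(val)
    return out


def quadrature_loglik(
    spec: ModelSpec, theta: Theta, data: Dataset, cfg: QuadConfig = QuadConfig()
) -> float:
    """Deterministic log marginal likelihood, summed over observations."""
    return float(np.sum(quadrature_obs_loglik(spec, theta, data, cfg)))


# ---------------------------------------------------------------------------
# simple Monte Carlo


def _latent_standard_draws(spec, n, M, seed):
    rng = np.random.default_rng(seed)
    if spec.has_covariate_observation:
        if spec.gaussian_latent_sd is not None:
            return rng.normal(size=(n, M)) * spec.gaussian_latent_sd
        return rng.standard_t(spec.latent_df, size=(n, M))
    return rng.normal(size=(n, M))  # location/scale applied per theta


def mc_loglik(
    spec: ModelSpec,
    theta: Theta,
    data: Dataset,
    M: int = 20000,
    seed: int = 0,
) -> tuple[float, float]:
    """Monte Carlo log marginal likelihood with delta-method standard error.

    Per observation, ``L_i = mean_j f(y_i | x_j) f(w_i | x_j)`` with
    ``x_j ~ g``.  The underlying standard draws depend only on ``seed``,
    so sweeping theta over a grid uses common random numbers and yields
    smooth curves.
    """
    if M < 100:
        raise ValueError("M must be >= 100")
    theta.validate_for(spec)
    z = _latent_standard_draws(spec, data.n, M, seed)
    if spec.family == "poisson_quadratic":
        from .models import QUADRATIC_LATENT_VAR

        x = theta["beta"] + np.sqrt(QUADRATIC_LATENT_VAR) * z
    elif spec.family == "variance_partition":
        x = theta["mu"] + np.sqrt(theta["tau2"]) * z
    else:
        x = z
    from .models import _response_loglik  # conditional density only

    logw = _response_loglik(spec, theta, x, data.y[:, None])
    if spec.has_covariate_observation:
        s1 = theta["sigma1"]
        logw = logw + stats.norm.logpdf(data.w[:, None], loc=x, scale=s1)
    shift = np.max(logw, axis=1)
    dead = ~np.isfinite(shift)
    if dead.any():
        warnings.warn(
            f"all Monte Carlo weights are zero for observations "
            f"{np.flatnonzero(dead).tolist()}",
            RuntimeWarning,
        )
        return -np.inf, np.nan
    u = np.exp(logw - shift[:, None])
    mean_u = u.mean(axis=1)
    se_i = u.std(axis=1, ddof=1) / (np.sqrt(M) * mean_u)
    value = float(np.sum(shift + np.log(mean_u)))
    return value, float(np.sqrt(np.sum(se_i**2)))


# ---------------------------------------------------------------------------
# likelihood curves


@dataclass
class LikelihoodCurve:
    """Log-likelihood values for one parameter on a grid, per method."""

    parameter_name: str
    grid: np.ndarray
    loglik_by_method: dict[str, np.ndarray]
    se_by_method: dict[str, np.ndarray] = field(default_factory=dict)
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        for name, ll in self.loglik_by_method.items():
            ll = np.asarray(ll, dtype=float)
            if ll.shape != self.grid.shape:
                raise ValueError(f"method {name!r} length mismatch")
            self.loglik_by_method[name] = ll

    @property
    def relative(self) -> dict[str, np.ndarray]:
        """Relative likelihood exp(l - max l) per method, in (0, 1]."""
        out = {}
        for name, ll in self.loglik_by_method.items():
            out[name] = np.exp(ll - np.nanmax(ll))
        return out

    def argmax(self, method: str) -> float:
        ll = self.loglik_by_method[method]
        return float(self.grid[int(np.nanargmax(ll))])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        rel = self.relative
        for name, ll in self.loglik_by_method.items():
            rows.append(pd.DataFrame({
                self.parameter_name: self.grid,
                "method": name,
                "loglik": ll,
                "relative": rel[name],
            }))
        return pd.concat(rows, ignore_index=True)


def likelihood_curve(
    spec: ModelSpec,
    data: Dataset,
    parameter_name: str,
    grid: Sequence[float],
    theta_fixed: Theta,
    methods: Mapping[str, Callable[[Theta], float]] | Sequence[str] = ("quadrature",),
    quad_cfg: QuadConfig = QuadConfig(),
    mc_M: int = 20000,
    mc_seed: int = 0,
) -> LikelihoodCurve:
    """Evaluate log-likelihood methods along a one-parameter grid.

    ``methods`` may name the built-in evaluators (``"quadrature"``,
    ``"mc"``) or map arbitrary labels to callables ``theta -> loglik``
    (used by the Laplace and importance-ratio routes).  A failure at a
    grid point is recorded as NaN, not raised.
    """
    grid = np.asarray(grid, dtype=float)
    if isinstance(methods, Mapping):
        evaluators = dict(methods)
    else:
        evaluators = {}
        for name in methods:
            if name == "quadrature":
                evaluators[name] = lambda th: quadrature_loglik(spec, th, data, quad_cfg)
            elif name == "mc":
                evaluators[name] = lambda th: mc_loglik(spec, th, data, mc_M, mc_seed)[0]
            else:
                raise ValueError(f"no built-in evaluator named {name!r}")
    loglik = {name: np.full(grid.size, np.nan) for name in evaluators}
    for j, v in enumerate(grid):
        theta = theta_fixed.replace(**{parameter_name: v})
        for name, fn in evaluators.items():
            try:
                loglik[name][j] = fn(theta)
            except Exception as exc:  # recorded as missing, not fatal
                warnings.warn(f"{name} failed at {parameter_name}={v}: {exc}",
                              RuntimeWarning)
    return LikelihoodCurve(parameter_name, grid, loglik)


# ---------------------------------------------------------------------------
# likelihood-ratio intervals


@dataclass(frozen=True)
class LrInterval:
    lower: float
    upper: float
    theta_hat: float
    loglik_max: float
    level: float
    open_lower: bool = False
    open_upper: bool = False

    def __iter__(self):
        return iter((self.lower, self.upper))

    def contains(self, value: float) -> bool:
        return self.lower <= value <= self.upper


def _curve_to_callable(curve: LikelihoodCurve, method: str | None):
    if method is None:
        method = next(iter(curve.loglik_by_method))
    ll = curve.loglik_by_method[method]
    grid = curve.grid

    def f(x):
        return float(np.interp(x, grid, ll))

    return f, (float(grid[0]), float(grid[-1]))


def lr_confidence_interval(
    loglik: Callable[[float], float] | LikelihoodCurve,
    level: float = 0.95,
    search_range: tuple[float, float] | None = None,
    method: str | None = None,
    xtol: float = 1e-4,
) -> LrInterval:
    """Invert the likelihood-ratio test for a scalar parameter.

    Returns the connected set ``{t : 2 (l(t_hat) - l(t)) <= chi2_1(level)}``
    around the maximizer, endpoints located by bisection to ``xtol``.
    Endpoints clipped by the search range are flagged open-ended.
    """
    if isinstance(loglik, LikelihoodCurve):
        loglik, rng = _curve_to_callable(loglik, method)
        search_range = search_range or rng
    if search_range is None:
        raise ValueError("search_range required for a callable log-likelihood")
    a, b = search_range
    res = optimize.minimize_scalar(
        lambda t: -loglik(t), bounds=(a, b), method="bounded",
        options={"xatol": min(xtol, 1e-5)},
    )
    that = float(res.x)
    lmax = float(-res.fun)
    if level >= 1.0:
        return LrInterval(a, b, that, lmax, level, True, True)
    cut = lmax - 0.5 * stats.chi2.ppf(level, df=1)

    def drop(t):
        return loglik(t) - cut

    if drop(a) < 0:
        lower, open_lo = float(optimize.brentq(drop, a, that, xtol=xtol)), False
    else:
        lower, open_lo = a, True
    if drop(b) < 0:
        upper, open_hi = float(optimize.brentq(drop, that, b, xtol=xtol)), False
    else:
        upper, open_hi = b, True
    return LrInterval(lower, upper, that, lmax, level, open_lo, open_hi)


# ---------------------------------------------------------------------------
# profile likelihood (quadrature gold standard)


def profile_loglik_oracle(
    spec: ModelSpec,
    data: Dataset,
    psi_name: str,
    psi_grid: Sequence[float],
    theta_init: Theta,
    cfg: QuadConfig = QuadConfig(),
    objective: Callable[[Theta], float] | None = None,
    method_label: str = "quadrature_profile",
) -> LikelihoodCurve:
    """Profile log-likelihood for ``psi`` by direct nuisance maximization.

    At each grid value the remaining free parameters are maximized
    (Nelder-Mead on log-transformed dispersions), warm-started from the
    previous grid point's optimum.
    """
    psi_grid = np.asarray(psi_grid, dtype=float)
    nuisance = [p for p in spec.free_parameters if p != psi_name]
    if objective is None:
        def objective(th):
            return quadrature_loglik(spec, th, data, cfg)
    values = np.full(psi_grid.size, np.nan)
    converged = np.zeros(psi_grid.size, dtype=bool)
    paths = []
    current = theta_init
    for j, psi in enumerate(psi_grid):
        base = current.replace(**{psi_name: psi})
        if not nuisance:
            values[j] = objective(base)
            converged[j] = True
            paths.append(base)
            current = base
            continue
        z0 = to_unconstrained(base, nuisance)

        def neg(z, _psi=psi):
            th = from_unconstrained(z, nuisance, base)
            try:
                return -objective(th)
            except Exception:
                return np.inf

        res = optimize.minimize(neg, z0, method="Nelder-Mead",
                                options={"xatol": 1e-6, "fatol": 1e-8,
                                         "maxiter": 400 * len(nuisance)})
        values[j] = -res.fun
        converged[j] = bool(res.success)
        current = from_unconstrained(res.x, nuisance, base)
        paths.append(current)
    curve = LikelihoodCurve(psi_name, psi_grid, {method_label: values})
    curve.extras["converged"] = converged
    curve.extras["nuisance_paths"] = paths
    return curve
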