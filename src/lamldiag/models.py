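"""Hierarchical model definitions and synthetic-data generation.

Six model families are supported, all with one scalar latent variable per
observation:

* Four errors-in-variables (EIV) regressions through the origin, where the
  covariate ``x_i`` is latent with a known wide distribution (Student-T with
  ``latent_df`` degrees of freedom by default), observed only through a noisy
  measurement ``w_i | x_i ~ Normal(x_i, sigma1^2)``, and the response is

  - ``normal_eiv``:  ``y_i | x_i ~ Normal(x_i * beta, sigma2^2)``
  - ``poisson_eiv``: ``y_i | x_i ~ Poisson(exp(x_i * beta))``
  - ``logit_eiv``:   ``y_i | x_i ~ Bernoulli(expit(x_i * beta))``
  - ``probit_eiv``:  ``y_i | x_i ~ Bernoulli(Phi(x_i * beta))``

* Two non-identifiable models:

  - ``poisson_quadratic``: ``y_i | x_i ~ Poisson(x_i^2)``, ``x_i ~ Normal(beta, 5)``
    (the sign of ``beta`` is not identifiable; the 5 is a variance);
  - ``variance_partition``: ``y_i | mu_i ~ Normal(mu_i, sigma2_obs)``,
    ``mu_i ~ Normal(mu, tau2)`` (only ``sigma2_obs + tau2`` is identifiable;
    both entries are variances).

For testing, the EIV families admit an all-Gaussian variant in which the
latent law is ``Normal(0, gaussian_latent_sd^2)``: there the conditional
law of the latent given the data is exactly Gaussian, so the Laplace
approximation to the marginal likelihood is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping

import json
import math

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "FAMILIES",
    "ModelSpec",
    "Theta",
    "Dataset",
    "simulate_dataset",
    "log_joint",
    "obs_log_joint",
    "dlog_joint_dx",
    "d2log_joint_dx2",
    "child_seed",
]

FAMILIES = (
    "normal_eiv",
    "poisson_eiv",
    "logit_eiv",
    "probit_eiv",
    "poisson_quadratic",
    "variance_partition",
)

_EIV = ("normal_eiv", "poisson_eiv", "logit_eiv", "probit_eiv")

# latent variance of x ~ N(beta, 5) in the quadratic-mean Poisson model
QUADRATIC_LATENT_VAR = 5.0

_POSITIVE = ("sigma1", "sigma2")          # SDs, strictly positive
_NONNEGATIVE = ("sigma2_obs", "tau2")     # variances, >= 0 (0 only on ridge ends)

_FREE_DEFAULT = {
    "normal_eiv": ("beta", "sigma1", "sigma2"),
    "poisson_eiv": ("beta", "sigma1"),
    "logit_eiv": ("beta", "sigma1"),
    "probit_eiv": ("beta", "sigma1"),
    "poisson_quadratic": ("beta",),
    "variance_partition": ("mu", "sigma2_obs", "tau2"),
}


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one hierarchical model family.

    Parameters
    ----------
    family:
        One of :data:`FAMILIES`.
    latent_df:
        Degrees of freedom of the standard Student-T latent law (EIV
        families only).
    free_parameters:
        Ordered names of the parameters treated as unknown; the rest are
        fixed at the values supplied in a :class:`Theta`.
    gaussian_latent_sd:
        If set (EIV families), replaces the T latent law with
        ``Normal(0, gaussian_latent_sd^2)`` — the all-Gaussian variant.
    """

    family: str
    latent_df: float | None = None
    free_parameters: tuple[str, ...] = ()
    gaussian_latent_sd: float | None = None

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.family in _EIV:
            if self.gaussian_latent_sd is None:
                if self.latent_df is None or self.latent_df <= 0:
                    raise ValueError("EIV families need latent_df > 0")
            elif self.gaussian_latent_sd <= 0:
                raise ValueError("gaussian_latent_sd must be > 0")
        if not self.free_parameters:
            object.__setattr__(
                self, "free_parameters", _FREE_DEFAULT[self.family]
            )
        allowed = set(_FREE_DEFAULT[self.family])
        if not set(self.free_parameters) <= allowed:
            raise ValueError(
                f"free_parameters {self.free_parameters} not a subset of "
                f"{sorted(allowed)} for family {self.family!r}"
            )

    @property
    def has_covariate_observation(self) -> bool:
        return self.family in _EIV

    @property
    def parameter_names(self) -> tuple[str, ...]:
        return _FREE_DEFAULT[self.family]

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "latent_df": self.latent_df,
            "free_parameters": list(self.free_parameters),
            "gaussian_latent_sd": self.gaussian_latent_sd,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelSpec":
        return cls(
            family=d["family"],
            latent_df=d.get("latent_df"),
            free_parameters=tuple(d.get("free_parameters") or ()),
            gaussian_latent_sd=d.get("gaussian_latent_sd"),
        )


class Theta(dict):
    """Named parameter map with positivity constraints enforced on entry."""

    def __init__(self, **values: float):
        for name, v in values.items():
            v = float(v)
            if name in _POSITIVE and v <= 0:
                raise ValueError(f"{name} must be > 0, got {v}")
            if name in _NONNEGATIVE and v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v}")
            self[name] = v

    def replace(self, **updates: float) -> "Theta":
        merged = dict(self)
        merged.update(updates)
        return Theta(**merged)

    def validate_for(self, spec: ModelSpec) -> None:
        missing = set(spec.parameter_names) - set(self)
        if missing:
            raise ValueError(f"theta missing parameters {sorted(missing)}")


@dataclass
class Dataset:
    """One simulated sample: responses ``y`` and, for EIV families, the
    error-prone covariate measurements ``w``."""

    y: np.ndarray
    w: np.ndarray | None = None
    true_theta: Theta | None = None
    seed: int | None = None
    x_true: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float)
        if self.y.ndim != 1 or self.y.size == 0:
            raise ValueError("y must be a non-empty 1-D array")
        if self.w is not None:
            self.w = np.asarray(self.w, dtype=float)
            if self.w.shape != self.y.shape:
                raise ValueError("w must match y in length")

    @property
    def n(self) -> int:
        return self.y.size

    def to_csv(self, path, sidecar: str | None = "auto") -> None:
        cols = {"y": self.y}
        if self.w is not None:
            cols["w"] = self.w
        pd.DataFrame(cols).to_csv(path, index=False)
        if sidecar:
            side = f"{path}.json" if sidecar == "auto" else sidecar
            meta = {
                "seed": self.seed,
                "true_theta": dict(self.true_theta) if self.true_theta else None,
            }
            with open(side, "w") as fh:
                json.dump(meta, fh, indent=1)

    @classmethod
    def from_csv(cls, path, sidecar=None) -> "Dataset":
        df = pd.read_csv(path)
        theta = seed = None
        if sidecar:
            with open(sidecar) as fh:
                meta = json.load(fh)
            seed = meta.get("seed")
            if meta.get("true_theta"):
                theta = Theta(**meta["true_theta"])
        return cls(
            y=df["y"].to_numpy(),
            w=df["w"].to_numpy() if "w" in df else None,
            true_theta=theta,
            seed=seed,
        )


def child_seed(root_seed: int, index: int) -> int:
    """Deterministic per-replicate seed below 2**31."""
    ss = np.random.SeedSequence(entropy=root_seed, spawn_key=(index,))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31 - 1))


# ---------------------------------------------------------------------------
# simulation


def simulate_dataset(spec: ModelSpec, theta: Theta, n: int, seed: int) -> Dataset:
    """Draw one synthetic dataset of size ``n`` from the model's generative
    law.  Identical ``(spec, theta, n, seed)`` give bit-identical output."""
    theta.validate_for(spec)
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)

    if spec.family in _EIV:
        if spec.gaussian_latent_sd is not None:
            x = rng.normal(0.0, spec.gaussian_latent_sd, size=n)
        else:
            x = rng.standard_t(spec.latent_df, size=n)
        w = rng.normal(x, theta["sigma1"])
        eta = x * theta["beta"]
        if spec.family == "normal_eiv":
            y = rng.normal(eta, theta["sigma2"])
        elif spec.family == "poisson_eiv":
            # heavy-tailed latents occasionally give astronomical means;
            # there the Poisson is indistinguishable from N(lam, lam)
            lam = np.exp(np.minimum(eta, 700.0))  # keep lam finite
            big = lam > 1e12
            y = np.where(big, np.round(lam + np.sqrt(lam) *
                                       rng.standard_normal(n)),
                         rng.poisson(np.where(big, 1.0, lam))).astype(float)
        elif spec.family == "logit_eiv":
            y = rng.binomial(1, special.expit(eta)).astype(float)
        else:  # probit_eiv
            y = rng.binomial(1, special.ndtr(eta)).astype(float)
        return Dataset(y=y, w=w, true_theta=theta, seed=seed, x_true=x)

    if spec.family == "poisson_quadratic":
        x = rng.normal(theta["beta"], math.sqrt(QUADRATIC_LATENT_VAR), size=n)
        y = rng.poisson(x**2).astype(float)
        return Dataset(y=y, w=None, true_theta=theta, seed=seed, x_true=x)

    # variance_partition
    x = rng.normal(theta["mu"], math.sqrt(theta["tau2"]), size=n)
    y = rng.normal(x, math.sqrt(theta["sigma2_obs"]))
    return Dataset(y=y, w=None, true_theta=theta, seed=seed, x_true=x)


# ---------------------------------------------------------------------------
# joint log-density and latent derivatives
#
# All pieces broadcast: x may be shaped (n,), (n, M), ... with y (and w)
# broadcast against it, so quadrature and Monte Carlo sweeps are vectorized.


@lru_cache(maxsize=32)
def _t_logconst(df: float) -> float:
    return float(special.gammaln((df + 1.0) / 2.0) - special.gammaln(df / 2.0)
                 - 0.5 * math.log(df * math.pi))


def _latent_logpdf(spec, theta, x):
    if spec.family in _EIV:
        if spec.gaussian_latent_sd is not None:
            s = spec.gaussian_latent_sd
            return -0.5 * math.log(2 * math.pi) - math.log(s) - 0.5 * (x / s) ** 2
        df = spec.latent_df
        return _t_logconst(df) - 0.5 * (df + 1.0) * np.log1p(x**2 / df)
    if spec.family == "poisson_quadratic":
        v = QUADRATIC_LATENT_VAR
        return -0.5 * math.log(2 * math.pi * v) - 0.5 * (x - theta["beta"]) ** 2 / v
    t2 = theta["tau2"]
    if t2 == 0.0:
        return np.where(x == theta["mu"], 0.0, -np.inf)
    return -0.5 * np.log(2 * math.pi * t2) - 0.5 * (x - theta["mu"]) ** 2 / t2


def _dlatent(spec, theta, x):
    if spec.family in _EIV:
        if spec.gaussian_latent_sd is not None:
            return -x / spec.gaussian_latent_sd**2
        df = spec.latent_df
        return -(df + 1.0) * x / (df + x**2)
    if spec.family == "poisson_quadratic":
        return -(x - theta["beta"]) / QUADRATIC_LATENT_VAR
    return -(x - theta["mu"]) / theta["tau2"]


def _d2latent(spec, theta, x):
    if spec.family in _EIV:
        if spec.gaussian_latent_sd is not None:
            return np.broadcast_to(-1.0 / spec.gaussian_latent_sd**2, np.shape(x)).copy()
        df = spec.latent_df
        return -(df + 1.0) * (df - x**2) / (df + x**2) ** 2
    if spec.family == "poisson_quadratic":
        return np.broadcast_to(-1.0 / QUADRATIC_LATENT_VAR, np.shape(x)).copy()
    return np.broadcast_to(-1.0 / theta["tau2"], np.shape(x)).copy()


def _response_loglik(spec, theta, x, y):
    fam = spec.family
    if fam == "normal_eiv":
        s2 = theta["sigma2"]
        return -0.5 * math.log(2 * math.pi) - math.log(s2) \
            - 0.5 * ((y - x * theta["beta"]) / s2) ** 2
    if fam == "poisson_eiv":
        eta = x * theta["beta"]
        with np.errstate(over="ignore"):
            return y * eta - np.exp(eta) - special.gammaln(y + 1.0)
    if fam == "logit_eiv":
        eta = x * theta["beta"]
        # y*eta - log(1+exp(eta)) computed stably
        return y * eta - np.logaddexp(0.0, eta)
    if fam == "probit_eiv":
        eta = x * theta["beta"]
        return np.where(y > 0.5, special.log_ndtr(eta), special.log_ndtr(-eta))
    if fam == "poisson_quadratic":
        lam = x**2
        with np.errstate(divide="ignore", invalid="ignore"):
            out = special.xlogy(y, lam) - lam - special.gammaln(y + 1.0)
        return np.where((lam == 0) & (y > 0), -np.inf, out)
    # variance_partition: y | mu_i ~ N(x, sigma2_obs)
    v = theta["sigma2_obs"]
    if v == 0.0:
        return np.where(y == x, 0.0, -np.inf)
    return -0.5 * np.log(2 * math.pi * v) - 0.5 * (y - x) ** 2 / v


def _dresponse(spec, theta, x, y):
    fam = spec.family
    b = theta.get("beta")
    if fam == "normal_eiv":
        return b * (y - x * b) / theta["sigma2"] ** 2
    if fam == "poisson_eiv":
        with np.errstate(over="ignore"):
            return b * (y - np.exp(x * b))
    if fam == "logit_eiv":
        return b * (y - special.expit(x * b))
    if fam == "probit_eiv":
        eta = x * b
        lam = np.exp(stats.norm.logpdf(eta) - special.log_ndtr(eta))
        mil = np.exp(stats.norm.logpdf(eta) - special.log_ndtr(-eta))
        return b * np.where(y > 0.5, lam, -mil)
    if fam == "poisson_quadratic":
        xs = np.where(np.abs(x) < 1e-8, 1e-8, x)
        return np.where(y > 0, 2.0 * y / xs, 0.0) - 2.0 * x
    return (y - x) / theta["sigma2_obs"]


def _d2response(spec, theta, x, y):
    fam = spec.family
    b = theta.get("beta")
    if fam == "normal_eiv":
        return np.broadcast_to(-(b / theta["sigma2"]) ** 2, np.shape(x)).copy()
    if fam == "poisson_eiv":
        with np.errstate(over="ignore"):
            return -(b**2) * np.exp(x * b)
    if fam == "logit_eiv":
        p = special.expit(x * b)
        return -(b**2) * p * (1.0 - p)
    if fam == "probit_eiv":
        eta = x * b
        lam = np.exp(stats.norm.logpdf(eta) - special.log_ndtr(eta))
        mil = np.exp(stats.norm.logpdf(eta) - special.log_ndtr(-eta))
        return b**2 * np.where(y > 0.5, -lam * (eta + lam), mil * (eta - mil))
    if fam == "poisson_quadratic":
        xs = np.where(np.abs(x) < 1e-8, 1e-8, x)
        return np.where(y > 0, -2.0 * y / xs**2, 0.0) - 2.0
    return np.broadcast_to(-1.0 / theta["sigma2_obs"], np.shape(x)).copy()


def obs_log_joint(spec: ModelSpec, theta: Theta, x, y, w=None):
    """Per-observation log joint ``log f(y|x) + log f(w|x) + log g(x)``.

    Broadcasts over ``x``; used directly by the quadrature and Monte Carlo
    marginal likelihoods.
    """
    x = np.asarray(x, dtype=float)
    out = _response_loglik(spec, theta, x, y) + _latent_logpdf(spec, theta, x)
    if spec.has_covariate_observation:
        if w is None:
            raise ValueError(f"family {spec.family} requires w")
        s1 = theta["sigma1"]
        out = out - 0.5 * math.log(2 * math.pi) - math.log(s1) \
            - 0.5 * ((w - x) / s1) ** 2
    return out


def _check_dims(spec, x, data):
    x = np.asarray(x, dtype=float)
    if x.shape[0] != data.n:
        raise ValueError(f"latent vector length {x.shape[0]} != n={data.n}")
    return x


def log_joint(spec: ModelSpec, theta: Theta, x, data: Dataset) -> float:
    """Joint log-density of ``(y, w, x)`` summed over observations."""
    theta.validate_for(spec)
    x = _check_dims(spec, x, data)
    return float(np.sum(obs_log_joint(spec, theta, x, data.y, data.w)))


def dlog_joint_dx(spec: ModelSpec, theta: Theta, x, data: Dataset) -> np.ndarray:
    """Componentwise first derivative of the log joint in the latents."""
    x = _check_dims(spec, x, data)
    g = _dresponse(spec, theta, x, data.y) + _dlatent(spec, theta, x)
    if spec.has_covariate_observation:
        g = g + (data.w - x) / theta["sigma1"] ** 2
    return np.asarray(g, dtype=float)


def d2log_joint_dx2(spec: ModelSpec, theta: Theta, x, data: Dataset) -> np.ndarray:
    """Componentwise second derivative (diagonal Hessian) of the log joint.

    The Hessian over the full latent vector is diagonal because latents are
    conditionally independent across observations.
    """
    x = _check_dims(spec, x, data)
    h = _d2response(spec, theta, x, data.y) + _d2latent(spec, theta, x)
    if spec.has_covariate_observation:
        h = h - 1.0 / theta["sigma1"] ** 2
    return np.asarray(h, dtype=float)
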