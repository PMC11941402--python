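"""Laplace approximation: inner modes, exactness, bias, MLE machinery."""

import numpy as np
import pytest

from lamldiag import (InnerConfig, ModelSpec, Theta, inner_modes, laml_loglik,
                      laml_mle, profile_laml, quadrature_loglik,
                      simulate_dataset)
from lamldiag.models import dlog_joint_dx

from conftest import random_theta


def test_inner_modes_gaussian_closed_form():
    """All-Gaussian variant: the latent mode is the posterior-precision
    weighted average of prior mean (0), w/sigma1^2 and beta*y/sigma2^2."""
    spec = ModelSpec("normal_eiv", gaussian_latent_sd=2.0,
                     free_parameters=("beta",))
    theta = Theta(beta=0.7, sigma1=1.3, sigma2=0.8)
    d = simulate_dataset(spec, theta, 15, seed=2)
    u, h, info = inner_modes(spec, theta, d)
    prec = 1 / 4 + 1 / 1.3**2 + 0.7**2 / 0.8**2
    expected = (d.w / 1.3**2 + 0.7 * d.y / 0.8**2) / prec
    np.testing.assert_allclose(u, expected, atol=1e-8)
    np.testing.assert_allclose(h, -prec, atol=1e-10)
    assert info["converged"]


@pytest.mark.parametrize("family,df", [("normal_eiv", 2), ("poisson_eiv", 2),
                                       ("logit_eiv", 10), ("probit_eiv", 10)])
def test_inner_gradient_vanishes_at_mode(family, df):
    spec = ModelSpec(family, latent_df=df)
    rng = np.random.default_rng(3)
    theta = random_theta(spec, rng)
    d = simulate_dataset(spec, theta, 20, seed=8)
    u, h, _ = inner_modes(spec, theta, d)
    g = dlog_joint_dx(spec, theta, u, d)
    assert np.max(np.abs(g)) < 1e-7
    assert np.all(h < 0)


def test_multistart_finds_two_modes_quadratic_poisson():
    """Poisson(x^2) conditional densities are bimodal in x for y > 0:
    multistart must flag distinct local maxima, confirmed by a grid scan."""
    spec = ModelSpec("poisson_quadratic")
    theta = Theta(beta=2.0)
    d = simulate_dataset(spec, theta, 30, seed=3)
    _, _, info = inner_modes(spec, theta, d,
                             InnerConfig(start_policy="multistart"))
    assert info["distinct_inner_modes"] > 0
    # independent confirmation on the first y>0 observation: scan the joint
    from lamldiag.models import obs_log_joint
    i = int(np.argmax(d.y > 0))
    half = np.sqrt(d.y[i]) + 4.0
    xs = np.linspace(-half, half, 2001)
    f = obs_log_joint(spec, theta, xs, d.y[i], None)
    interior = (f[1:-1] > f[:-2]) & (f[1:-1] > f[2:])
    assert interior.sum() >= 2


def test_gaussian_exactness_master(gaussian_variant):
    """Laplace equals the exact marginal log-likelihood when the conditional
    latent law is Gaussian — for any theta and dataset."""
    spec, _ = gaussian_variant
    rng = np.random.default_rng(5)
    for k in range(10):
        theta = random_theta(spec, rng)
        d = simulate_dataset(spec, theta, 12, seed=200 + k)
        assert laml_loglik(spec, theta, d) == pytest.approx(
            quadrature_loglik(spec, theta, d), abs=1e-8)


def test_laml_determinism(ex1a_dataset):
    spec, theta, d = ex1a_dataset
    assert laml_loglik(spec, theta, d) == laml_loglik(spec, theta, d)
    f1 = laml_mle(spec, d, theta, free=["beta"])
    f2 = laml_mle(spec, d, theta, free=["beta"])
    assert f1.theta_hat == f2.theta_hat
    assert f1.loglik == f2.loglik


def test_laml_argmax_mislocated_ex1a(ex1a_dataset):
    """At (beta=-1, sigma1=3, sigma2=2, T2 latent) the Laplace curve peaks
    at a different location than the exact likelihood."""
    spec, theta, d = ex1a_dataset
    grid = np.linspace(-2.0, 0.0, 41)
    ll_q = [quadrature_loglik(spec, theta.replace(beta=float(b)), d)
            for b in grid]
    ll_l = [laml_loglik(spec, theta.replace(beta=float(b)), d) for b in grid]
    b_q = grid[int(np.argmax(ll_q))]
    b_l = grid[int(np.argmax(ll_l))]
    assert abs(b_q - b_l) > 0.1


def test_laml_mle_matches_oracle_in_gaussian_case(gaussian_variant):
    """Identical objectives imply identical maximizers."""
    spec, theta = gaussian_variant
    d = simulate_dataset(spec, theta, 30, seed=9)
    fit = laml_mle(spec, d, theta, free=["beta"])
    from lamldiag import lr_confidence_interval
    iv = lr_confidence_interval(
        lambda b: quadrature_loglik(spec, theta.replace(beta=b), d),
        search_range=(-2, 4))
    assert fit.theta_hat["beta"] == pytest.approx(iv.theta_hat, abs=1e-4)
    assert fit.wald_se is not None and fit.wald_se["beta"] > 0


def test_laml_mle_stable_under_perturbed_start(ex1a_dataset):
    spec, theta, d = ex1a_dataset
    f1 = laml_mle(spec, d, theta.replace(beta=-0.5), free=["beta"])
    f2 = laml_mle(spec, d, theta.replace(beta=-1.5), free=["beta"])
    assert f1.theta_hat["beta"] == pytest.approx(f2.theta_hat["beta"],
                                                 abs=1e-4)


def test_profile_laml_single_parameter_reduces_to_curve(ex1a_dataset):
    spec, theta, d = ex1a_dataset
    grid = np.linspace(-1.5, -0.5, 5)
    prof = profile_laml(spec, d, "beta", grid, theta)
    direct = [laml_loglik(spec, theta.replace(beta=float(b)), d) for b in grid]
    np.testing.assert_allclose(prof.loglik_by_method["laml_profile"], direct,
                               atol=1e-10)


def test_variance_partition_fit_start_dependent_on_ridge():
    """Non-identifiable variance split: outer fits from different starts
    stop at materially different ridge points (similar loglik, different
    variance partition)."""
    spec = ModelSpec("variance_partition")
    theta = Theta(mu=0.0, sigma2_obs=1.0, tau2=1.0)
    d = simulate_dataset(spec, theta, 40, seed=12)
    s2 = float(np.var(d.y))
    f_lo = laml_mle(spec, d, Theta(mu=0.0, sigma2_obs=0.9 * s2,
                                   tau2=0.1 * s2), n_restarts=1)
    f_hi = laml_mle(spec, d, Theta(mu=0.0, sigma2_obs=0.1 * s2,
                                   tau2=0.9 * s2), n_restarts=1)
    assert f_lo.loglik == pytest.approx(f_hi.loglik, abs=0.05)
    assert abs(f_lo.theta_hat["tau2"] - f_hi.theta_hat["tau2"]) > 0.2
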