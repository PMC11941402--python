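"""Quadrature and Monte Carlo marginal likelihoods against closed forms."""

import numpy as np
import pytest
from scipy import stats

from lamldiag import (Dataset, ModelSpec, QuadConfig, Theta,
                      likelihood_curve, lr_confidence_interval, mc_loglik,
                      profile_loglik_oracle, quadrature_loglik,
                      simulate_dataset)

from conftest import all_specs, random_theta


def test_quadrature_matches_bivariate_normal_closed_form(gaussian_variant):
    """All-Gaussian variant: (y, w) is bivariate normal, so the marginal
    log-likelihood has a closed form.  beta=1, all scales 1 gives
    covariance [[2, 1], [1, 2]]."""
    spec, theta = gaussian_variant
    d = Dataset(y=np.array([0.0]), w=np.array([0.0]))
    expected = stats.multivariate_normal(
        mean=[0, 0], cov=[[2.0, 1.0], [1.0, 2.0]]).logpdf([0.0, 0.0])
    assert quadrature_loglik(spec, theta, d) == pytest.approx(expected,
                                                              abs=1e-10)
    # and on a simulated sample of nontrivial size
    d2 = simulate_dataset(spec, theta, 25, seed=1)
    cov = np.array([[2.0, 1.0], [1.0, 2.0]])
    expected2 = stats.multivariate_normal(mean=[0, 0], cov=cov).logpdf(
        np.column_stack([d2.y, d2.w])).sum()
    assert quadrature_loglik(spec, theta, d2) == pytest.approx(expected2,
                                                               abs=1e-8)


def test_quadrature_matches_variance_partition_closed_form():
    """y_i ~ N(mu, sigma2_obs + tau2) marginally."""
    spec = ModelSpec("variance_partition")
    theta = Theta(mu=0.3, sigma2_obs=1.2, tau2=0.7)
    d = simulate_dataset(spec, theta, 30, seed=5)
    expected = stats.norm.logpdf(d.y, 0.3, np.sqrt(1.9)).sum()
    assert quadrature_loglik(spec, theta, d) == pytest.approx(expected,
                                                              abs=1e-8)


def test_variance_partition_ridge_flatness():
    """The exact likelihood is constant along sigma2_obs + tau2 = c."""
    spec = ModelSpec("variance_partition")
    theta = Theta(mu=0.0, sigma2_obs=1.0, tau2=1.0)
    d = simulate_dataset(spec, theta, 40, seed=2)
    vals = [quadrature_loglik(
        spec, Theta(mu=0.0, sigma2_obs=2.0 - t, tau2=t), d)
        for t in (0.2, 0.7, 1.2, 1.8)]
    assert max(vals) - min(vals) < 1e-6


def test_fixed_node_agrees_with_adaptive_and_converges(ex1a_dataset):
    spec, theta, d = ex1a_dataset
    fixed = quadrature_loglik(spec, theta, d, QuadConfig(node_count=201))
    adaptive = quadrature_loglik(spec, theta, d, QuadConfig(rule="adaptive"))
    assert fixed == pytest.approx(adaptive, abs=1e-3)
    doubled = quadrature_loglik(spec, theta, d, QuadConfig(node_count=401))
    redoubled = quadrature_loglik(spec, theta, d, QuadConfig(node_count=801))
    assert abs(doubled - redoubled) < 1e-6


@pytest.mark.parametrize("spec", all_specs(), ids=lambda s: s.family)
def test_mc_agrees_with_quadrature(spec):
    """Monte Carlo and quadrature marginal log-likelihoods agree within
    Monte Carlo error over random (theta, dataset) draws.

    Slopes are drawn at the magnitude of the demonstration settings
    (|beta| <= 1.25): prior-sampling Monte Carlo is the gold standard only
    where the latent prior overlaps the conditional spike, which fails for
    the astronomical counts a T2 latent can produce at larger |beta|.
    """
    rng = np.random.default_rng(11)
    n_bad = 0
    for k in range(5):
        theta = random_theta(spec, rng)
        if "beta" in theta:
            theta = theta.replace(beta=np.clip(theta["beta"], -1.25, 1.25))
        d = simulate_dataset(spec, theta, 15, seed=100 + k)
        q = quadrature_loglik(spec, theta, d)
        mc, se = mc_loglik(spec, theta, d, M=20000, seed=k)
        n_bad += abs(mc - q) >= 3 * se
    assert n_bad <= 1


def test_mc_se_scaling(ex1a_dataset):
    """Standard error shrinks like M^{-1/2}."""
    spec, theta, d = ex1a_dataset
    _, se1 = mc_loglik(spec, theta, d, M=5000, seed=3)
    _, se4 = mc_loglik(spec, theta, d, M=20000, seed=3)
    assert 0.35 < se4 / se1 < 0.65


def test_mc_common_random_numbers_smooth(ex1a_dataset):
    """Same seed across theta: the Monte Carlo error drifts smoothly along
    the grid instead of jittering independently, so successive increments
    of (mc - quadrature) are far smaller than the pointwise MC SE."""
    spec, theta, d = ex1a_dataset
    grid = np.linspace(-1.3, -0.7, 7)
    mc = np.array([mc_loglik(spec, theta.replace(beta=float(b)), d,
                             M=4000, seed=9)[0] for b in grid])
    q = np.array([quadrature_loglik(spec, theta.replace(beta=float(b)), d)
                  for b in grid])
    se = mc_loglik(spec, theta, d, M=4000, seed=9)[1]
    assert np.max(np.abs(np.diff(mc - q))) < se
    # and the estimator is reproducible under the same seed
    again = mc_loglik(spec, theta, d, M=4000, seed=9)[0]
    assert again == mc_loglik(spec, theta, d, M=4000, seed=9)[0]


def test_likelihood_curve_normalization_and_failures(ex1a_dataset):
    spec, theta, d = ex1a_dataset
    grid = np.linspace(-2.0, 0.0, 9)
    curve = likelihood_curve(spec, d, "beta", grid, theta, ("quadrature",))
    rel = curve.relative["quadrature"]
    assert rel.max() == pytest.approx(1.0)
    assert np.all(rel > 0) and np.all(rel <= 1.0)

    def flaky(th):
        if th["beta"] > -0.5:
            raise RuntimeError("boom")
        return quadrature_loglik(spec, th, d)

    with pytest.warns(RuntimeWarning):
        curve2 = likelihood_curve(spec, d, "beta", grid, theta,
                                  {"flaky": flaky})
    assert np.isnan(curve2.loglik_by_method["flaky"][-1])
    assert np.isfinite(curve2.loglik_by_method["flaky"][0])


def test_lr_interval_exact_normal_mean():
    """Known-variance normal mean: the LR interval is xbar +- 1.96 sigma/sqrt(n)."""
    rng = np.random.default_rng(0)
    y = rng.normal(1.0, 2.0, size=40)

    def ll(mu):
        return float(stats.norm.logpdf(y, mu, 2.0).sum())

    iv = lr_confidence_interval(ll, level=0.95, search_range=(-5, 5))
    half = stats.norm.ppf(0.975) * 2.0 / np.sqrt(40)
    assert iv.lower == pytest.approx(y.mean() - half, abs=1e-3)
    assert iv.upper == pytest.approx(y.mean() + half, abs=1e-3)
    assert iv.lower <= iv.theta_hat <= iv.upper
    assert not (iv.open_lower or iv.open_upper)


def test_lr_interval_width_shrinks_with_n():
    spec = ModelSpec("normal_eiv", latent_df=2, free_parameters=("beta",))
    theta = Theta(beta=-1.0, sigma1=3.0, sigma2=2.0)
    widths = []
    for n in (25, 100, 400):
        d = simulate_dataset(spec, theta, n, seed=4)
        iv = lr_confidence_interval(
            lambda b: quadrature_loglik(spec, theta.replace(beta=b), d),
            search_range=(-4, 2))
        widths.append(iv.upper - iv.lower)
    # each 4x increase in n should shrink the width by roughly half
    assert widths[1] / widths[0] < 0.75
    assert widths[2] / widths[1] < 0.75


def test_poisson_quadratic_sign_symmetry():
    """Only |beta| enters the marginal law, so the likelihood is even."""
    spec = ModelSpec("poisson_quadratic")
    theta = Theta(beta=2.0)
    d = simulate_dataset(spec, theta, 30, seed=3)
    grid = np.linspace(-3.0, 3.0, 13)
    ll = np.array([quadrature_loglik(spec, theta.replace(beta=float(b)), d)
                   for b in grid])
    assert np.max(np.abs(ll - ll[::-1])) < 1e-6


def test_profile_reduces_to_curve_without_nuisance(ex1a_dataset):
    spec, theta, d = ex1a_dataset  # free_parameters = (beta,) only
    grid = np.linspace(-1.4, -0.6, 5)
    prof = profile_loglik_oracle(spec, d, "beta", grid, theta)
    direct = [quadrature_loglik(spec, theta.replace(beta=float(b)), d)
              for b in grid]
    np.testing.assert_allclose(prof.loglik_by_method["quadrature_profile"],
                               direct, atol=1e-10)


def test_profile_dominates_slice():
    """Profile >= any fixed-nuisance slice, with equality at the slice's
    nuisance optimum; profile max equals the full MLE's loglik."""
    spec = ModelSpec("normal_eiv", latent_df=2,
                     free_parameters=("beta", "sigma2"))
    theta = Theta(beta=-1.0, sigma1=3.0, sigma2=2.0)
    d = simulate_dataset(spec, theta, 25, seed=6)
    grid = np.array([-1.4, -1.0, -0.6])
    prof = profile_loglik_oracle(spec, d, "beta", grid, theta)
    pvals = prof.loglik_by_method["quadrature_profile"]
    slice_vals = [quadrature_loglik(spec, theta.replace(beta=float(b)), d)
                  for b in grid]
    assert np.all(pvals >= np.asarray(slice_vals) - 1e-6)
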