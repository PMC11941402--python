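"""Generative laws, joint densities and analytic latent derivatives."""

import numpy as np
import pytest
from scipy import stats

from lamldiag import (Dataset, ModelSpec, Theta, d2log_joint_dx2,
                      dlog_joint_dx, log_joint, simulate_dataset)
from lamldiag.models import obs_log_joint

from conftest import all_specs, random_theta


@pytest.mark.parametrize("spec", all_specs(), ids=lambda s: s.family)
def test_simulator_determinism_and_support(spec):
    theta = random_theta(spec, np.random.default_rng(1))
    d1 = simulate_dataset(spec, theta, 40, seed=123)
    d2 = simulate_dataset(spec, theta, 40, seed=123)
    assert np.array_equal(d1.y, d2.y)
    if spec.has_covariate_observation:
        assert np.array_equal(d1.w, d2.w)
        assert d1.w.shape == (40,)
    else:
        assert d1.w is None
    if spec.family in ("poisson_eiv", "poisson_quadratic"):
        assert np.all(d1.y >= 0) and np.all(d1.y == np.round(d1.y))
    if spec.family in ("logit_eiv", "probit_eiv"):
        assert set(np.unique(d1.y)) <= {0.0, 1.0}
    d3 = simulate_dataset(spec, theta, 40, seed=124)
    assert not np.array_equal(d1.y, d3.y)


def test_simulator_rejects_bad_inputs():
    spec = ModelSpec("normal_eiv", latent_df=2)
    with pytest.raises(ValueError):
        simulate_dataset(spec, Theta(beta=0.0, sigma1=1.0, sigma2=1.0), 0, 1)
    with pytest.raises(ValueError):
        Theta(beta=0.0, sigma1=-1.0, sigma2=1.0)
    with pytest.raises(ValueError):
        # poisson_eiv has no sigma2
        ModelSpec("poisson_eiv", latent_df=2,
                  free_parameters=("beta", "sigma2"))


def test_moments_of_generative_law():
    """Marginal moments of y match the law of total mean/variance at large n.

    For y = beta*x + eps with x ~ T10 independent of eps ~ N(0, sigma2^2):
    E[y] = 0 and Var[y] = beta^2 * df/(df-2) + sigma2^2.
    """
    spec = ModelSpec("normal_eiv", latent_df=10)
    theta = Theta(beta=0.5, sigma1=1.0, sigma2=1.0)
    d = simulate_dataset(spec, theta, 20000, seed=42)
    var_y = 0.5**2 * (10 / 8) + 1.0
    se_mean = np.sqrt(var_y / 20000)
    assert abs(d.y.mean()) < 4 * se_mean
    assert abs(d.y.var() - var_y) / var_y < 0.05
    # w = x + noise: Var[w] = df/(df-2) + sigma1^2
    var_w = 10 / 8 + 1.0
    assert abs(d.w.var() - var_w) / var_w < 0.05


def test_log_joint_closed_form_single_point():
    """Joint at one point equals the sum of the three standard log-densities."""
    spec = ModelSpec("normal_eiv", latent_df=2)
    theta = Theta(beta=0.0, sigma1=1.0, sigma2=1.0)
    d = Dataset(y=np.array([0.0]), w=np.array([0.0]))
    expected = (stats.norm.logpdf(0.0, 0.0, 1.0) * 2
                + stats.t.logpdf(0.0, df=2))
    assert log_joint(spec, theta, np.array([0.0]), d) == pytest.approx(
        expected, abs=1e-12)


def test_log_joint_additivity():
    spec = ModelSpec("poisson_eiv", latent_df=2)
    theta = Theta(beta=-1.0, sigma1=3.0)
    d = simulate_dataset(spec, theta, 2, seed=5)
    x = np.array([0.3, -0.7])
    parts = [log_joint(spec, theta, x[i : i + 1],
                       Dataset(y=d.y[i : i + 1], w=d.w[i : i + 1]))
             for i in range(2)]
    assert log_joint(spec, theta, x, d) == pytest.approx(sum(parts), abs=1e-12)


def test_poisson_zero_count_term():
    """Poisson pmf at y=0 contributes exactly -exp(x*beta) to the joint."""
    spec = ModelSpec("poisson_eiv", latent_df=2)
    theta = Theta(beta=0.5, sigma1=1.0)
    x, w = 0.8, 0.2
    with_y0 = obs_log_joint(spec, theta, x, 0.0, w)
    # subtracting the w and latent terms leaves the response term
    resp = with_y0 - (stats.norm.logpdf(w, x, 1.0) + stats.t.logpdf(x, df=2))
    assert resp == pytest.approx(-np.exp(x * 0.5), abs=1e-12)


@pytest.mark.parametrize("spec", all_specs(), ids=lambda s: s.family)
def test_derivatives_match_finite_differences(spec):
    """Analytic d/dx and d2/dx2 of the log joint vs central differences at
    random interior points, 20 draws per family."""
    rng = np.random.default_rng(7)
    for _ in range(20):
        theta = random_theta(spec, rng)
        d = simulate_dataset(spec, theta, 6, seed=int(rng.integers(1e6)))
        x = np.asarray(d.x_true) + rng.normal(scale=0.3, size=6)
        if spec.family == "poisson_quadratic":
            x = np.where(np.abs(x) < 0.05, 0.5, x)  # keep clear of the pole
        h = 1e-5 * np.maximum(1.0, np.abs(x))
        f = lambda z: obs_log_joint(spec, theta, z, d.y, d.w)
        g_num = (f(x + h) - f(x - h)) / (2 * h)
        h_num = (f(x + h) - 2 * f(x) + f(x - h)) / h**2
        np.testing.assert_allclose(dlog_joint_dx(spec, theta, x, d), g_num,
                                   rtol=1e-5, atol=1e-5)
        np.testing.assert_allclose(d2log_joint_dx2(spec, theta, x, d), h_num,
                                   rtol=1e-3, atol=1e-3)


def test_normal_gaussian_variant_constant_curvature():
    """With Gaussian latent and Gaussian response, the log joint is exactly
    quadratic in x: its second derivative is constant."""
    spec = ModelSpec("normal_eiv", gaussian_latent_sd=2.0)
    theta = Theta(beta=0.7, sigma1=1.3, sigma2=0.8)
    d = simulate_dataset(spec, theta, 5, seed=3)
    h1 = d2log_joint_dx2(spec, theta, np.zeros(5), d)
    h2 = d2log_joint_dx2(spec, theta, np.full(5, 4.2), d)
    np.testing.assert_allclose(h1, h2, rtol=0, atol=1e-12)
    expected = -(1 / 4 + 1 / 1.3**2 + 0.7**2 / 0.8**2)
    np.testing.assert_allclose(h1, expected, atol=1e-12)


def test_dataset_csv_roundtrip(tmp_path):
    spec = ModelSpec("normal_eiv", latent_df=2)
    theta = Theta(beta=-1.0, sigma1=3.0, sigma2=2.0)
    d = simulate_dataset(spec, theta, 10, seed=9)
    p = tmp_path / "d.csv"
    d.to_csv(p)
    back = Dataset.from_csv(p, sidecar=f"{p}.json")
    np.testing.assert_allclose(back.y, d.y)
    np.testing.assert_allclose(back.w, d.w)
    assert back.seed == 9
    assert back.true_theta == theta
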