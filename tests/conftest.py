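import numpy as np
import pytest

from lamldiag import ModelSpec, Theta, simulate_dataset


@pytest.fixture(scope="session")
def eiv_specs():
    """The four errors-in-variables families at their demonstration settings."""
    return {
        "normal_eiv": (ModelSpec("normal_eiv", latent_df=2,
                                 free_parameters=("beta",)),
                       Theta(beta=-1.0, sigma1=3.0, sigma2=2.0)),
        "poisson_eiv": (ModelSpec("poisson_eiv", latent_df=2,
                                  free_parameters=("beta",)),
                        Theta(beta=-1.0, sigma1=3.0)),
        "logit_eiv": (ModelSpec("logit_eiv", latent_df=10,
                                free_parameters=("beta",)),
                      Theta(beta=-1.0, sigma1=3.0)),
        "probit_eiv": (ModelSpec("probit_eiv", latent_df=10,
                                 free_parameters=("beta",)),
                       Theta(beta=-1.0, sigma1=3.0)),
    }


@pytest.fixture(scope="session")
def gaussian_variant():
    """All-Gaussian EIV model: Laplace approximation exact by construction."""
    spec = ModelSpec("normal_eiv", gaussian_latent_sd=1.0,
                     free_parameters=("beta",))
    theta = Theta(beta=1.0, sigma1=1.0, sigma2=1.0)
    return spec, theta


@pytest.fixture(scope="session")
def ex1a_dataset(eiv_specs):
    """n=50 sample from the Normal-Normal EIV model at the demonstration
    parameters (beta=-1, sigma1=3, sigma2=2, T2 latent)."""
    spec, theta = eiv_specs["normal_eiv"]
    return spec, theta, simulate_dataset(spec, theta, 50, 7)


def random_theta(spec, rng):
    """A valid random parameter point inside sensible constraint boxes."""
    vals = {}
    for p in spec.parameter_names:
        if p in ("beta", "mu"):
            vals[p] = float(rng.uniform(-2.0, 2.0))
        elif p in ("sigma1", "sigma2"):
            vals[p] = float(rng.uniform(0.5, 3.0))
        else:  # variances
            vals[p] = float(rng.uniform(0.3, 2.5))
    return Theta(**vals)


def all_specs():
    return [
        ModelSpec("normal_eiv", latent_df=2),
        ModelSpec("poisson_eiv", latent_df=2),
        ModelSpec("logit_eiv", latent_df=10),
        ModelSpec("probit_eiv", latent_df=10),
        ModelSpec("poisson_quadratic"),
        ModelSpec("variance_partition"),
    ]
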