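import numpy as np
import pytest

from erpdcm.network import ModelParameters, build_attention_network
from erpdcm.laplace import GaussianBelief
from erpdcm.synth import default_scenario, generate_dataset


@pytest.fixture(scope="session")
def spec():
    return build_attention_network()


@pytest.fixture(scope="session")
def template_params(spec):
    return ModelParameters(spec=spec)


@pytest.fixture(scope="session")
def scenario():
    """(spec, true_params, design) of the default two-condition study."""
    return default_scenario()


@pytest.fixture(scope="session")
def noisy_dataset(scenario):
    """One seeded 10 dB dataset from the default scenario."""
    spec, params, _ = scenario
    data, truth = generate_dataset(spec, params, snr_db=10.0, seed=7)
    return data, truth


@pytest.fixture(scope="session")
def clean_dataset(scenario):
    spec, params, _ = scenario
    data, truth = generate_dataset(spec, params, snr_db=np.inf, seed=0)
    return data, truth


def make_linear_problem(seed=3, n=40, p=3, sigma2=0.3):
    """Conjugate linear-Gaussian regression fixture with its exact evidence.

    Returns (y, X, prior, log_precision, posterior_mean, posterior_cov,
    log_evidence); the oracle quantities come from closed-form conjugate
    algebra, independent of the variational machinery under test.
    """
    from scipy.stats import multivariate_normal

    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    beta = rng.normal(0, 0.7, p)
    y = X @ beta + rng.normal(0, np.sqrt(sigma2), n)
    m0 = rng.normal(0, 0.3, p)
    S0 = np.diag(rng.uniform(0.5, 2.0, p))
    prior = GaussianBelief(tuple(f"beta{i}" for i in range(p)), m0, S0)
    lam = float(np.log(1.0 / sigma2))
    P0 = np.linalg.inv(S0)
    H = np.exp(lam) * X.T @ X + P0
    Sig = np.linalg.inv(H)
    m_post = Sig @ (np.exp(lam) * X.T @ y + P0 @ m0)
    logZ = float(multivariate_normal.logpdf(y, X @ m0,
                                            sigma2 * np.eye(n) + X @ S0 @ X.T))
    return y, X, prior, lam, m_post, Sig, logZ


@pytest.fixture()
def linear_problem():
    return make_linear_problem()
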