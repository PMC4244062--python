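import numpy as np
import pytest

from snpquant.intensity import SnpParams


@pytest.fixture
def clean_params() -> SnpParams:
    """A well-behaved SNP: tight, well-separated clusters."""
    return SnpParams(
        snp_id="snpX",
        mu_aa=0.05, mu_ab=0.5, mu_bb=0.95,
        sigma_aa=0.01, sigma_ab=0.05, sigma_bb=0.01,
        n_aa=20, n_ab=20, n_bb=20,
        tau_a=10.0, tau_b=10.0,
        f_b=0.5, eps_hat=0.0, eps_tilde=0.01,
        usable=True,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240902)


def random_genotype_matrix(rng: np.random.Generator, symmetric: bool = True) -> np.ndarray:
    """A random valid 2x2 genotype probability matrix."""
    w = rng.dirichlet(np.ones(3))
    g = np.array([[w[0], w[1] / 2], [w[1] / 2, w[2]]])
    if not symmetric:
        split = rng.uniform()
        g = np.array([[w[0], w[1] * split], [w[1] * (1 - split), w[2]]])
    return g
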