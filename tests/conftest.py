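import numpy as np
import pytest

import mtmepred as mp


@pytest.fixture(scope="session")
def me_study():
    """Two-environment study used across prepare/evaluate tests."""
    cfg = mp.SimConfig(n_individuals=60, n_markers=120, n_environments=2, seed=42)
    return mp.simulate_study(cfg)


@pytest.fixture(scope="session")
def ue_study():
    """Single-environment study."""
    cfg = mp.SimConfig(n_individuals=60, n_markers=120, n_environments=1, seed=43)
    return mp.simulate_study(cfg)


@pytest.fixture(scope="session")
def utue_ds(ue_study):
    """UTUE dataset prepared from the genomic relationship matrix."""
    G = mp.vanraden_g(ue_study.markers)
    return mp.prepare_data(ue_study.phenotypes, G, multi_trait=False)


@pytest.fixture(scope="session")
def linear_fixture():
    """Noiseless linear regression problem: y = Xβ, n=250, p=20."""
    rng = np.random.default_rng(0)
    X = rng.standard_normal((250, 20))
    beta = rng.standard_normal(20)
    return X, X @ beta


@pytest.fixture(scope="session")
def random_pd_matrix():
    """A random symmetric positive definite 8x8 matrix."""
    rng = np.random.default_rng(5)
    A = rng.standard_normal((8, 8))
    return A @ A.T + 8 * np.eye(8)
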