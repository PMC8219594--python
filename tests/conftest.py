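import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import truthfx as tx

settings.register_profile("suite", deadline=None, max_examples=50, derandomize=True)
settings.load_profile("suite")


@pytest.fixture
def tiny_frame() -> pd.DataFrame:
    """Two subjects x four ratings; values fixed for exact reproducibility."""
    return pd.DataFrame(
        {
            "subject": [1, 1, 1, 1, 2, 2, 2, 2],
            "statement": [1, 2, 3, 4, 5, 6, 7, 8],
            "repeated": [1, 1, 0, 0, 1, 1, 0, 0],
            "truth": [1, 0, 1, 0, 0, 1, 0, 1],
            "rating": [0.6, 0.4, -0.2, 0.1, 0.3, -0.5, 0.2, -0.4],
        }
    )


@pytest.fixture
def tiny_data(tiny_frame) -> tx.RatingDataset:
    return tx.from_frame(tiny_frame)


@pytest.fixture
def one_subject_data() -> tx.RatingDataset:
    """Single participant, four ratings: the smallest fittable instance."""
    df = pd.DataFrame(
        {
            "subject": [1, 1, 1, 1],
            "statement": [1, 2, 3, 4],
            "repeated": [1, 1, 0, 0],
            "truth": [1, 0, 1, 0],
            "rating": [0.8, 0.2, -0.4, 0.3],
        }
    )
    return tx.from_frame(df)


@pytest.fixture(scope="session")
def mu_data_small():
    """Moderate unconstrained-model dataset shared across slow tests."""
    cfg = tx.GeneratorConfig(
        model="Mu",
        n_subjects=40,
        n_statements_per_subject=40,
        effect_mean=0.15,
        effect_sd=0.15,
        seed=42,
    )
    data, truth = tx.generate(cfg)
    return data, truth


@pytest.fixture(scope="session")
def mu_fit_small(mu_data_small):
    data, _ = mu_data_small
    return tx.fit(data, "Mu", n_iterations=4000, burn_in=500, seed=7)


def make_dummy_samples(
    theta: np.ndarray,
    nu: np.ndarray | None = None,
    g_theta: np.ndarray | None = None,
    sigma2: np.ndarray | None = None,
    model: str = "Mu",
) -> tx.PosteriorSamples:
    """Hand-built PosteriorSamples for estimator-level unit tests."""
    theta = np.asarray(theta, float)
    n, I = theta.shape
    ones = np.ones(n)
    return tx.PosteriorSamples(
        model=model,
        mu=np.zeros(n),
        alpha=np.zeros((n, I)),
        beta=np.zeros(n),
        nu=ones * 0.0 if nu is None else np.asarray(nu, float),
        eta=theta.copy(),
        theta=theta,
        sigma2=ones if sigma2 is None else np.asarray(sigma2, float),
        g_alpha=ones,
        g_beta=ones,
        g_nu=ones,
        g_theta=ones if g_theta is None else np.asarray(g_theta, float),
        n_iterations=n,
        burn_in=0,
        thinning=1,
        seed=0,
    )
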