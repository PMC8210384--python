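import numpy as np
import pandas as pd
import pytest

from equitrend.cohort import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    """A 3,000-person four-wave cohort under the default conditions."""
    return generate_cohort(GeneratorConfig(n_individuals=3000, seed=42))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260922)


def random_weighted_sample(rng, n, mu_link=0.0, slope=0.0):
    """Income, gamma weights, and a binary outcome with a rank gradient."""
    from scipy.stats import norm

    income = rng.lognormal(9.0, 1.0, n)
    w = rng.gamma(4.0, 0.25, n)
    order = np.argsort(np.argsort(income))
    q = (order + 0.5) / n
    y = (rng.random(n) < norm.cdf(mu_link + slope * q)).astype(float)
    return income, w, y
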