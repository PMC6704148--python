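import numpy as np
import pandas as pd
import pytest

from sigcordance.simulate import default_params, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """300-sample synthetic cohort shared across read-only tests."""
    return generate_cohort(default_params(n_samples=300, seed=11))


@pytest.fixture(scope="session")
def toy_models():
    from sigcordance.models import load_toy_models

    return load_toy_models()


@pytest.fixture()
def rng():
    return np.random.default_rng(123)


def random_risk_labels(rng, n, classes=("low", "intermediate", "high"),
                       na_rate=0.0):
    labels = rng.choice(list(classes), size=n)
    out = pd.Series(labels, dtype=object)
    if na_rate > 0:
        out[rng.random(n) < na_rate] = np.nan
    return out
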