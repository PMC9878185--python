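import numpy as np
import pytest

from epicog.synthetic import CohortConfig, simulate_plv_features


@pytest.fixture(scope="session")
def cohort_4040():
    """Phase-level cohort with the default implanted theta contrast (n=40+40)."""
    cfg = CohortConfig(seed=7, n_con=40, n_ci=40, kappa_spread=0.5)
    feats, labels, truth = simulate_plv_features(cfg)
    return feats, labels, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
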