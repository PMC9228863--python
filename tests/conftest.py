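import numpy as np
import pytest

from fadsmets import default_config, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One full study-condition cohort (354 subjects, 330 genotyped), seed 0."""
    return generate_cohort(default_config(seed=0))


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort for fast pipeline-level tests."""
    cfg = default_config(seed=5)
    cfg.n_mets, cfg.n_con, cfg.n_genotyped = 45, 45, 80
    return generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
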