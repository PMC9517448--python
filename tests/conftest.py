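import numpy as np
import pytest

from screensem.synthetic import default_config, simulate_table


@pytest.fixture(scope="session")
def gastric_male_table():
    """Default synthetic gastric/male stratum at the study size (47)."""
    return simulate_table(default_config("gastric", "male", seed=1234))


@pytest.fixture()
def rng():
    return np.random.default_rng(20160401)
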