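import logging

import pytest

from locaset.synthetic import SimulationConfig, generate_cohort, write_cohort

logging.getLogger("locaset").setLevel(logging.WARNING)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_genes=300, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def cohort_dir(small_cohort, tmp_path_factory):
    d = tmp_path_factory.mktemp("cohort")
    write_cohort(small_cohort, d, force=True)
    return d
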