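import pytest

import smokewas as sw


@pytest.fixture(scope="session")
def cohort():
    """A 34-donor cohort under the default study-like configuration."""
    return sw.generate_cohort(34, seed=11)


@pytest.fixture(scope="session")
def methylome(cohort):
    """A small synthetic methylome with cell structure, no planted effects."""
    return sw.generate_methylome(cohort, 300, n_cell_types=3, noise_sd=0.1, seed=12)
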