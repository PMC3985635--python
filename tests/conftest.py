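import numpy as np
import pytest

from rnhl.synthetic import SuperfamilyConfig, simulate_superfamily


@pytest.fixture(scope="session")
def small_dataset():
    """Four families, five members each, short core: fast shared fixture."""
    cfg = SuperfamilyConfig(
        n_families=4, seqs_per_family=5, core_length=120, seed=11
    )
    return simulate_superfamily(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
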