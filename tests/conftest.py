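import numpy as np
import pytest

from structbind import synthetic


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_cohort():
    """A small planted cohort shared by profile/stratification tests."""
    config = synthetic.GeneratorConfig(
        seed=11, n_transcripts=60, read_depth=50.0, length_range=(150, 400)
    )
    return synthetic.generate_structure_profiles(config)


@pytest.fixture(scope="session")
def lfq_experiment():
    params = synthetic.LfqParams(n_proteins=400, planted_auc=0.8)
    return synthetic.generate_lfq_experiment(params, seed=7)
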