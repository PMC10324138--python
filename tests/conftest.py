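import numpy as np
import pytest

from pcmlab.synthetic_data import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def small_study():
    """A small synthetic study shared across tests (30 compounds, 60 pairs)."""
    config = SyntheticConfig(n_compounds=30, seed=7)
    compounds, sites, dataset, truth = generate_dataset(config)
    return {
        "config": config,
        "compounds": compounds,
        "sites": sites,
        "dataset": dataset,
        "truth": truth,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
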