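import numpy as np
import pandas as pd
import pytest

from proteoformsim.proteome import ProteomeConfig, generate_proteome


@pytest.fixture(scope="session")
def small_model():
    """A 60-protein proteome with multi-proteoform structure, fixed seed."""
    return generate_proteome(ProteomeConfig(n_proteins=60), seed=12345)


@pytest.fixture(scope="session")
def base_abundances(small_model):
    return pd.DataFrame(
        {"IS": [p.base_abundance for p in small_model.proteoforms]},
        index=[p.proteoform_id for p in small_model.proteoforms],
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(987)
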