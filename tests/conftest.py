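import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from streamstate import MCMCConfig, OccurrencePanel

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def reduced_config():
    """Short-chain settings used for simulation studies in the tests."""
    return MCMCConfig(n_chains=2, total_steps=1500, burn_in=500, thin=5, seed=0)


def make_control_panel(occ, genera=None, genus_group=None):
    """Wrap a (genus, series, occasion) array as a control-only panel."""
    occ = np.asarray(occ, dtype=np.int8)
    n_g, n_s, n_t = occ.shape
    genera = genera or [f"g{i}" for i in range(n_g)]
    return OccurrencePanel(
        occurrences=occ,
        genera=genera,
        series_meta=pd.DataFrame(
            {"stream": np.arange(n_s) + 1, "frequency": ["C"] * n_s, "battery": [1] * n_s}
        ),
        occasion_days=np.arange(n_t) + 1,
        genus_group=genus_group or {g: 1 for g in genera},
    )


@pytest.fixture
def single_series_panel():
    """One genus observed 0, 1, 1 in a single control series."""
    return make_control_panel(np.array([0, 1, 1]).reshape(1, 1, 3))
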