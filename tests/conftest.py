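import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from nespec import BroadeningParams, ConformerRecord, Ensemble, ExcitedState

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def single_state_record():
    """One conformer with one bright transition at 2.5 eV, f = 1."""
    return ConformerRecord(0, (ExcitedState(1, 2.5, 1.0),), "B3LYP", "gas")


@pytest.fixture
def single_state_ensemble(single_state_record):
    return Ensemble((single_state_record,))


@pytest.fixture
def narrow_grid():
    """2 eV wide grid around the 2.5 eV fixture transition, 1 meV step."""
    return BroadeningParams(grid_min_eV=1.5, grid_max_eV=3.5)


def random_ensemble(rng: np.random.Generator, n_p: int, n_s: int = 3) -> Ensemble:
    """Small random but valid ensemble for property tests."""
    records = []
    for k in range(n_p):
        states = tuple(
            ExcitedState(j + 1, float(rng.uniform(2.0, 4.0)), float(rng.uniform(0, 1)))
            for j in range(n_s)
        )
        records.append(ConformerRecord(k, states, "B3LYP", "gas"))
    return Ensemble(tuple(records))
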