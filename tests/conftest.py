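import numpy as np
import pytest

from del22q import load_region_model
from del22q.caller import DeletionCaller
from del22q.simulate import (
    DeletionScenario,
    SampleTruth,
    SimParams,
    simulate_null_panel,
    simulate_sample,
)


@pytest.fixture(scope="session")
def model():
    return load_region_model()


@pytest.fixture(scope="session")
def sim_params():
    return SimParams()


@pytest.fixture(scope="session")
def fitted_caller(model, sim_params):
    panel = simulate_null_panel(sim_params, model.grid, seed=1234)
    return DeletionCaller(model=model).fit(panel)


@pytest.fixture(scope="session")
def simulate_case(model, sim_params):
    """Factory: simulate one plasma sample for (origin, deletion name, ff, seed)."""
    from del22q import canonical_deletions

    dels = canonical_deletions(model)

    def _make(origin, deletion, ff, seed, params=None):
        interval = dels[deletion] if deletion is not None else None
        truth = SampleTruth(
            sample_id=f"{origin}_{deletion}_{seed}",
            ff=ff,
            scenario=DeletionScenario(origin=origin, interval=interval),
            seed=seed,
        )
        return truth, simulate_sample(truth, params or sim_params, model.grid)

    return _make
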