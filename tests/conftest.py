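import pandas as pd
import pytest

from ugicea.economics import EconParams, build_econ_params
from ugicea.state_space import build_state_space
from ugicea.synthetic import default_parameter_set


@pytest.fixture(scope="session")
def space():
    return build_state_space()


@pytest.fixture(scope="session")
def pset():
    return default_parameter_set()


@pytest.fixture(scope="session")
def econ(space, pset):
    return build_econ_params(pset.values, space)


@pytest.fixture(scope="session")
def zero_life_table():
    """No background mortality, ages 40-99."""
    return pd.Series(0.0, index=range(40, 100))


@pytest.fixture
def neutral_econ(space):
    """All utilities 1 (except death), zero costs everywhere."""
    utilities = {s.id: 0.0 if s.stage == "death" else 1.0
                 for s in space.states}
    return EconParams(
        mobilization_cost=0.0, endoscopy_cost=0.0, complication_cost=0.0,
        initial_treatment={k: 0.0 for k in ("ec_sev", "ec_early", "ec_adv",
                                            "gc_hgin", "gc_early",
                                            "gc_adv")},
        annual_cost_by_state={}, utilities_by_state=utilities)
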