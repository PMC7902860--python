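import numpy as np
import pytest

from micnn.data_io import GaitTrial
from micnn.synthetic_data import SimulationSpec, generate_collection, generate_trial


@pytest.fixture(scope="session")
def default_cohort():
    """The default-sized synthetic cohort (26 PFPS + 15 controls)."""
    return generate_collection(SimulationSpec(seed=0))


@pytest.fixture()
def one_trial():
    return generate_trial(1, SimulationSpec(seed=1), subject_index=0)


@pytest.fixture()
def control_trial():
    return generate_trial(0, SimulationSpec(seed=1), subject_index=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_trial(values, subject_id="s1", label=1, condition="walking"):
    return GaitTrial(subject_id=subject_id, label=label, condition=condition,
                     values=np.asarray(values, dtype=float))
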