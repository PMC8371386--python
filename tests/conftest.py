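import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from ionode import mech
from ionode.protocols import StepProtocol
from ionode.simulate import SimulationConfig


@pytest.fixture(scope="session")
def candidate():
    return mech.load_candidate_params()


@pytest.fixture(scope="session")
def ground_truth():
    return mech.load_ground_truth_params()


@pytest.fixture(scope="session")
def E_rev():
    return mech.nernst_potential()


@pytest.fixture(scope="session")
def short_step_protocol():
    """A three-segment activation/deactivation unit, cheap to simulate."""
    return StepProtocol(((200.0, -80.0), (800.0, 20.0), (800.0, -40.0)))


@pytest.fixture(scope="session")
def sim_cfg():
    return SimulationConfig()


# ---------------------------------------------------------------------------
# Expensive end-to-end study runs, shared across acceptance tests
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def no_discrepancy_report():
    """Full study with the candidate model as its own generator."""
    from ionode.study import StudyConfig, run_synthetic_study

    return run_synthetic_study(StudyConfig(generator="candidate", master_seed=1))


@pytest.fixture(scope="session")
def discrepancy_report():
    """Full study with the three-state ground-truth generator."""
    from ionode.study import StudyConfig, run_synthetic_study

    return run_synthetic_study(StudyConfig(generator="ground_truth", master_seed=1))
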