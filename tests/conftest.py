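import numpy as np
import pytest

from pcsattitude import NetworkTopology, ParticipantProfile
from pcsattitude.design import enumerate_design, organize_sets
from pcsattitude.synth import PopulationConfig, sample_profiles


@pytest.fixture(scope="session")
def topology():
    return NetworkTopology()


@pytest.fixture
def profile(topology):
    """One deterministic, hand-written respondent."""
    p = ParticipantProfile(agent_id="a0", condition="rational")
    imps = [6, 4, 5, 3, 2]
    gvals = [3, 2, 4, 1, 2]
    for g, imp, gv in zip(topology.goal_ids, imps, gvals):
        p.importances[g] = imp
        p.valences[g] = gv
    p.valences["ice_car"] = -2
    p.valences["e_car"] = 3
    beliefs = {
        "ice_car": [5, 4, 1, 5, 1],
        "e_car": [3, 4, 6, 3, 6],
    }
    for o, bs in beliefs.items():
        for g, b in zip(topology.goal_ids, bs):
            p.beliefs[(g, o)] = b
    return p


@pytest.fixture(scope="session")
def organized_sets(topology):
    return organize_sets(enumerate_design(topology), seed=7)


@pytest.fixture(scope="session")
def small_population():
    """12 agents from the default distribution (4 per condition)."""
    return sample_profiles(seed=11, config=PopulationConfig(n_agents=12))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
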