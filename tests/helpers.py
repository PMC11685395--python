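"""Shared construction helpers for the test suite."""

import numpy as np

from pcsattitude import AttitudeNetwork, ParticipantProfile


def make_profile(topology, importance=4, goal_valence=2, option_valence=0, belief=3.5):
    """A uniform profile with every rating set to the given values."""
    p = ParticipantProfile(agent_id="x")
    for g in topology.goal_ids:
        p.importances[g] = importance
        p.valences[g] = goal_valence
    for o in topology.option_ids:
        p.valences[o] = option_valence
        for g in topology.goal_ids:
            p.beliefs[(g, o)] = belief
    return p


def random_network(topology, rng):
    """Random admissible symmetric weights for oracle checks."""
    net = AttitudeNetwork(topology)
    mask = topology.link_mask()
    n = topology.n_nodes
    W = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if mask[i, j]:
                lo = 0.0 if i == 0 else -1.0
                W[i, j] = W[j, i] = rng.uniform(lo, 1.0)
    net.weights = W
    net.validate()
    return net
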