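import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pcsattitude import (
    ActivationParams,
    AttitudeNetwork,
    NetworkTopology,
    ParticipantProfile,
    attitude_of,
    build_network,
    energy,
    net_input,
    settle,
)
from pcsattitude.network import settle_batch
from pcsattitude.profiles import read_profiles, write_profiles


from helpers import make_profile as _make_profile, random_network as _random_network


class TestTopology:
    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError):
            NetworkTopology(goal_ids=("a", "a"), option_ids=("o",))

    def test_needs_goals_and_options(self):
        with pytest.raises(ValueError):
            NetworkTopology(goal_ids=(), option_ids=("o",))

    def test_no_intra_layer_or_special_option_links(self, topology):
        mask = topology.link_mask()
        oi = topology.option_indices
        gi = topology.goal_indices
        assert not mask[np.ix_(oi, oi)].any()
        assert not mask[np.ix_(gi, gi)].any()
        assert not mask[np.ix_([0], oi)].any()
        assert not mask[0, 1]


class TestBuild:
    def test_midpoint_beliefs_give_zero_belief_weights(self, topology):
        net = build_network(_make_profile(topology, belief=3.5), topology)
        for g in topology.goal_ids:
            for o in topology.option_ids:
                assert net.get_weight(g, o) == 0.0

    def test_endpoint_importance_gives_unit_priority(self, topology):
        net = build_network(_make_profile(topology, importance=6), topology)
        for g in topology.goal_ids:
            assert net.get_weight(topology.special_id, g) == 1.0

    def test_full_profile_matches_hand_rescaled_table(self, topology, profile):
        # independent element-wise rescaling, written out by hand
        net = build_network(profile, topology)
        for g in topology.goal_ids:
            assert net.get_weight(topology.special_id, g) == pytest.approx(
                (profile.importances[g] - 1) / 5
            )
            assert net.get_weight(topology.valence_id, g) == pytest.approx(
                profile.valences[g] / 4
            )
            for o in topology.option_ids:
                assert net.get_weight(g, o) == pytest.approx(
                    2 * (profile.beliefs[(g, o)] - 1) / 5 - 1
                )
        for o in topology.option_ids:
            assert net.get_weight(topology.valence_id, o) == pytest.approx(
                profile.valences[o] / 4
            )
        # symmetry over the full matrix
        assert np.array_equal(net.weights, net.weights.T)

    def test_missing_rating_named_in_error(self, topology, profile):
        del profile.beliefs[("comfort", "e_car")]
        with pytest.raises(ValueError, match="belief_comfort_e_car"):
            build_network(profile, topology)

    def test_out_of_scale_rating_rejected(self, topology, profile):
        profile.importances["comfort"] = 9
        with pytest.raises(ValueError):
            build_network(profile, topology)


class TestNetInput:
    def test_two_term_sum(self, topology):
        net = AttitudeNetwork(topology)
        net.set_weight("valence", "comfort", 0.5)
        net.set_weight("comfort", "e_car", 0.3)
        acts = net.activations.copy()
        acts[topology.index("valence")] = 1.0
        acts[topology.index("e_car")] = -1.0
        net.activations = acts
        assert net_input(net, "comfort") == pytest.approx(0.5 * 1.0 + 0.3 * (-1.0))

    def test_zero_weights(self, topology):
        net = AttitudeNetwork(topology)
        assert net_input(net, "comfort") == 0.0

    def test_unknown_node_rejected(self, topology):
        with pytest.raises(KeyError):
            net_input(AttitudeNetwork(topology), "bicycle")

    def test_matches_brute_force_dot_product(self, topology, rng):
        net = _random_network(topology, rng)
        net.activations = rng.uniform(-1, 1, topology.n_nodes)
        for label in topology.labels:
            j = topology.index(label)
            raw = sum(
                net.weights[i, j] * net.activations[i]
                for i in range(topology.n_nodes)
                if i != j
            )
            expected = min(1.0, max(-1.0, raw))
            assert net_input(net, label) == pytest.approx(expected, rel=1e-12)


class TestSettle:
    def test_single_priority_link_fixed_point(self, topology):
        # a* solves a = a(1-d) + 0.5(1-a)  ->  a* = 0.5/0.55
        net = AttitudeNetwork(topology)
        net.set_weight("special", "comfort", 0.5)
        res = settle(net)
        assert res.converged
        assert res.activation("comfort") == pytest.approx(0.5 / 0.55, abs=1e-3)

    def test_all_zero_weights_stay_at_zero(self, topology):
        net = AttitudeNetwork(topology)
        res = settle(net)
        assert res.converged and res.iterations == 1
        free = [l for l in topology.labels if l not in net.clamped]
        assert all(res.activation(l) == 0.0 for l in free)

    def test_negative_branch_single_step(self, topology):
        # constant net input -0.5 onto a node at 0: first update gives
        # 0*(1-d) + (-0.5)*(0-(-1)) = -0.5
        net = AttitudeNetwork(topology)
        net.set_weight("valence", "comfort", -0.5)
        a, _, _ = settle_batch(
            net.weights[None],
            net.clamped_indices,
            net.clamped_values,
            ActivationParams(max_iterations=1),
        )
        assert a[0, topology.index("comfort")] == pytest.approx(-0.5)

    def test_weights_untouched_and_symmetric_after_settle(self, topology, profile):
        net = build_network(profile, topology)
        before = net.weights.copy()
        settle(net)
        assert np.array_equal(net.weights, before)
        assert np.array_equal(net.weights, net.weights.T)

    def test_fixed_point_stable_under_extra_update(self, topology, profile):
        net = build_network(profile, topology)
        res = settle(net)
        p = ActivationParams()
        a = res.activations.copy()
        net_in = np.clip(net.weights.T @ a, -1, 1)
        new = a * (1 - p.decay) + np.where(
            net_in > 0, net_in * (p.max - a), net_in * (a - p.min)
        )
        new = np.clip(new, p.min, p.max)
        new[net.clamped_indices] = net.clamped_values
        assert np.max(np.abs(new - a)) < p.convergence_threshold

    def test_sign_coherence_of_opposed_options(self):
        top = NetworkTopology(goal_ids=("g",), option_ids=("o1", "o2"))
        p = ParticipantProfile(agent_id="s")
        p.importances["g"] = 6
        p.valences.update({"g": 0, "o1": 0, "o2": 0})
        p.beliefs[("g", "o1")] = 6  # +1
        p.beliefs[("g", "o2")] = 1  # -1
        res = settle(build_network(p, top))
        a1, a2 = res.activation("o1"), res.activation("o2")
        assert a1 > 0
        assert a1 == pytest.approx(-a2, abs=1e-9)

    def test_deterministic_repeat(self, topology, profile):
        r1 = settle(build_network(profile, topology))
        r2 = settle(build_network(profile, topology))
        assert np.array_equal(r1.activations, r2.activations)
        assert r1.iterations == r2.iterations

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_boundedness_throughout(self, seed):
        top = NetworkTopology()
        rng = np.random.default_rng(seed)
        net = _random_network(top, rng)
        p = ActivationParams()
        a = net.initial_activations()
        for _ in range(60):
            net_in = np.clip(net.weights.T @ a, -1, 1)
            a = a * (1 - p.decay) + np.where(
                net_in > 0, net_in * (p.max - a), net_in * (a - p.min)
            )
            a = np.clip(a, p.min, p.max)
            a[net.clamped_indices] = net.clamped_values
            assert np.all(a >= p.min) and np.all(a <= p.max)


class TestEnergy:
    def test_single_satisfied_link_counts_ordered_pairs(self, topology):
        net = AttitudeNetwork(topology)
        net.set_weight("valence", "comfort", 1.0)
        acts = np.zeros(topology.n_nodes)
        acts[topology.index("valence")] = 1.0
        acts[topology.index("comfort")] = 1.0
        assert energy(net, acts) == pytest.approx(-2.0)

    def test_zero_activations(self, topology):
        net = AttitudeNetwork(topology)
        assert energy(net, np.zeros(topology.n_nodes)) == 0.0

    def test_matches_double_loop(self, topology, rng):
        net = _random_network(topology, rng)
        a = rng.uniform(-1, 1, topology.n_nodes)
        brute = -sum(
            net.weights[i, j] * a[i] * a[j]
            for i in range(topology.n_nodes)
            for j in range(topology.n_nodes)
        )
        assert energy(net, a) == pytest.approx(brute, rel=1e-12)

    def test_flipping_satisfied_link_raises_energy(self, topology, rng):
        net = _random_network(topology, rng)
        a = rng.uniform(0.2, 1.0, topology.n_nodes)  # all positive
        i, j = 1, topology.index("comfort")
        w = abs(net.weights[i, j])  # positive weight + positive acts: satisfied
        net.weights[i, j] = w
        net.weights[j, i] = w
        e0 = energy(net, a)
        flipped = net.copy()
        flipped.weights[i, j] = -w
        flipped.weights[j, i] = -w
        e1 = energy(flipped, a)
        assert e1 - e0 == pytest.approx(2 * abs(w * a[i] * a[j]) * 2, rel=1e-9)


class TestAttitude:
    def test_positive_support_gives_positive_attitude(self, topology):
        p = _make_profile(topology, belief=6, option_valence=3)
        res = settle(build_network(p, topology))
        for o in topology.option_ids:
            assert attitude_of(res, o) > 0

    def test_unknown_option_rejected(self, topology):
        res = settle(AttitudeNetwork(topology))
        with pytest.raises(KeyError):
            attitude_of(res, "bus")


class TestSerialization:
    def test_json_round_trip(self, topology, profile):
        net = build_network(profile, topology)
        settle(net)
        back = AttitudeNetwork.from_json(net.to_json())
        assert np.array_equal(back.weights, net.weights)
        assert np.array_equal(back.activations, net.activations)
        assert back.clamped == net.clamped
        assert back.topology == net.topology

    def test_profile_csv_round_trip(self, topology, profile, tmp_path):
        path = tmp_path / "profiles.csv"
        write_profiles([profile], path)
        (back,) = read_profiles(path, topology)
        assert back.importances == profile.importances
        assert back.beliefs == profile.beliefs
        assert back.valences == profile.valences
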