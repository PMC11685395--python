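"""Build one respondent's attitude network and settle it to coherence.

A respondent rates the importance of five transport goals, the
pleasantness of each goal and of the two vehicle options, and how well
each option serves each goal.  Those ratings become link weights; the
settled activation of each option node is the simulated attitude, and
the network energy scores how coherent the whole representation is
(lower = more coherent).
"""

from pcsattitude import (
    NetworkTopology,
    ParticipantProfile,
    attitude_of,
    build_network,
    energy,
    settle,
)

top = NetworkTopology()

profile = ParticipantProfile(agent_id="demo", condition="rational")
for goal, imp, val in [
    ("independence", 6, 3),
    ("comfort", 5, 2),
    ("eco_friendliness", 4, 4),
    ("driving_experience", 3, 2),
    ("good_conscience", 4, 3),
]:
    profile.importances[goal] = imp
    profile.valences[goal] = val
profile.valences["ice_car"] = -1
profile.valences["e_car"] = 3
for goal, ice, ev in [
    ("independence", 5, 3),
    ("comfort", 4, 4),
    ("eco_friendliness", 1, 6),
    ("driving_experience", 5, 3),
    ("good_conscience", 1, 6),
]:
    profile.beliefs[(goal, "ice_car")] = ice
    profile.beliefs[(goal, "e_car")] = ev

network = build_network(profile, top)
result = settle(network)

print(f"settled in {result.iterations} iterations (converged={result.converged})")
for option in top.option_ids:
    print(f"attitude toward {option}: {attitude_of(result, option):+.3f}")
print(f"network energy: {energy(network, result.activations):.3f}")
print()
print("The attitudes are the option nodes' settled activations in [-1, 1]:")
print("this respondent leans clearly pro-electric. The negative energy says")
print("the belief/affect pattern is internally coherent (conflicting ratings")
print("would push energy toward zero or above).")
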