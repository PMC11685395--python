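"""Apply one persuasive message to a receiver and watch the weights move.

A skeptical receiver (negative affect toward the advocated option) gets
a positive emotional message.  Under the published emotional-condition
learning coefficients the dissonance-squared term dominates and the
transmitted affect links move *away* from the message — the backfire
effect at the level of mental structure.
"""

from pcsattitude import (
    LearningParams,
    NetworkTopology,
    Vignette,
    build_network,
    simulate_treatment,
)
from pcsattitude.profiles import ParticipantProfile

top = NetworkTopology()

profile = ParticipantProfile(agent_id="skeptic", condition="emotional")
for goal in top.goal_ids:
    profile.importances[goal] = 5
    profile.valences[goal] = -2  # goals framed negatively by this agent
profile.valences["ice_car"] = 3
profile.valences["e_car"] = -3  # dislikes electric cars
for goal in top.goal_ids:
    profile.beliefs[(goal, "ice_car")] = 5
    profile.beliefs[(goal, "e_car")] = 2

network = build_network(profile, top)
message = Vignette(
    condition="emotional",
    option="e_car",
    goal_pair=("comfort", "eco_friendliness"),
    valence="positive",
)
params = LearningParams.reported("emotional")
record = simulate_treatment(network, message, params)

print(f"message: {message.valence} emotional appeal for {message.option}")
print(f"learning coefficients b1..b5: {tuple(params.as_array().tolist())}")
print()
print(f"{'link':38s} {'sender':>7s} {'pre':>7s} {'post':>7s}")
for entry in record.links:
    name = " -- ".join(sorted(entry["link"]))
    print(f"{name:38s} {entry['w_s']:+7.2f} {entry['w_r_pre']:+7.2f} {entry['w_r_post']:+7.2f}")
print()
print(f"attitude toward {message.option}: {record.A_base:+.3f} -> {record.A_sim:+.3f}")
print(f"network energy: {record.energy_pre:.3f} -> {record.energy_post:.3f}")
print()
print("Every transmitted link moved in the negative direction despite the")
print("+1 message weights: the receiver's negative prior affect, fed into")
print("the polynomial adjustment rule, turns a positive appeal into further")
print("polarization (attitude change opposite to the message).")
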