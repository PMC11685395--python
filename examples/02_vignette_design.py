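"""Enumerate the factorial message design and organize balanced sets.

Messages (vignettes) form the factorial design condition x vehicle x
goal-pair x valence: 3 x 2 x 10 x 2 = 120 unique cells, organized into
12 balanced sets of 10 (four per condition, five per vehicle in each
set, valence balanced).  Each vignette encodes as a sender network and
a condition-specific transmission plan.
"""

from pcsattitude import (
    NetworkTopology,
    encode_vignette,
    enumerate_design,
    goal_pairs,
    organize_sets,
    transmission_plan,
)
from pcsattitude.design import design_to_frame

top = NetworkTopology()
pairs = goal_pairs(top.goal_ids)
design = enumerate_design(top)
sets = organize_sets(design, seed=7)
df = design_to_frame(sets)

print(f"goal pairs: {len(pairs)}")
print(f"unique vignettes: {len(design)}")
print(f"sets: {df.set_id.nunique()} x {len(df) // df.set_id.nunique()} vignettes")
print()
print("set 0 contents:")
print(df[df.set_id == 0][["condition", "option", "goal_1", "goal_2", "valence"]].to_string(index=False))

v = sets[0]
sender = encode_vignette(v, top)
plan = transmission_plan(v, top)
print()
print(f"first vignette: {v.condition}, {v.valence} message about {v.option}")
print(f"emphasized sender links (weight {v.sign:+.0f}):")
for link in sender.emphasized:
    print("  ", " -- ".join(sorted(link)))
print(f"links actually transmitted in the {v.condition} condition: {len(plan)}")
print()
print("Rational messages transmit only the two goal-option belief links,")
print("emotional ones only the three valence links, combined all five.")
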