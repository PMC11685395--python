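"""Factorial vignette design and its encoding as sender weight patterns.

A vignette is one persuasive message: a cell of the factorial design
condition x option x goal-pair x valence.  With the default topology
(3 conditions, 2 vehicle options, 5 goals -> 10 same-valence goal
pairs, 2 valences) the design has 120 unique vignettes, organized into
12 balanced sets of 10 (four sets per condition; within a set, five
vignettes per vehicle with near-balanced valence).

Each vignette is encoded as a *sender network*: a weight pattern on the
receiver topology in which the message's two goal-option belief links
and the three affective links (valence-goal x2, valence-option) carry
weight +1.0 (or -1.0 for negative messages) and every other admissible
link carries a negligible filler weight of 0.01.  What the receiver
actually absorbs depends on the condition: rational messages transmit
only the belief links, emotional messages only the affect links, and
combined messages both.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .network import AttitudeNetwork, NetworkTopology

__all__ = [
    "CONDITIONS",
    "VALENCES",
    "Vignette",
    "SenderNetwork",
    "TransmissionPlan",
    "goal_pairs",
    "enumerate_design",
    "organize_sets",
    "validate_sets",
    "encode_vignette",
    "transmission_plan",
    "design_to_frame",
    "frame_to_design",
]

CONDITIONS = ("rational", "emotional", "combined")
VALENCES = ("positive", "negative")

FILLER_WEIGHT = 0.01


@dataclass(frozen=True)
class Vignette:
    """One persuasive message cell of the factorial design."""

    condition: str
    option: str
    goal_pair: tuple
    valence: str
    set_id: int | None = None
    position: int | None = None

    def __post_init__(self):
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.valence not in VALENCES:
            raise ValueError(f"unknown valence {self.valence!r}")
        if len(set(self.goal_pair)) != 2:
            raise ValueError("goal_pair members must be distinct")

    @property
    def sign(self) -> float:
        return 1.0 if self.valence == "positive" else -1.0


@dataclass(frozen=True)
class SenderNetwork:
    """A vignette's weight pattern on the shared topology.

    ``emphasized`` maps the five message links (unordered label pairs)
    to +/-1.0; every other admissible link has weight
    :data:`FILLER_WEIGHT`.
    """

    topology: NetworkTopology
    vignette: Vignette
    emphasized: dict

    def weight(self, a: str, b: str) -> float:
        key = frozenset((a, b))
        if key in self.emphasized:
            return self.emphasized[key]
        i, j = self.topology.index(a), self.topology.index(b)
        if not self.topology.link_mask()[i, j]:
            raise KeyError(f"{a!r}-{b!r} is not a link of the topology")
        return FILLER_WEIGHT

    def as_matrix(self) -> np.ndarray:
        mask = self.topology.link_mask()
        W = np.where(mask, FILLER_WEIGHT, 0.0)
        for key, w in self.emphasized.items():
            a, b = tuple(key)
            i, j = self.topology.index(a), self.topology.index(b)
            W[i, j] = w
            W[j, i] = w
        return W


@dataclass(frozen=True)
class TransmissionPlan:
    """Which sender links a condition actually conveys to the receiver."""

    condition: str
    links: tuple  # tuple of frozenset label pairs

    def __len__(self):
        return len(self.links)


def goal_pairs(goal_ids) -> list[tuple]:
    """All unordered pairs of goals, in lexicographic (input) order.

    Five goals yield the study's 10 same-valence belief combinations.
    """
    goal_ids = tuple(goal_ids)
    if len(goal_ids) < 2:
        raise ValueError("need at least two goals to form pairs")
    return list(itertools.combinations(goal_ids, 2))


def enumerate_design(
    topology: NetworkTopology | None = None,
    conditions=CONDITIONS,
    valences=VALENCES,
) -> list[Vignette]:
    """Full Cartesian design: condition x option x goal-pair x valence.

    The default study configuration yields 120 unique vignettes.  Order
    is stable: conditions, then options, then goal pairs, then valences.
    """
    top = topology or NetworkTopology()
    return [
        Vignette(condition=c, option=o, goal_pair=gp, valence=v)
        for c in conditions
        for o in top.option_ids
        for gp in goal_pairs(top.goal_ids)
        for v in valences
    ]


def organize_sets(
    vignettes,
    sets_per_condition: int = 4,
    seed: int | None = None,
) -> list[Vignette]:
    """Partition the design into balanced sets of 10 vignettes.

    Each condition's vignettes are split into ``sets_per_condition``
    sets such that every set holds an equal number of vignettes per
    vehicle and per-vehicle valence counts differ by at most one, with
    overall valence in each set exactly balanced.  The default design
    (120 vignettes) yields 12 sets of 10, four per condition.

    Construction is deterministic: within a condition and option,
    vignettes are taken in lexicographic order (optionally permuted at
    the goal-pair level by ``seed``) and dealt round-robin to the sets,
    positive valence first; successive options start the deal at
    staggered sets so that overall valence balances out.  Returns new
    ``Vignette`` objects carrying ``set_id`` (global, 0-based) and
    ``position`` within the set.
    """
    vignettes = list(vignettes)
    conditions = sorted({v.condition for v in vignettes}, key=CONDITIONS.index)
    rng = np.random.default_rng(seed) if seed is not None else None
    out: list[Vignette] = []
    n_sets_total = 0
    for ci, cond in enumerate(conditions):
        cond_vs = [v for v in vignettes if v.condition == cond]
        options = sorted({v.option for v in cond_vs})
        k = sets_per_condition
        if len(cond_vs) % k != 0:
            raise ValueError(
                f"condition {cond!r} has {len(cond_vs)} vignettes, "
                f"not divisible into {k} sets"
            )
        buckets: list[list[Vignette]] = [[] for _ in range(k)]
        for oi, opt in enumerate(options):
            ov = sorted(
                (v for v in cond_vs if v.option == opt),
                key=lambda v: (v.valence == "negative", v.goal_pair),
            )
            if rng is not None:
                # permute at the goal-pair level, preserving valence blocks
                pos = [v for v in ov if v.valence == "positive"]
                neg = [v for v in ov if v.valence == "negative"]
                perm = rng.permutation(len(pos))
                ov = [pos[i] for i in perm] + [neg[i] for i in perm]
            start = (oi * k) // max(len(options), 1)
            for r, v in enumerate(ov):
                buckets[(start + r) % k].append(v)
        sizes = {len(b) for b in buckets}
        if len(sizes) != 1:
            raise ValueError("balance constraints infeasible: unequal set sizes")
        for si, bucket in enumerate(buckets):
            for pos_i, v in enumerate(bucket):
                out.append(replace(v, set_id=n_sets_total + si, position=pos_i))
        n_sets_total += k
    validate_sets(out, sets_per_condition=sets_per_condition)
    return out


def validate_sets(assigned, sets_per_condition: int = 4) -> None:
    """Re-check the balance constraints of an organized design.

    Raises ``ValueError`` naming the first violated constraint: equal
    set sizes, equal per-vehicle counts within each set, per-vehicle
    valence counts differing by at most one, each vignette in exactly
    one set of its condition.
    """
    df = design_to_frame(assigned)
    if df["set_id"].isna().any():
        raise ValueError("unassigned vignette (missing set_id)")
    for cond, cdf in df.groupby("condition"):
        n_sets = cdf["set_id"].nunique()
        if n_sets != sets_per_condition:
            raise ValueError(f"{cond}: {n_sets} sets, expected {sets_per_condition}")
        dup = cdf.duplicated(subset=["option", "goal_1", "goal_2", "valence"])
        if dup.any():
            raise ValueError(f"{cond}: vignette appears in more than one set")
        sizes = cdf.groupby("set_id").size()
        if sizes.nunique() != 1:
            raise ValueError(f"{cond}: unequal set sizes {sorted(sizes)}")
        for sid, sdf in cdf.groupby("set_id"):
            per_opt = sdf.groupby("option").size()
            if per_opt.nunique() != 1:
                raise ValueError(f"set {sid}: unequal per-vehicle counts")
            for opt, odf in sdf.groupby("option"):
                counts = odf["valence"].value_counts()
                if abs(counts.get("positive", 0) - counts.get("negative", 0)) > 1:
                    raise ValueError(
                        f"set {sid}, option {opt}: valence counts differ by more than 1"
                    )


def encode_vignette(v: Vignette, topology: NetworkTopology | None = None) -> SenderNetwork:
    """Encode a vignette as a sender weight pattern.

    The two goal-option belief links and the three affective links of
    the message get weight +1.0 (positive valence) or -1.0 (negative);
    every other admissible link carries the 0.01 filler weight.
    """
    top = topology or NetworkTopology()
    g1, g2 = v.goal_pair
    for g in (g1, g2):
        if g not in top.goal_ids:
            raise KeyError(f"unknown goal {g!r}")
    if v.option not in top.option_ids:
        raise KeyError(f"unknown option {v.option!r}")
    s = v.sign
    emphasized = {
        frozenset((g1, v.option)): s,
        frozenset((g2, v.option)): s,
        frozenset((top.valence_id, g1)): s,
        frozenset((top.valence_id, g2)): s,
        frozenset((top.valence_id, v.option)): s,
    }
    return SenderNetwork(topology=top, vignette=v, emphasized=emphasized)


def transmission_plan(v: Vignette, topology: NetworkTopology | None = None) -> TransmissionPlan:
    """Links conveyed to the receiver under the vignette's condition.

    rational -> the two belief links (goal-option); emotional -> the
    three affect links (valence-goal x2, valence-option); combined ->
    the union of both.
    """
    top = topology or NetworkTopology()
    g1, g2 = v.goal_pair
    belief = (frozenset((g1, v.option)), frozenset((g2, v.option)))
    affect = (
        frozenset((top.valence_id, g1)),
        frozenset((top.valence_id, g2)),
        frozenset((top.valence_id, v.option)),
    )
    if v.condition == "rational":
        links = belief
    elif v.condition == "emotional":
        links = affect
    elif v.condition == "combined":
        links = belief + affect
    else:  # pragma: no cover - Vignette already validates
        raise ValueError(f"unknown condition {v.condition!r}")
    return TransmissionPlan(condition=v.condition, links=links)


# -- CSV round trip ----------------------------------------------------


def design_to_frame(vignettes) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "condition": [v.condition for v in vignettes],
            "option": [v.option for v in vignettes],
            "goal_1": [v.goal_pair[0] for v in vignettes],
            "goal_2": [v.goal_pair[1] for v in vignettes],
            "valence": [v.valence for v in vignettes],
            "set_id": [v.set_id for v in vignettes],
            "position": [v.position for v in vignettes],
        }
    )


def frame_to_design(frame: pd.DataFrame) -> list[Vignette]:
    out = []
    for _, r in frame.iterrows():
        out.append(
            Vignette(
                condition=r["condition"],
                option=r["option"],
                goal_pair=(r["goal_1"], r["goal_2"]),
                valence=r["valence"],
                set_id=None if pd.isna(r.get("set_id")) else int(r["set_id"]),
                position=None if pd.isna(r.get("position")) else int(r["position"]),
            )
        )
    return out
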