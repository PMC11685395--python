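"""Participant profiles: the raw survey ratings a network is built from.

One profile holds, for a single respondent, the goal importances
(six-point scale), affective valence ratings of each goal and option
(semantic differential, -4..+4) and the goal-by-option beliefs
(six-point scale), plus the experimental condition the respondent was
assigned to.  Profiles travel as tidy tables (one row per agent) with
columns ``importance_<goal>``, ``valence_<goal|option>`` and
``belief_<goal>_<option>``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .scales import IMPORTANCE6, LIKERT6, SEMANTIC_DIFFERENTIAL

__all__ = ["ParticipantProfile", "profiles_to_frame", "frame_to_profiles",
           "read_profiles", "write_profiles"]


@dataclass
class ParticipantProfile:
    """Survey ratings of one respondent.

    Parameters
    ----------
    agent_id:
        Unique identifier.
    importances:
        Goal label -> importance rating on the six-point scale (1..6).
    valences:
        Concept label (goal or option) -> valence rating on the
        semantic differential (-4..+4).
    beliefs:
        (goal, option) -> belief rating on the six-point scale (1..6).
    condition:
        Experimental condition label, or ``None`` if unassigned.
    """

    agent_id: str
    importances: dict = field(default_factory=dict)
    valences: dict = field(default_factory=dict)
    beliefs: dict = field(default_factory=dict)
    condition: str | None = None

    def validate(self, topology) -> None:
        """Check completeness and scale bounds against a topology.

        Raises ``ValueError`` naming the first missing or out-of-range
        field.
        """
        for g in topology.goal_ids:
            if g not in self.importances:
                raise ValueError(f"agent {self.agent_id}: missing importance_{g}")
            IMPORTANCE6.rescale(self.importances[g])
        for c in (*topology.goal_ids, *topology.option_ids):
            if c not in self.valences:
                raise ValueError(f"agent {self.agent_id}: missing valence_{c}")
            SEMANTIC_DIFFERENTIAL.rescale(self.valences[c])
        for g in topology.goal_ids:
            for o in topology.option_ids:
                if (g, o) not in self.beliefs:
                    raise ValueError(
                        f"agent {self.agent_id}: missing belief_{g}_{o}"
                    )
                LIKERT6.rescale(self.beliefs[(g, o)])


def profiles_to_frame(profiles) -> pd.DataFrame:
    """Flatten profiles into a tidy one-row-per-agent table."""
    rows = []
    for p in profiles:
        row: dict = {"agent_id": p.agent_id, "condition": p.condition}
        for g, v in p.importances.items():
            row[f"importance_{g}"] = v
        for c, v in p.valences.items():
            row[f"valence_{c}"] = v
        for (g, o), v in p.beliefs.items():
            row[f"belief_{g}_{o}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_profiles(frame: pd.DataFrame, topology) -> list[ParticipantProfile]:
    """Rebuild profiles from a tidy table, validating against ``topology``."""
    out = []
    for _, row in frame.iterrows():
        p = ParticipantProfile(
            agent_id=str(row["agent_id"]),
            condition=row.get("condition") if "condition" in frame.columns else None,
        )
        for g in topology.goal_ids:
            p.importances[g] = float(row[f"importance_{g}"])
        for c in (*topology.goal_ids, *topology.option_ids):
            p.valences[c] = float(row[f"valence_{c}"])
        for g in topology.goal_ids:
            for o in topology.option_ids:
                p.beliefs[(g, o)] = float(row[f"belief_{g}_{o}"])
        p.validate(topology)
        out.append(p)
    return out


def write_profiles(profiles, path) -> None:
    """Write profiles as CSV (TSV if the path ends in ``.tsv``)."""
    sep = "\t" if str(path).endswith(".tsv") else ","
    profiles_to_frame(profiles).to_csv(path, sep=sep, index=False)


def read_profiles(path, topology) -> list[ParticipantProfile]:
    """Read a profile CSV/TSV written by :func:`write_profiles`."""
    sep = "\t" if str(path).endswith(".tsv") else ","
    return frame_to_profiles(pd.read_csv(path, sep=sep), topology)
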