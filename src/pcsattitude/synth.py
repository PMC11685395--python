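"""Synthetic participant populations and ground-truth response generation.

The empirical survey data behind this model are not public, so every
stage of the pipeline runs on synthetic respondents that emulate the
study's instruments: per-goal importances on a six-point scale,
valence ratings of goals and options on a -4..+4 semantic differential,
goal-by-option beliefs on a six-point scale, and a seven-point
self-reported attitude-change item per vignette (4 = "no change").

Ratings are drawn by rounding truncated-normal latents onto the scale
points.  An optional two-cluster mixture shifts beliefs and option
valences toward one vehicle or the other, producing the polarized
attitude poles (pro-combustion vs pro-electric) under which the
coherence analyses are most informative.  Responses are generated from
a ground-truth response model — the same persuasion machinery run with
known learning coefficients plus truncated Gaussian report noise — so
that parameter recovery can be tested end to end.

All outputs are pure functions of (config, seed); per-agent random
substreams are derived from one master seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .design import CONDITIONS, Vignette, design_to_frame
from .learning import LearningParams, TreatmentDataset, simulate_A_sim
from .network import ActivationParams, NetworkTopology, build_network, settle_batch
from .profiles import ParticipantProfile
from .scales import CHANGE7, rescale, inverse_rescale  # noqa: F401  (re-exported)

__all__ = [
    "PopulationConfig",
    "ResponseRecord",
    "sample_profiles",
    "assign_design",
    "simulate_responses",
    "responses_to_frame",
    "write_manifest",
    "config_hash",
]


@dataclass(frozen=True)
class PopulationConfig:
    """Distributional assumptions of the synthetic population.

    Latent means/SDs are on the raw scale of each instrument; draws are
    rounded to integer scale points and clipped to the scale bounds.
    The surveyed goals are intrinsically desirable motives, so their
    valence latents centre clearly positive; and because real attitude
    structure is coherent, an agent's valence toward an option tracks
    its mean belief about that option through
    ``valence_belief_coupling`` (differential points per belief scale
    point above the belief midpoint 3.5).

    ``polarization`` in [0, 1] is the fraction of agents assigned to
    one of two attitude poles; each pole shifts the belief latents
    toward its favored option by ``pole_belief_shift`` scale points
    (and away from the other), and the option-valence latents by
    ``pole_valence_shift`` differential points.
    """

    n_agents: int = 480
    conditions: tuple = CONDITIONS
    importance_mean: float = 4.5
    importance_sd: float = 1.2
    goal_valence_mean: float = 2.5
    goal_valence_sd: float = 1.2
    option_valence_mean: float = 0.0
    option_valence_sd: float = 1.5
    valence_belief_coupling: float = 1.5
    belief_mean: float = 3.5
    belief_sd: float = 1.3
    polarization: float = 0.0
    pole_belief_shift: float = 1.5
    pole_valence_shift: float = 2.0
    allow_unbalanced: bool = False

    def polarized(self, fraction: float = 1.0) -> "PopulationConfig":
        """A copy with the given fraction of agents at attitude poles."""
        d = asdict(self)
        d["polarization"] = fraction
        return PopulationConfig(**{**d, "conditions": self.conditions})


@dataclass
class ResponseRecord:
    """One simulated self-report after a vignette treatment."""

    agent_id: str
    vignette: Vignette
    presentation_order: int
    reported_change: int  # seven-point scale, 4 = no change
    A_emp: float  # derived reported attitude in [-1, 1]
    A_base: float
    A_sim_true: float


def _draw_scale(rng, mean, sd, lo, hi, size):
    """Truncated-normal latent rounded onto integer scale points."""
    a, b = (lo - 0.5 - mean) / sd, (hi + 0.5 - mean) / sd
    latent = stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)
    return np.clip(np.round(latent), lo, hi).astype(int)


def sample_profiles(
    n: int | None = None,
    seed: int = 0,
    config: PopulationConfig | None = None,
    topology: NetworkTopology | None = None,
) -> list[ParticipantProfile]:
    """Draw a complete synthetic population.

    Agents are assigned to conditions in balanced round-robin order
    (``n`` must be divisible by the number of conditions unless
    ``allow_unbalanced``).  Each agent draws from its own substream of
    the master seed, so populations are reproducible and insensitive to
    draw order.
    """
    cfg = config or PopulationConfig()
    top = topology or NetworkTopology()
    n = cfg.n_agents if n is None else n
    k = len(cfg.conditions)
    if n % k != 0 and not cfg.allow_unbalanced:
        raise ValueError(f"n={n} not divisible by {k} conditions")
    children = np.random.SeedSequence(seed).spawn(n)
    profiles = []
    for i in range(n):
        rng = np.random.default_rng(children[i])
        pole = 0
        if cfg.polarization > 0 and rng.random() < cfg.polarization:
            pole = 1 if rng.random() < 0.5 else -1  # +1 favors the first option
        p = ParticipantProfile(
            agent_id=f"agent_{i:04d}", condition=cfg.conditions[i % k]
        )
        imps = _draw_scale(rng, cfg.importance_mean, cfg.importance_sd, 1, 6, len(top.goal_ids))
        gvals = _draw_scale(rng, cfg.goal_valence_mean, cfg.goal_valence_sd, -4, 4, len(top.goal_ids))
        for g, imp, gv in zip(top.goal_ids, imps, gvals):
            p.importances[g] = int(imp)
            p.valences[g] = int(gv)
        for oi, o in enumerate(top.option_ids):
            favored = pole == (1 if oi == 0 else -1)
            vshift = cfg.pole_valence_shift * (1 if favored else -1) if pole else 0.0
            bshift = cfg.pole_belief_shift * (1 if favored else -1) if pole else 0.0
            beliefs = _draw_scale(rng, cfg.belief_mean + bshift, cfg.belief_sd, 1, 6, len(top.goal_ids))
            for g, bel in zip(top.goal_ids, beliefs):
                p.beliefs[(g, o)] = int(bel)
            v_mean = (
                cfg.option_valence_mean
                + cfg.valence_belief_coupling * (beliefs.mean() - 3.5)
                + vshift
            )
            p.valences[o] = int(
                _draw_scale(rng, v_mean, cfg.option_valence_sd, -4, 4, 1)[0]
            )
        p.validate(top)
        profiles.append(p)
    return profiles


def assign_design(profiles, organized_sets, seed: int = 0) -> pd.DataFrame:
    """Give each agent one randomly chosen set of its condition.

    Each agent draws uniformly among the sets available for its
    condition and receives that set's 10 vignettes in a random
    presentation order (both from the agent's own seed substream).
    Returns a tidy frame: one row per agent x vignette with a
    ``presentation_order`` column.
    """
    sets_df = design_to_frame(organized_sets)
    by_cond = {
        cond: sorted(cdf["set_id"].unique()) for cond, cdf in sets_df.groupby("condition")
    }
    children = np.random.SeedSequence(seed).spawn(len(profiles))
    rows = []
    for i, p in enumerate(profiles):
        if p.condition not in by_cond:
            raise ValueError(f"no organized sets for condition {p.condition!r}")
        rng = np.random.default_rng(children[i])
        set_id = by_cond[p.condition][rng.integers(len(by_cond[p.condition]))]
        chosen = sets_df[sets_df["set_id"] == set_id].sort_values("position")
        order = rng.permutation(len(chosen))
        for pres, (_, r) in zip(order, chosen.iterrows()):
            rows.append(
                {
                    "agent_id": p.agent_id,
                    "presentation_order": int(pres),
                    "condition": r["condition"],
                    "option": r["option"],
                    "goal_1": r["goal_1"],
                    "goal_2": r["goal_2"],
                    "valence": r["valence"],
                    "set_id": int(r["set_id"]),
                    "position": int(r["position"]),
                }
            )
    df = pd.DataFrame(rows).sort_values(["agent_id", "presentation_order"])
    return df.reset_index(drop=True)


def _row_vignette(row) -> Vignette:
    return Vignette(
        condition=row["condition"],
        option=row["option"],
        goal_pair=(row["goal_1"], row["goal_2"]),
        valence=row["valence"],
        set_id=int(row["set_id"]),
        position=int(row["position"]),
    )


def simulate_responses(
    profiles,
    assignments: pd.DataFrame,
    true_params: dict,
    noise_sd: float = 0.0,
    seed: int = 0,
    act_params: ActivationParams | None = None,
    topology: NetworkTopology | None = None,
) -> list[ResponseRecord]:
    """Generate self-reports from a ground-truth response model.

    For every assigned treatment the true-parameter persuasion event is
    simulated (independently against the agent's baseline network);
    the reported attitude is ``A_emp = A_sim + eps`` with ``eps``
    Gaussian(0, ``noise_sd``) truncated so A_emp stays in [-1, 1].  The
    equivalent seven-point reported-change value is obtained by inverse
    rescaling of ``A_emp - A_base`` and rounding onto the scale.
    """
    ap = act_params or ActivationParams()
    top = topology or NetworkTopology()
    nets = {p.agent_id: build_network(p, top) for p in profiles}

    # baseline attitudes per agent, one batched settle
    ids = list(nets)
    W = np.array([nets[a].weights for a in ids])
    first = nets[ids[0]]
    a_base, _, _ = settle_batch(W, first.clamped_indices, first.clamped_values, ap)
    base_by_agent = {a: a_base[i] for i, a in enumerate(ids)}

    records: list[ResponseRecord] = []
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    for cond, cdf in assignments.groupby("condition", sort=True):
        params = true_params[cond]
        if not isinstance(params, LearningParams):
            params = LearningParams.from_array(params, cond)
        events = [(nets[r["agent_id"]], _row_vignette(r), None) for _, r in cdf.iterrows()]
        ds = TreatmentDataset.from_events(events, condition=cond)
        a_sim, conv = simulate_A_sim(ds, params.as_array()[None, :], ap)
        a_sim = a_sim[0]
        if noise_sd > 0:
            lo = (-1.0 - a_sim) / noise_sd
            hi = (1.0 - a_sim) / noise_sd
            a_emp = stats.truncnorm.rvs(
                lo, hi, loc=a_sim, scale=noise_sd, random_state=rng
            )
        else:
            a_emp = a_sim.copy()
        for j, (_, r) in enumerate(cdf.iterrows()):
            vig = _row_vignette(r)
            base_att = float(base_by_agent[r["agent_id"]][top.index(vig.option)])
            change = float(np.clip(a_emp[j] - base_att, -1.0, 1.0))
            reported = int(np.clip(round(inverse_rescale(change, CHANGE7)), 1, 7))
            records.append(
                ResponseRecord(
                    agent_id=r["agent_id"],
                    vignette=vig,
                    presentation_order=int(r["presentation_order"]),
                    reported_change=reported,
                    A_emp=float(a_emp[j]),
                    A_base=base_att,
                    A_sim_true=float(a_sim[j]),
                )
            )
    order = {(r["agent_id"], r["presentation_order"]): i for i, (_, r) in enumerate(assignments.iterrows())}
    records.sort(key=lambda rec: order[(rec.agent_id, rec.presentation_order)])
    return records


def responses_to_frame(records) -> pd.DataFrame:
    rows = []
    for r in records:
        v = r.vignette
        rows.append(
            {
                "agent_id": r.agent_id,
                "presentation_order": r.presentation_order,
                "condition": v.condition,
                "option": v.option,
                "goal_1": v.goal_pair[0],
                "goal_2": v.goal_pair[1],
                "valence": v.valence,
                "set_id": v.set_id,
                "reported_change": r.reported_change,
                "A_emp": r.A_emp,
                "A_base": r.A_base,
                "A_sim_true": r.A_sim_true,
            }
        )
    return pd.DataFrame(rows)


def config_hash(config) -> str:
    """Stable hash of a (dataclass or dict) configuration."""
    if not isinstance(config, dict):
        config = asdict(config)
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(path, seed: int, config, extra: dict | None = None) -> dict:
    """Record seed, config and config hash next to emitted artifacts."""
    doc = {
        "seed": int(seed),
        "config": asdict(config) if not isinstance(config, dict) else config,
        "config_hash": config_hash(config),
    }
    if extra:
        doc.update(extra)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, default=str)
    return doc
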