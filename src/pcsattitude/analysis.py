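"""Population-level simulation analyses.

Given a synthetic population, a vignette assignment and per-condition
learning coefficients, this module runs every persuasion event,
collects baseline and post-treatment attitudes, energies and per-link
weight changes, and reproduces the model-level analyses: validation of
baseline attitudes against profile-implied scores, the inverted-U
energy-versus-attitude curve, pre/post coherence by condition, binned
weight-change surfaces, and backfire rates.

The empirical "agreement with the message" rating has no synthetic
counterpart; the regression machinery accepts any supplied agreement
proxy and ships a documented default (negative mean absolute
dissonance between sender and receiver on the transmitted links).
Results using it are structural analogs, not replications.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .learning import LearningParams, TreatmentDataset, _features
from .network import ActivationParams, NetworkTopology, build_network, energy_batch, settle_batch
from .scales import IMPORTANCE6, LIKERT6
from .synth import _row_vignette

__all__ = [
    "PopulationResult",
    "run_treatments",
    "profile_implied_scores",
    "validate_prior_attitudes",
    "quadratic_fit",
    "energy_attitude_curve",
    "pre_post_energy",
    "weight_change_surface",
    "backfire_rate",
    "agreement_proxy",
    "agreement_energy_regression",
]


@dataclass
class PopulationResult:
    """All simulated quantities for one population run.

    ``baselines``: one row per agent (condition, baseline energy, one
    ``attitude_<option>`` column per option).
    ``treatments``: one row per persuasion event (A_base, A_sim,
    optional A_emp, pre/post energy, convergence flag).
    ``links``: one row per transmitted link per event (w_s, w_r_pre,
    w_r_post, link type "belief" or "affect").
    """

    baselines: pd.DataFrame
    treatments: pd.DataFrame
    links: pd.DataFrame
    topology: NetworkTopology

    def condition_counts(self) -> pd.Series:
        return self.treatments.groupby("condition").size()


def run_treatments(
    profiles,
    assignments: pd.DataFrame,
    params: dict,
    act_params: ActivationParams | None = None,
    topology: NetworkTopology | None = None,
    responses: pd.DataFrame | None = None,
    cumulative: bool = False,
) -> PopulationResult:
    """Simulate every assigned persuasion event.

    ``params`` maps condition -> LearningParams (or 5-vector).  Each
    event is applied independently to the agent's baseline network and
    re-settled (``cumulative=True`` instead carries each agent's
    network forward through its sequence).  If ``responses`` (a frame
    with agent_id, presentation_order, A_emp) is given, reported
    attitudes are merged into the treatment table.
    """
    if cumulative:
        return _run_treatments_sequential(
            profiles, assignments, params, act_params, topology, responses, True
        )
    ap = act_params or ActivationParams()
    top = topology or NetworkTopology()
    nets = {p.agent_id: build_network(p, top) for p in profiles}
    ids = list(nets)
    first = nets[ids[0]]
    W0 = np.array([nets[a].weights for a in ids])
    a0, it0, conv0 = settle_batch(W0, first.clamped_indices, first.clamped_values, ap)
    e0 = energy_batch(W0, a0)
    opt_idx = top.option_indices
    base_rows = pd.DataFrame(
        {
            "agent_id": ids,
            "condition": [p.condition for p in profiles],
            "energy": e0,
            "iterations": it0,
            "converged": conv0,
            **{
                f"attitude_{o}": a0[:, opt_idx[k]]
                for k, o in enumerate(top.option_ids)
            },
        }
    )
    agent_pos = {a: i for i, a in enumerate(ids)}

    treat_rows = []
    link_rows = []
    for cond, cdf in assignments.groupby("condition", sort=True):
        p = params[cond]
        if not isinstance(p, LearningParams):
            p = LearningParams.from_array(p, cond)
        events = [(nets[r["agent_id"]], _row_vignette(r), None) for _, r in cdf.iterrows()]
        ds = TreatmentDataset.from_events(events, condition=cond)
        w_r = ds.w_r
        dw = _features(ds.w_s - w_r, w_r) @ p.as_array()
        post_w = np.clip(w_r + dw, -1.0, 1.0)
        Wp = ds.base_W.copy()
        rows = np.arange(ds.n)[:, None]
        Wp[rows, ds.link_i, ds.link_j] = post_w
        Wp[rows, ds.link_j, ds.link_i] = post_w
        a_post, _, conv = settle_batch(Wp, ds.clamp_idx, ds.clamp_val, ap)
        e_post = energy_batch(Wp, a_post)
        labels = top.labels
        for j, (_, r) in enumerate(cdf.iterrows()):
            ai = agent_pos[r["agent_id"]]
            oidx = ds.option_idx[j]
            treat_rows.append(
                {
                    "agent_id": r["agent_id"],
                    "condition": cond,
                    "option": r["option"],
                    "goal_1": r["goal_1"],
                    "goal_2": r["goal_2"],
                    "valence": r["valence"],
                    "set_id": int(r["set_id"]),
                    "presentation_order": int(r["presentation_order"]),
                    "A_base": float(a0[ai, oidx]),
                    "A_sim": float(a_post[j, oidx]),
                    "energy_pre": float(e0[ai]),
                    "energy_post": float(e_post[j]),
                    "converged": bool(conv0[ai] and conv[j]),
                }
            )
            tid = len(treat_rows) - 1
            for l in range(ds.w_s.shape[1]):
                na, nb = labels[ds.link_i[j, l]], labels[ds.link_j[j, l]]
                link_type = "affect" if top.valence_id in (na, nb) else "belief"
                link_rows.append(
                    {
                        "treatment_idx": tid,
                        "agent_id": r["agent_id"],
                        "condition": cond,
                        "valence": r["valence"],
                        "link_type": link_type,
                        "node_a": na,
                        "node_b": nb,
                        "w_s": float(ds.w_s[j, l]),
                        "w_r_pre": float(w_r[j, l]),
                        "w_r_post": float(post_w[j, l]),
                    }
                )
    treatments = pd.DataFrame(treat_rows)
    if responses is not None:
        treatments = treatments.merge(
            responses[["agent_id", "presentation_order", "A_emp"]],
            on=["agent_id", "presentation_order"],
            how="left",
        )
    return PopulationResult(
        baselines=base_rows,
        treatments=treatments,
        links=pd.DataFrame(link_rows),
        topology=top,
    )


def _run_treatments_sequential(
    profiles, assignments, params, act_params, topology, responses, cumulative
) -> PopulationResult:
    """Per-agent loop used for the cumulative treatment mode."""
    from .learning import simulate_sequence
    from .network import energy as energy_of, settle

    ap = act_params or ActivationParams()
    top = topology or NetworkTopology()
    base_rows, treat_rows, link_rows = [], [], []
    for p in profiles:
        net = build_network(p, top)
        base = settle(net.copy(), ap)
        base_rows.append(
            {
                "agent_id": p.agent_id,
                "condition": p.condition,
                "energy": energy_of(net, base.activations),
                "iterations": base.iterations,
                "converged": base.converged,
                **{
                    f"attitude_{o}": base.activation(o) for o in top.option_ids
                },
            }
        )
        adf = assignments[assignments["agent_id"] == p.agent_id].sort_values(
            "presentation_order"
        )
        vigs = [_row_vignette(r) for _, r in adf.iterrows()]
        lp = params[p.condition]
        if not isinstance(lp, LearningParams):
            lp = LearningParams.from_array(lp, p.condition)
        recs = simulate_sequence(net, vigs, lp, ap, cumulative=cumulative, agent_id=p.agent_id)
        for (_, r), rec in zip(adf.iterrows(), recs):
            treat_rows.append(
                {
                    "agent_id": p.agent_id,
                    "condition": r["condition"],
                    "option": r["option"],
                    "goal_1": r["goal_1"],
                    "goal_2": r["goal_2"],
                    "valence": r["valence"],
                    "set_id": int(r["set_id"]),
                    "presentation_order": int(r["presentation_order"]),
                    "A_base": rec.A_base,
                    "A_sim": rec.A_sim,
                    "energy_pre": rec.energy_pre,
                    "energy_post": rec.energy_post,
                    "converged": rec.converged,
                }
            )
            tid = len(treat_rows) - 1
            for entry in rec.links:
                na, nb = sorted(entry["link"])
                link_rows.append(
                    {
                        "treatment_idx": tid,
                        "agent_id": p.agent_id,
                        "condition": r["condition"],
                        "valence": r["valence"],
                        "link_type": "affect" if top.valence_id in (na, nb) else "belief",
                        "node_a": na,
                        "node_b": nb,
                        "w_s": entry["w_s"],
                        "w_r_pre": entry["w_r_pre"],
                        "w_r_post": entry["w_r_post"],
                    }
                )
    treatments = pd.DataFrame(treat_rows)
    if responses is not None:
        treatments = treatments.merge(
            responses[["agent_id", "presentation_order", "A_emp"]],
            on=["agent_id", "presentation_order"],
            how="left",
        )
    return PopulationResult(
        baselines=pd.DataFrame(base_rows),
        treatments=treatments,
        links=pd.DataFrame(link_rows),
        topology=top,
    )


def profile_implied_scores(profiles, topology: NetworkTopology | None = None) -> pd.DataFrame:
    """Importance-weighted mean of rescaled beliefs, per agent x option.

    score(o) = sum_g imp_g * belief_{g,o} / sum_g imp_g with importances
    rescaled to [0, 1] and beliefs to [-1, 1]; a direct survey-side
    attitude summary against which settled option activations are
    validated.
    """
    top = topology or NetworkTopology()
    rows = []
    for p in profiles:
        imps = np.array([IMPORTANCE6.rescale(p.importances[g]) for g in top.goal_ids])
        denom = imps.sum()
        row = {"agent_id": p.agent_id}
        for o in top.option_ids:
            bel = np.array([LIKERT6.rescale(p.beliefs[(g, o)]) for g in top.goal_ids])
            row[f"score_{o}"] = float((imps * bel).sum() / denom) if denom > 0 else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def validate_prior_attitudes(
    population: PopulationResult, profiles, topology: NetworkTopology | None = None
) -> dict:
    """Pearson r per option between settled baseline attitudes and
    profile-implied scores.  Zero-variance inputs yield ``nan``.
    """
    top = topology or population.topology
    scores = profile_implied_scores(profiles, top)
    merged = population.baselines.merge(scores, on="agent_id")
    out = {}
    for o in top.option_ids:
        x = merged[f"attitude_{o}"].to_numpy()
        y = merged[f"score_{o}"].to_numpy()
        if np.std(x) == 0 or np.std(y) == 0:
            out[o] = float("nan")
        else:
            out[o] = float(stats.pearsonr(x, y).statistic)
    return out


def quadratic_fit(x, y) -> dict:
    """Least-squares fit y = c0 + c1 x + c2 x^2 with R-squared."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 3:
        raise ValueError("need at least 3 points for a quadratic fit")
    X = np.stack([np.ones_like(x), x, x * x], axis=1)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    ss_res = float(np.sum(resid**2))
    r2 = 0.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return {"c0": float(coef[0]), "c1": float(coef[1]), "c2": float(coef[2]), "r_squared": r2}


def energy_attitude_curve(population: PopulationResult) -> dict:
    """Quadratic fit of baseline energy on baseline attitude, per option.

    A negative quadratic coefficient (concave, inverted U) means both
    strongly negative and strongly positive attitudes come with low
    energy (high coherence) while ambivalence sits at high energy.
    """
    out = {}
    for o in population.topology.option_ids:
        fit = quadratic_fit(
            population.baselines[f"attitude_{o}"], population.baselines["energy"]
        )
        fit["c2_sign"] = int(np.sign(fit["c2"]))
        out[o] = fit
    return out


def pre_post_energy(
    population: PopulationResult, n_boot: int = 1000, seed: int = 0
) -> pd.DataFrame:
    """Mean network energy before/after treatment per condition.

    The paired per-treatment difference (post - pre) gets a seeded
    bootstrap percentile interval; negative differences mean coherence
    increased.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for cond, cdf in population.treatments.groupby("condition", sort=True):
        diff = (cdf["energy_post"] - cdf["energy_pre"]).to_numpy()
        boots = np.array(
            [diff[rng.integers(0, len(diff), len(diff))].mean() for _ in range(n_boot)]
        )
        rows.append(
            {
                "condition": cond,
                "n": len(cdf),
                "mean_pre": float(cdf["energy_pre"].mean()),
                "mean_post": float(cdf["energy_post"].mean()),
                "mean_diff": float(diff.mean()),
                "diff_ci_low": float(np.quantile(boots, 0.025)),
                "diff_ci_high": float(np.quantile(boots, 0.975)),
            }
        )
    return pd.DataFrame(rows)


def weight_change_surface(links: pd.DataFrame, bin_width: float = 0.5) -> pd.DataFrame:
    """Mean applied weight change binned by prior and sender weight.

    Bins cover [-1, 1] at ``bin_width``; combinations never observed
    are absent from the table (missing, not zero).  The change is the
    realized (clipped) ``w_r_post - w_r_pre``.
    """
    edges = np.round(np.arange(-1.0, 1.0 + bin_width / 2, bin_width), 10)
    df = links.copy()
    df["dw"] = df["w_r_post"] - df["w_r_pre"]
    df["w_r_bin"] = pd.cut(df["w_r_pre"], edges, include_lowest=True)
    df["w_s_bin"] = pd.cut(df["w_s"], edges, include_lowest=True)
    grouped = (
        df.groupby(["condition", "link_type", "w_r_bin", "w_s_bin"], observed=True)["dw"]
        .agg(["mean", "count"])
        .reset_index()
        .rename(columns={"mean": "mean_dw", "count": "n"})
    )
    return grouped[grouped["n"] > 0].reset_index(drop=True)


def backfire_rate(treatments: pd.DataFrame, tol: float = 1e-9) -> pd.DataFrame:
    """Share of events moving the attitude against the message.

    An event backfires when sign(A_sim - A_base) opposes the message
    valence by more than ``tol`` (no movement is no backfire).
    Stratified by condition x valence x prior-attitude sign.
    """
    df = treatments.copy()
    sign = np.where(df["valence"] == "positive", 1.0, -1.0)
    move = (df["A_sim"] - df["A_base"]).to_numpy()
    df["backfired"] = move * sign < -tol
    df["prior_sign"] = np.select(
        [df["A_base"] > tol, df["A_base"] < -tol], ["positive", "negative"], "neutral"
    )
    out = (
        df.groupby(["condition", "valence", "prior_sign"], observed=True)["backfired"]
        .agg(["mean", "count"])
        .reset_index()
        .rename(columns={"mean": "rate", "count": "n"})
    )
    return out


def agreement_proxy(population: PopulationResult) -> pd.Series:
    """Default agreement stand-in: negative mean |w_s - w_r_pre|.

    The empirical agreement rating is unavailable for synthetic agents;
    low dissonance between transmitted and held weights plays its
    structural role.  Indexed by treatment row.
    """
    d = population.links.copy()
    d["abs_diss"] = (d["w_s"] - d["w_r_pre"]).abs()
    return -d.groupby("treatment_idx")["abs_diss"].mean()


def agreement_energy_regression(
    population: PopulationResult, agreement: pd.Series | None = None
) -> pd.DataFrame:
    """Quadratic regression of baseline energy on agreement.

    Runs per condition x valence on the supplied agreement values (or
    the :func:`agreement_proxy` default) — a structural analog of the
    empirical agreement-coherence analysis, not a replication.
    """
    agree = agreement_proxy(population) if agreement is None else agreement
    df = population.treatments.copy()
    df["agreement"] = df.index.map(agree)
    rows = []
    for (cond, val), g in df.groupby(["condition", "valence"], sort=True):
        if g["agreement"].std() == 0 or len(g) < 3:
            continue
        fit = quadratic_fit(g["agreement"], g["energy_pre"])
        rows.append({"condition": cond, "valence": val, "n": len(g), **fit})
    return pd.DataFrame(rows)
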