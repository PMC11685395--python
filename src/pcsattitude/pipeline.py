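"""End-to-end experiment runs: generate -> settle -> treat -> fit -> analyze.

A run is fully determined by a :class:`RunConfig` (one master seed plus
the sub-configurations of every stage); identical configs give
byte-identical artifacts.  Artifacts are tidy CSV tables plus JSON
summaries and a manifest recording the seed, config hash, stage
timings and exclusion counts.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .analysis import (
    backfire_rate,
    energy_attitude_curve,
    pre_post_energy,
    run_treatments,
    validate_prior_attitudes,
    weight_change_surface,
)
from .design import design_to_frame, enumerate_design, organize_sets, validate_sets
from .learning import (
    FitConfig,
    LearningParams,
    REPORTED_PARAMS,
    TreatmentDataset,
    fit_params,
)
from .network import ActivationParams, NetworkTopology, build_network
from .profiles import write_profiles
from .synth import (
    PopulationConfig,
    assign_design,
    config_hash,
    responses_to_frame,
    sample_profiles,
    simulate_responses,
    write_manifest,
    _row_vignette,
)

__all__ = ["RunConfig", "run_experiment", "validate_run"]


@dataclass
class RunConfig:
    """Everything an experiment run depends on.

    ``true_params`` (condition -> b1..b5) drive the ground-truth
    response generator; the published per-condition optima are the
    default.  ``fit_enabled`` toggles the grid-search fitting stage
    (when off, analyses use the true parameters).  ``cumulative``
    switches treatments from independent-per-vignette (default) to
    sequential carry-over within each agent.
    """

    seed: int
    out_dir: str = "run_output"
    population: PopulationConfig = field(default_factory=PopulationConfig)
    activation: ActivationParams = field(default_factory=ActivationParams)
    fit: FitConfig = field(default_factory=FitConfig)
    sets_per_condition: int = 4
    noise_sd: float = 0.05
    true_params: dict = field(default_factory=lambda: dict(REPORTED_PARAMS))
    fit_enabled: bool = True
    cumulative: bool = False
    clamp_valence: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "seed" not in raw:
            raise ValueError("config must set a seed")
        kwargs = dict(raw)
        if "population" in kwargs:
            kwargs["population"] = PopulationConfig(
                **{
                    **kwargs["population"],
                    **(
                        {"conditions": tuple(kwargs["population"]["conditions"])}
                        if "conditions" in kwargs["population"]
                        else {}
                    ),
                }
            )
        if "activation" in kwargs:
            kwargs["activation"] = ActivationParams(**kwargs["activation"])
        if "fit" in kwargs:
            fk = dict(kwargs["fit"])
            if "bounds" in fk:
                fk["bounds"] = tuple(fk["bounds"])
            kwargs["fit"] = FitConfig(**fk)
        if "true_params" in kwargs:
            kwargs["true_params"] = {
                k: tuple(v) for k, v in kwargs["true_params"].items()
            }
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["true_params"] = {k: list(v) for k, v in self.true_params.items()}
        return d


def _stage(manifest: dict, name: str):
    """Context manager recording a stage's wall time or failure."""

    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            manifest["stage_timings"][name] = round(time.perf_counter() - self.t0, 3)
            if exc is not None:
                manifest["failed_stage"] = name
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
            return False

    return _Ctx()


def run_experiment(config: RunConfig, topology: NetworkTopology | None = None) -> dict:
    """Execute all stages in order and write artifacts under ``out_dir``.

    Returns the manifest.  Any stage failure aborts with the stage name;
    artifacts of completed stages remain on disk.
    """
    top = topology or NetworkTopology()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    seeds = {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(
            ("profiles", "sets", "assign", "responses", "bootstrap"), ss.spawn(5)
        )
    }
    manifest: dict = {
        "seed": config.seed,
        "derived_seeds": seeds,
        "config": config.to_dict(),
        "config_hash": config_hash(config.to_dict()),
        "version": __version__,
        "stage_timings": {},
        "counts": {},
        "exclusions": {},
    }

    with _stage(manifest, "generate"):
        profiles = sample_profiles(
            seed=seeds["profiles"], config=config.population, topology=top
        )
        write_profiles(profiles, out / "profiles.csv")
        manifest["counts"]["agents"] = len(profiles)

    with _stage(manifest, "design"):
        design = enumerate_design(top, conditions=config.population.conditions)
        sets = organize_sets(
            design, sets_per_condition=config.sets_per_condition, seed=seeds["sets"]
        )
        design_to_frame(sets).to_csv(out / "design.csv", index=False)
        manifest["counts"]["vignettes"] = len(design)

    with _stage(manifest, "assign"):
        assignments = assign_design(profiles, sets, seed=seeds["assign"])
        assignments.to_csv(out / "assignments.csv", index=False)
        manifest["counts"]["treatments"] = len(assignments)
        manifest["counts"]["treatments_per_condition"] = {
            k: int(v) for k, v in assignments.groupby("condition").size().items()
        }

    with _stage(manifest, "simulate"):
        records = simulate_responses(
            profiles,
            assignments,
            config.true_params,
            noise_sd=config.noise_sd,
            seed=seeds["responses"],
            act_params=config.activation,
            topology=top,
        )
        responses = responses_to_frame(records)
        responses.to_csv(out / "responses.csv", index=False)

    with _stage(manifest, "fit"):
        fitted: dict = {}
        fit_doc: dict = {}
        if config.fit_enabled:
            nets = {p.agent_id: build_network(p, top) for p in profiles}
            merged = assignments.merge(
                responses[["agent_id", "presentation_order", "A_emp"]],
                on=["agent_id", "presentation_order"],
            )
            for cond, cdf in merged.groupby("condition", sort=True):
                events = [
                    (nets[r["agent_id"]], _row_vignette(r), r["A_emp"])
                    for _, r in cdf.iterrows()
                ]
                ds = TreatmentDataset.from_events(events, condition=cond)
                params, diag = fit_params(ds, config.fit, config.activation)
                fitted[cond] = params
                fit_doc[cond] = {
                    "b1": params.b1,
                    "b2": params.b2,
                    "b3": params.b3,
                    "b4": params.b4,
                    "b5": params.b5,
                    **diag,
                }
                manifest["exclusions"][cond] = diag["n_excluded"]
        else:
            fitted = {
                c: LearningParams.from_array(b, c)
                for c, b in config.true_params.items()
            }
            fit_doc = {"skipped": True}
        with open(out / "fitted_params.json", "w") as fh:
            json.dump(fit_doc, fh, indent=1)
        manifest["counts"]["fitted_parameter_sets"] = len(fitted)

    with _stage(manifest, "analyze"):
        population = run_treatments(
            profiles,
            assignments,
            fitted,
            act_params=config.activation,
            topology=top,
            responses=responses,
            cumulative=config.cumulative,
        )
        population.baselines.to_csv(out / "baselines.csv", index=False)
        population.treatments.to_csv(out / "treatments.csv", index=False)
        population.links.to_csv(out / "links.csv", index=False)
        pre_post_energy(population, seed=seeds["bootstrap"]).to_csv(
            out / "pre_post_energy.csv", index=False
        )
        backfire_rate(population.treatments).to_csv(out / "backfire.csv", index=False)
        weight_change_surface(population.links).to_csv(
            out / "weight_surface.csv", index=False
        )
        summary = {
            "energy_attitude_curve": energy_attitude_curve(population),
            "prior_attitude_validation": validate_prior_attitudes(population, profiles),
        }
        with open(out / "analysis_summary.json", "w") as fh:
            json.dump(summary, fh, indent=1)
        manifest["exclusions"]["non_convergent_treatments"] = int(
            (~population.treatments["converged"]).sum()
        )

    write_manifest(out / "manifest.json", config.seed, config.to_dict(), extra=manifest)
    return manifest


ARTIFACTS = (
    "profiles.csv",
    "design.csv",
    "assignments.csv",
    "responses.csv",
    "fitted_params.json",
    "baselines.csv",
    "treatments.csv",
    "links.csv",
    "pre_post_energy.csv",
    "backfire.csv",
    "weight_surface.csv",
    "analysis_summary.json",
    "manifest.json",
)


def validate_run(out_dir) -> dict:
    """Re-check the structural invariants of a completed run.

    Verifies artifact presence, count consistency, weight/attitude
    bounds, design balance, and — when the run's parameters are all
    zero — the no-change (null pipeline) property.  Returns a report
    ``{"passed": bool, "violations": [...]}``.
    """
    out = Path(out_dir)
    violations: list[str] = []
    missing = [name for name in ARTIFACTS if not (out / name).exists()]
    if missing:
        return {"passed": False, "violations": [f"missing artifact: {m}" for m in missing]}

    with open(out / "manifest.json") as fh:
        manifest = json.load(fh)
    treatments = pd.read_csv(out / "treatments.csv")
    links = pd.read_csv(out / "links.csv")
    assignments = pd.read_csv(out / "assignments.csv")
    design = pd.read_csv(out / "design.csv")

    counts = manifest.get("counts", {})
    if len(treatments) != counts.get("treatments"):
        violations.append("treatment count does not match manifest")
    per_cond = treatments.groupby("condition").size()
    if per_cond.nunique() > 1:
        violations.append("unequal per-condition treatment counts")
    n_agents = counts.get("agents", 0)
    if len(assignments) != n_agents * 10:
        violations.append("assignments != agents x 10")

    from .design import frame_to_design

    try:
        validate_sets(frame_to_design(design))
    except ValueError as e:
        violations.append(f"design balance: {e}")

    for col in ("A_base", "A_sim"):
        if (treatments[col].abs() > 1 + 1e-9).any():
            violations.append(f"{col} outside [-1, 1]")
    for col in ("w_s", "w_r_pre", "w_r_post"):
        if (links[col].abs() > 1 + 1e-9).any():
            violations.append(f"{col} outside [-1, 1]")

    params_doc = json.load(open(out / "fitted_params.json"))
    b_vals = [
        params_doc[c][k]
        for c in params_doc
        if isinstance(params_doc[c], dict)
        for k in ("b1", "b2", "b3", "b4", "b5")
        if k in params_doc[c]
    ]
    run_cfg = manifest.get("config", {})
    if not run_cfg.get("fit_enabled", True):
        b_vals = [v for bs in run_cfg.get("true_params", {}).values() for v in bs]
    if b_vals and all(v == 0 for v in b_vals):
        if not np.allclose(treatments["A_sim"], treatments["A_base"]):
            violations.append("null pipeline: A_sim differs from baseline")
        if not np.allclose(treatments["energy_post"], treatments["energy_pre"]):
            violations.append("null pipeline: energy changed")
        if not np.allclose(links["w_r_post"], links["w_r_pre"]):
            violations.append("null pipeline: weights changed")

    return {"passed": not violations, "violations": violations}
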