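import numpy as np
import pandas as pd
import pytest

from pcsattitude import (
    LearningParams,
    Vignette,
    build_network,
    settle,
    simulate_treatment,
)
from pcsattitude.analysis import (
    agreement_energy_regression,
    agreement_proxy,
    backfire_rate,
    energy_attitude_curve,
    pre_post_energy,
    profile_implied_scores,
    quadratic_fit,
    run_treatments,
    validate_prior_attitudes,
    weight_change_surface,
)
from pcsattitude.design import enumerate_design, organize_sets
from pcsattitude.learning import REPORTED_PARAMS
from pcsattitude.synth import PopulationConfig, assign_design, sample_profiles

ZERO = {c: LearningParams.zero(c) for c in REPORTED_PARAMS}
REPORTED = {c: LearningParams.reported(c) for c in REPORTED_PARAMS}


@pytest.fixture(scope="module")
def population(organized_sets):
    profiles = sample_profiles(seed=41, config=PopulationConfig(n_agents=24))
    assign = assign_design(profiles, organized_sets, seed=42)
    return profiles, assign


@pytest.fixture(scope="module")
def result(population, organized_sets):
    profiles, assign = population
    return run_treatments(profiles, assign, REPORTED)


class TestQuadraticFit:
    def test_exact_concave_parabola(self):
        x = np.linspace(-1, 1, 20)
        y = 3 - 0.5 * x - 2 * x * x
        fit = quadratic_fit(x, y)
        assert fit["r_squared"] == pytest.approx(1.0)
        assert fit["c2"] == pytest.approx(-2.0)
        assert fit["c2"] < 0

    def test_constant_energy(self):
        x = np.linspace(-1, 1, 10)
        fit = quadratic_fit(x, np.full(10, 5.0))
        assert fit["c1"] == pytest.approx(0.0, abs=1e-9)
        assert fit["c2"] == pytest.approx(0.0, abs=1e-9)
        assert fit["r_squared"] == 0.0

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            quadratic_fit([0, 1], [0, 1])

    def test_matches_textbook_closed_form_on_hand_example(self):
        # 5-point example solved via the normal equations independently
        x = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        y = np.array([1.0, 0.0, 1.0, 2.0, 2.0])
        X = np.stack([np.ones(5), x, x * x], axis=1)
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        fit = quadratic_fit(x, y)
        assert [fit["c0"], fit["c1"], fit["c2"]] == pytest.approx(list(beta))


class TestPriorAttitudeValidation:
    def test_perfect_and_negated_scores(self, population, result):
        profiles, _ = population
        scores = profile_implied_scores(profiles)
        pop = result
        # graft the implied scores in as the "simulated" attitudes
        forged = pop.baselines.copy()
        for o in pop.topology.option_ids:
            forged[f"attitude_{o}"] = forged["agent_id"].map(
                scores.set_index("agent_id")[f"score_{o}"]
            )
        import dataclasses

        forged_pop = dataclasses.replace(pop, baselines=forged)
        rs = validate_prior_attitudes(forged_pop, profiles)
        assert all(r == pytest.approx(1.0) for r in rs.values())
        for o in pop.topology.option_ids:
            forged[f"attitude_{o}"] = -forged[f"attitude_{o}"]
        rs = validate_prior_attitudes(dataclasses.replace(pop, baselines=forged), profiles)
        assert all(r == pytest.approx(-1.0) for r in rs.values())

    def test_pearson_matches_hand_formula(self, population, result):
        profiles, _ = population
        rs = validate_prior_attitudes(result, profiles)
        scores = profile_implied_scores(profiles)
        merged = result.baselines.merge(scores, on="agent_id")
        for o in result.topology.option_ids:
            x = merged[f"attitude_{o}"].to_numpy()
            y = merged[f"score_{o}"].to_numpy()
            hand = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
                np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
            )
            assert rs[o] == pytest.approx(hand, rel=1e-12)

    def test_zero_variance_reported_as_nan(self, population, result):
        import dataclasses

        profiles, _ = population
        flat = result.baselines.copy()
        for o in result.topology.option_ids:
            flat[f"attitude_{o}"] = 0.5
        rs = validate_prior_attitudes(dataclasses.replace(result, baselines=flat), profiles)
        assert all(np.isnan(r) for r in rs.values())


class TestEnergyCurve:
    def test_reports_sign_and_fit(self, result):
        curves = energy_attitude_curve(result)
        for o in result.topology.option_ids:
            assert set(curves[o]) >= {"c0", "c1", "c2", "r_squared", "c2_sign"}
            assert curves[o]["c2_sign"] == np.sign(curves[o]["c2"])


class TestPrePostEnergy:
    def test_zero_params_no_change(self, population):
        profiles, assign = population
        pop = run_treatments(profiles, assign, ZERO)
        pp = pre_post_energy(pop, n_boot=50, seed=0)
        assert np.allclose(pp["mean_pre"], pp["mean_post"])
        assert np.allclose(pp["mean_diff"], 0.0)

    def test_single_agent_reinforcement_decreases_energy(self, topology):
        # one satisfied belief link strengthened by pure reinforcement:
        # coherence rises, energy strictly drops
        from helpers import make_profile

        profile = make_profile(topology, belief=5, goal_valence=2, option_valence=2)
        net = build_network(profile, topology)
        vig = Vignette(
            condition="rational",
            option="e_car",
            goal_pair=("comfort", "eco_friendliness"),
            valence="positive",
        )
        rec = simulate_treatment(net, vig, LearningParams(0, 0.5, 0, 0, 0))
        assert rec.energy_post < rec.energy_pre

    def test_bootstrap_interval_brackets_mean(self, result):
        pp = pre_post_energy(result, n_boot=200, seed=1)
        assert ((pp["diff_ci_low"] <= pp["mean_diff"]) & (pp["mean_diff"] <= pp["diff_ci_high"])).all()


class TestWeightSurface:
    def test_zero_params_all_bins_zero(self, population):
        profiles, assign = population
        pop = run_treatments(profiles, assign, ZERO)
        surf = weight_change_surface(pop.links)
        assert np.allclose(surf["mean_dw"], 0.0)

    def test_pure_dissonance_rule_matches_closed_form(self, population):
        # with only b1 = 1 and |w_r + delta| <= 1 the realized change is
        # exactly w_s - w_r, so bin means equal bin means of (w_s - w_r)
        profiles, assign = population
        b1_only = {c: LearningParams(1, 0, 0, 0, 0, c) for c in REPORTED_PARAMS}
        pop = run_treatments(profiles, assign, b1_only)
        links = pop.links.copy()
        surf = weight_change_surface(links, bin_width=0.5)
        links["expected"] = links["w_s"] - links["w_r_pre"]
        edges = np.round(np.arange(-1, 1.25, 0.5), 10)
        links["w_r_bin"] = pd.cut(links["w_r_pre"], edges, include_lowest=True)
        links["w_s_bin"] = pd.cut(links["w_s"], edges, include_lowest=True)
        exp = (
            links.groupby(["condition", "link_type", "w_r_bin", "w_s_bin"], observed=True)[
                "expected"
            ]
            .mean()
            .dropna()
        )
        got = surf.set_index(["condition", "link_type", "w_r_bin", "w_s_bin"])["mean_dw"]
        assert np.allclose(got.sort_index(), exp.sort_index())

    def test_opposing_prior_bins_negative_under_rational_optimum(self, result):
        surf = weight_change_surface(result.links)
        belief = surf[(surf.condition == "rational") & (surf.link_type == "belief")]
        opposing = belief[
            belief["w_r_bin"].apply(lambda b: b.right <= 0)
            & belief["w_s_bin"].apply(lambda b: b.left >= 0.5)
        ]
        assert len(opposing) > 0
        pooled = np.average(opposing["mean_dw"], weights=opposing["n"])
        assert pooled < 0


class TestBackfire:
    def test_zero_params_rate_zero(self, population):
        profiles, assign = population
        pop = run_treatments(profiles, assign, ZERO)
        assert (backfire_rate(pop.treatments)["rate"] == 0.0).all()

    def test_pure_assimilation_never_moves_weights_against_message(self, population):
        # under b1-only learning every transmitted weight moves toward
        # the sender; attitude-level backfire can still arise through
        # the network (a strengthened belief about an unpleasant goal
        # lowers the option's activation), so the invariant is stated
        # at the weight level
        profiles, assign = population
        b1_only = {c: LearningParams(0.8, 0, 0, 0, 0, c) for c in REPORTED_PARAMS}
        pop = run_treatments(profiles, assign, b1_only)
        links = pop.links
        toward = np.sign(links["w_s"] - links["w_r_pre"])
        moved = np.sign(links["w_r_post"] - links["w_r_pre"])
        assert ((moved == toward) | (moved == 0)).all()


class TestBookkeeping:
    def test_counts_match_design(self, result, population):
        profiles, _ = population
        counts = result.condition_counts()
        per_cond = pd.Series([p.condition for p in profiles]).value_counts()
        for cond in counts.index:
            assert counts[cond] == per_cond[cond] * 10

    def test_batch_matches_single_treatment_path(self, result, population):
        # spot-check a few events against the one-at-a-time simulator
        profiles, assign = population
        by_id = {p.agent_id: p for p in profiles}
        rows = result.treatments.iloc[[0, 57, 123]]
        for _, r in rows.iterrows():
            net = build_network(by_id[r["agent_id"]], result.topology)
            vig = Vignette(
                condition=r["condition"],
                option=r["option"],
                goal_pair=(r["goal_1"], r["goal_2"]),
                valence=r["valence"],
            )
            rec = simulate_treatment(net, vig, REPORTED[r["condition"]])
            assert rec.A_sim == pytest.approx(r["A_sim"], abs=1e-12)
            assert rec.A_base == pytest.approx(r["A_base"], abs=1e-12)
            assert rec.energy_pre == pytest.approx(r["energy_pre"], abs=1e-9)
            assert rec.energy_post == pytest.approx(r["energy_post"], abs=1e-9)

    def test_cumulative_mode_chains_within_agent(self, population):
        profiles, assign = population
        pop = run_treatments(profiles, assign, REPORTED, cumulative=True)
        one = pop.treatments[pop.treatments.agent_id == profiles[0].agent_id]
        one = one.sort_values("presentation_order")
        # each event's pre-energy equals the previous event's post-energy
        assert np.allclose(
            one["energy_pre"].to_numpy()[1:], one["energy_post"].to_numpy()[:-1]
        )


class TestAgreementAnalog:
    def test_proxy_and_regression_produce_finite_fits(self, result):
        proxy = agreement_proxy(result)
        assert proxy.between(-2, 0).all()
        reg = agreement_energy_regression(result)
        assert len(reg) > 0
        assert np.isfinite(reg[["c0", "c1", "c2", "r_squared"]]).all().all()
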