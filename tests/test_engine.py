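"""Engine: capacity queue, simulation runs, ensembles, aggregation."""

import numpy as np
import pandas as pd
import pytest

from ibdsim import engine
from ibdsim.engine import (
    CHANNELS,
    CapacityModel,
    RunSpec,
    aggregate_monthly,
    apply_capacity,
    apply_capacity_single,
    run_ensemble,
    run_simulation,
)
from ibdsim.errors import ConfigError
from ibdsim.pathway import (
    AgentDraws,
    N_DRAWS,
    PathwayParameters,
    SUPPLY_SERVICES,
    advance_incidence,
    step_agent,
)
from ibdsim.scenarios import ScenarioModifiers


class TestCapacityQueue:
    def test_slack_capacity_serves_all_demand(self):
        step = apply_capacity_single(10, 100, 1.0, 0.0, 0.25, 0.05)
        assert step.served == 10 and step.backlog == 0

    def test_binding_capacity_queues_the_rest(self):
        step = apply_capacity_single(10, 4, 1.0, 0.0, 0.25, 0.0)
        assert step.served == 4 and step.backlog == 6

    def test_full_abandonment_empties_queue(self):
        step = apply_capacity_single(10, 4, 1.0, 50.0, 0.25, 1.0)
        assert step.backlog == 0

    def test_zero_multiplier_blocks_even_infinite_capacity(self):
        step = apply_capacity_single(10, np.inf, 0.0, 0.0, 0.25, 0.0)
        assert step.served == 0 and step.backlog == 10

    def test_backlog_admitted_after_fresh_demand(self):
        # capacity 10: fresh 6 served first, then 4 of the admitted backlog
        step = apply_capacity_single(6, 10, 1.0, 20.0, 0.5, 0.0)
        assert step.fresh_served == 6
        assert step.backlog_served == 4
        assert step.backlog == 20 - 4

    def test_all_services_updated(self):
        cap = CapacityModel(
            weekly_capacity={s: 5.0 for s in SUPPLY_SERVICES},
            backlog_service_rate=0.5,
            abandonment_rate=0.0,
        )
        steps, backlog = apply_capacity(
            {s: 8.0 for s in SUPPLY_SERVICES}, cap, {s: 1.0 for s in SUPPLY_SERVICES},
            {s: 0.0 for s in SUPPLY_SERVICES},
        )
        assert all(steps[s].served == 5.0 for s in SUPPLY_SERVICES)
        assert all(backlog[s] == 3.0 for s in SUPPLY_SERVICES)

    def test_negative_demand_rejected(self):
        with pytest.raises(ConfigError):
            apply_capacity_single(-1, 10, 1.0, 0.0, 0.25, 0.05)


@pytest.fixture(scope="module")
def sim_inputs(small_population, default_params):
    return small_population, default_params


class TestRunSimulation:
    def test_identity_scenario_is_bitwise_baseline(self, sim_inputs):
        agents, params = sim_inputs
        cap = CapacityModel.unlimited()
        a = run_simulation(agents, params, ScenarioModifiers.identity(52), cap, 52, seed=3)
        b = run_simulation(agents, params, ScenarioModifiers.identity(60), cap, 52, seed=3)
        pd.testing.assert_frame_equal(a.frame, b.frame)

    def test_empty_population_yields_zero_series(self, default_params):
        empty = pd.DataFrame(
            columns=["agent_id", "region", "sex", "age", "condition", "severity",
                     "state", "weight"]
        )
        s = run_simulation(
            empty, default_params, ScenarioModifiers.identity(10),
            CapacityModel.unlimited(), 10, seed=0,
        )
        assert len(s) == 10
        assert (s.frame[list(CHANNELS)].to_numpy() == 0).all()

    def test_supply_blackout_week_zeroes_service_and_fills_backlog(self, sim_inputs):
        agents, params = sim_inputs
        supply = np.ones(30)
        supply[10] = 0.0
        mods = ScenarioModifiers.from_profiles(np.ones(30), supply)
        cap = CapacityModel.for_population(agents, params, headroom=1.5)
        s = run_simulation(agents, params, mods, cap, 30, seed=5)
        assert s.frame["procedures"].iloc[10] == 0.0
        assert s.frame["outpatient_visits"].iloc[10] == 0.0
        assert s.backlog["procedures_backlog"].iloc[10] > 0

    def test_backlog_conservation_identity_every_week(self, sim_inputs):
        agents, params = sim_inputs
        supply = np.clip(np.ones(60) - 0.8 * (np.arange(60) % 13 == 0), 0, 1)
        mods = ScenarioModifiers.from_profiles(np.ones(60) * 0.9, supply)
        cap = CapacityModel.for_population(
            agents, params, headroom=1.1, abandonment_rate=0.07
        )
        s = run_simulation(agents, params, mods, cap, 60, seed=8)
        for svc in SUPPLY_SERVICES:
            lhs = s.backlog[f"{svc}_cum_demanded"]
            rhs = (
                s.backlog[f"{svc}_cum_served"]
                + s.backlog[f"{svc}_backlog"]
                + s.backlog[f"{svc}_cum_abandoned"]
            )
            assert np.allclose(lhs, rhs, atol=1e-9)

    def test_total_diagnosed_is_monotone(self, sim_inputs):
        agents, params = sim_inputs
        s = run_simulation(
            agents, params, ScenarioModifiers.identity(80),
            CapacityModel.unlimited(), 80, seed=2,
        )
        assert (np.diff(s.frame["total_patients"]) >= 0).all()

    def test_short_modifier_series_rejected(self, sim_inputs):
        agents, params = sim_inputs
        with pytest.raises(ConfigError):
            run_simulation(
                agents, params, ScenarioModifiers.identity(10),
                CapacityModel.unlimited(), 20, seed=0,
            )

    def test_rapid_backlog_release_amplifies_oscillation(self):
        """An 8-week supply blackout followed by fast backlog alleviation
        swings post-recovery service volumes harder than gradual release."""
        from ibdsim.population import MarginalTargetSet, generate_population

        targets = MarginalTargetSet(
            region_name="osc",
            total_patients=5000.0,
            sex_proportions={"male": 0.5, "female": 0.5},
            condition_proportions={"UC": 0.5, "CD": 0.5},
            age_targets={(c, s): (50.0, 12.0) for c in ("UC", "CD")
                         for s in ("male", "female")},
            initial_diagnosed_fraction=1.0,
            initial_biologic_fraction=0.15,
        )
        agents = generate_population(targets, 5000, seed=5)
        params = PathwayParameters(symptom_onset_hazard=0.0)
        H = 60
        supply = np.ones(H)
        supply[10:18] = 0.0
        mods = ScenarioModifiers.from_profiles(np.ones(H), supply)
        amplitude = {}
        for rate in (0.1, 0.9):
            cap = CapacityModel.for_population(
                agents, params, headroom=1.3,
                backlog_service_rate=rate, abandonment_rate=0.02,
            )
            s = run_simulation(agents, params, mods, cap, H, seed=9)
            post = s.frame["procedures"].iloc[18:44]
            amplitude[rate] = post.max() - post.min()
        assert amplitude[0.9] > amplitude[0.1]


class TestScalarVectorAgreement:
    def test_engine_matches_scalar_kernel_exactly(self, small_targets):
        """Under unlimited capacity and shared draws, stepping every agent
        through the scalar kernel reproduces the engine series bitwise."""
        from ibdsim.population import generate_population

        agents = generate_population(small_targets, 300, seed=3)
        params = PathwayParameters()
        horizon = 40
        series = run_simulation(
            agents, params, ScenarioModifiers.identity(horizon),
            CapacityModel.unlimited(), horizon, seed=7,
        )
        rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([7, 0x51D])))
        st = engine.initialize_state(agents, params, rng)
        n = len(agents)
        w = agents["weight"].to_numpy()
        states = [engine.state_of(st, i) for i in range(n)]
        und0 = sum(w[i] for i in range(n) if states[i].stage == "undiagnosed_asymptomatic")
        full = {"care_seeking": 1.0, "continuous_care_visits": 1.0, "biologic_refill": 1.0}
        rows = []
        for week in range(horizon):
            u = rng.random((N_DRAWS, n), dtype=np.float32)
            undw = sum(w[i] for i in range(n) if states[i].stage == "undiagnosed_asymptomatic")
            hazard = advance_incidence(params, week)
            if undw > 0:
                hazard = min(hazard * und0 / undw, 1.0)
            tally = dict.fromkeys(
                ["new_patients", "outpatient_visits", "procedures", "biologics",
                 "new_vedolizumab_starts"], 0.0,
            )
            for i in range(n):
                states[i], ev = step_agent(
                    states[i], params, full, week, AgentDraws(u[:, i]), onset_hazard=hazard
                )
                for key in tally:
                    tally[key] += ev[key] * w[i]
            total = sum(w[i] for i in range(n) if states[i].stage == "diagnosed_continuous_care")
            rows.append(
                [tally["new_patients"], total, tally["outpatient_visits"],
                 tally["procedures"], tally["biologics"], tally["biologics"],
                 tally["new_vedolizumab_starts"]]
            )
        # identical events and states; only float summation order differs
        assert np.allclose(
            np.asarray(rows), series.frame[list(CHANNELS)].to_numpy(),
            rtol=1e-10, atol=1e-8,
        )


class TestEnsembles:
    def test_single_run_collapses_summary(self, sim_inputs):
        agents, params = sim_inputs
        spec = RunSpec(agents, params, ScenarioModifiers.identity(20),
                       CapacityModel.unlimited(), 20)
        summary = run_ensemble(spec, 1, base_seed=4)
        f = summary.frame
        assert summary.n_runs == 1
        assert (f["min"] == f["max"]).all()

    def test_summary_order_statistics_are_sorted(self, sim_inputs):
        agents, params = sim_inputs
        spec = RunSpec(agents, params, ScenarioModifiers.identity(20),
                       CapacityModel.unlimited(), 20)
        summary = run_ensemble(spec, 8, base_seed=4)
        f = summary.frame
        assert (f["min"] <= f["q1"]).all()
        assert (f["q1"] <= f["median"]).all()
        assert (f["median"] <= f["q3"]).all()
        assert (f["q3"] <= f["max"]).all()

    def test_same_base_seed_reproduces_summary(self, sim_inputs):
        agents, params = sim_inputs
        spec = RunSpec(agents, params, ScenarioModifiers.identity(15),
                       CapacityModel.unlimited(), 15)
        a = run_ensemble(spec, 3, base_seed=10)
        b = run_ensemble(spec, 3, base_seed=10)
        pd.testing.assert_frame_equal(a.frame, b.frame)


class TestMonthlyAggregation:
    def test_constant_series_aggregates_to_constant(self, series_factory):
        s = series_factory({"outpatient_visits": [5.0] * 26})
        monthly = aggregate_monthly(s)
        assert np.allclose(monthly["outpatient_visits"], 5.0)

    def test_four_weeks_in_one_month_average(self, series_factory):
        # 2024-01-01 is a Monday; weeks 1, 8, 15, 22 Jan share the month
        s = series_factory({"procedures": [1.0, 2.0, 3.0, 4.0]}, start="2024-01-01")
        monthly = aggregate_monthly(s)
        assert len(monthly) == 1
        assert monthly["procedures"].iloc[0] == pytest.approx(2.5)

    def test_weeks_assigned_to_month_of_their_start(self, series_factory):
        # weeks starting Jan 29 and Feb 5: split across two months
        s = series_factory({"procedures": [10.0, 20.0]}, start="2024-01-29")
        monthly = aggregate_monthly(s)
        assert len(monthly) == 2
        assert monthly["procedures"].tolist() == [10.0, 20.0]
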