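"""Population construction: allocation, age moment matching, LP localization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad
from scipy.stats import norm

from ibdsim.errors import ConfigError, InfeasibleMomentsError, LocalizationError
from ibdsim.population import (
    MarginalTargetSet,
    allocate_cell_counts,
    fit_age_sampler,
    fit_truncated_normal_moments,
    generate_population,
    largest_remainder,
    localize_weights,
    max_attainable_sd,
    population_summary,
)


def truncnorm_moments_by_quadrature(mu, sigma, lo, hi):
    """Independent oracle: numerically integrate the truncated density."""
    z = quad(lambda x: norm.pdf(x, mu, sigma), lo, hi, epsabs=1e-13, limit=200)[0]
    m = quad(lambda x: x * norm.pdf(x, mu, sigma), lo, hi, epsabs=1e-13, limit=200)[0] / z
    v = quad(lambda x: (x - m) ** 2 * norm.pdf(x, mu, sigma), lo, hi, epsabs=1e-12, limit=200)[0] / z
    return m, np.sqrt(v)


class TestLargestRemainder:
    def test_tokyo_male_count_at_1000(self, tokyo_targets):
        counts = allocate_cell_counts(tokyo_targets, 1000)
        male = counts[("male", "UC")] + counts[("male", "CD")]
        assert male == 561

    def test_half_half_total_3_ties_break_to_first_cell(self):
        assert largest_remainder([0.5, 0.5], 3).tolist() == [2, 1]

    def test_zero_total_gives_empty_cells(self, tokyo_targets):
        assert all(v == 0 for v in allocate_cell_counts(tokyo_targets, 0).values())

    def test_negative_total_rejected(self, tokyo_targets):
        with pytest.raises(ConfigError):
            allocate_cell_counts(tokyo_targets, -1)

    @given(
        weights=st.lists(st.floats(0.01, 10.0), min_size=1, max_size=8),
        total=st.integers(0, 10_000),
    )
    @settings(derandomize=True, max_examples=200, deadline=None)
    def test_total_conserved_for_any_proportions(self, weights, total):
        props = np.asarray(weights) / np.sum(weights)
        counts = largest_remainder(props, total)
        assert counts.sum() == total
        assert (counts >= 0).all()


class TestTruncatedNormalMoments:
    @pytest.mark.parametrize(
        "mean,sd",
        [(46.0, 10.0), (53.8, 14.2), (61.4, 8.3), (52.3, 15.2), (30.0, 5.0)],
    )
    def test_fit_reproduces_targets_by_quadrature(self, mean, sd):
        mu, sigma = fit_truncated_normal_moments(mean, sd, 18.0, 74.0)
        m, s = truncnorm_moments_by_quadrature(mu, sigma, 18.0, 74.0)
        assert abs(m - mean) < 1e-6
        assert abs(s - sd) < 1e-6

    def test_symmetric_negligible_truncation(self):
        mu, sigma = fit_truncated_normal_moments(46.0, 3.0, 18.0, 74.0)
        assert abs(mu - 46.0) < 1e-9
        assert abs(sigma - 3.0) < 1e-6

    def test_overdispersed_pair_is_infeasible_and_names_bound(self):
        # no truncated normal on [18, 74] reaches SD 19 at mean 58.6; the
        # family's dispersion is capped near the tilted-uniform limit
        with pytest.raises(InfeasibleMomentsError, match="maximum SD"):
            fit_truncated_normal_moments(58.6, 19.0, 18.0, 74.0)

    def test_mean_outside_interval_rejected(self):
        with pytest.raises(InfeasibleMomentsError):
            fit_truncated_normal_moments(80.0, 5.0, 18.0, 74.0)

    def test_clipping_sampler_keeps_mean_exact(self):
        dist, _, achieved_sd = fit_age_sampler(58.6, 19.0, 18.0, 74.0)
        assert abs(dist.mean() - 58.6) < 1e-6
        assert achieved_sd < 19.0
        assert abs(achieved_sd - max_attainable_sd(58.6, 18.0, 74.0)) < 1e-9

    @given(
        mean=st.floats(32.0, 60.0),
        sd=st.floats(2.0, 10.0),
    )
    @settings(derandomize=True, max_examples=25, deadline=None)
    def test_feasible_targets_always_recovered(self, mean, sd):
        mu, sigma = fit_truncated_normal_moments(mean, sd, 18.0, 74.0)
        m, s = truncnorm_moments_by_quadrature(mu, sigma, 18.0, 74.0)
        assert abs(m - mean) < 1e-6 and abs(s - sd) < 1e-6


class TestGeneratePopulation:
    def test_weighted_totals_and_shares_exact(self, tokyo_targets):
        pop = generate_population(tokyo_targets, 20_000, seed=0)
        s = population_summary(pop)
        assert s["total_weight"] == pytest.approx(4_873_585, abs=1e-3)
        assert s["sex_shares"]["male"] == pytest.approx(0.561, abs=1e-12)
        assert s["condition_shares"]["UC"] == pytest.approx(0.565, abs=1e-12)

    def test_same_seed_reproduces_identical_table(self, small_targets):
        a = generate_population(small_targets, 500, seed=7)
        b = generate_population(small_targets, 500, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_different_seed_changes_ages(self, small_targets):
        a = generate_population(small_targets, 500, seed=7)
        b = generate_population(small_targets, 500, seed=8)
        assert not np.allclose(a["age"], b["age"])

    def test_ages_within_bounds(self, small_population, small_targets):
        lo, hi = small_targets.age_bounds
        assert small_population["age"].between(lo, hi).all()

    def test_severity_and_state_counts_follow_proportions(self, small_population):
        n = len(small_population)
        severe = (small_population["severity"] == "moderate_severe").mean()
        diagnosed = small_population["state"].str.startswith("diagnosed").mean()
        assert severe == pytest.approx(0.3, abs=2.0 / n * 4)
        assert diagnosed == pytest.approx(0.6, abs=2.0 / n * 4)

    def test_severity_independent_of_initial_state(self, small_population):
        # both attributes have exact counts; their joint must not be blockwise
        diag = small_population["state"].str.startswith("diagnosed")
        severe_given_diag = (small_population.loc[diag, "severity"] == "moderate_severe").mean()
        assert severe_given_diag == pytest.approx(0.3, abs=0.08)

    def test_integer_weights_demand_enough_patients(self, small_targets):
        with pytest.raises(ConfigError):
            generate_population(small_targets, 5000, seed=0, integer_weights=True)

    def test_invalid_n_agents(self, small_targets):
        with pytest.raises(ConfigError):
            generate_population(small_targets, 0, seed=0)


class TestPopulationSummary:
    def test_shares_sum_to_one(self, small_population):
        s = population_summary(small_population)
        assert sum(s["sex_shares"].values()) == pytest.approx(1.0, abs=1e-9)
        assert sum(s["condition_shares"].values()) == pytest.approx(1.0, abs=1e-9)

    def test_single_agent_sd_reported_absent(self, small_population):
        s = population_summary(small_population.iloc[:1])
        (cell,) = s["age_by_cell"].values()
        assert cell["age_sd"] is None
        assert set(s["sex_shares"].values()) <= {0.0, 1.0}

    def test_empty_table_rejected(self, small_population):
        with pytest.raises(ConfigError):
            population_summary(small_population.iloc[:0])


def _toy_agents(rows):
    return pd.DataFrame(
        [
            {
                "agent_id": f"a{i}",
                "region": "toy",
                "sex": sex,
                "age": 50.0,
                "condition": cond,
                "severity": "mild_moderate",
                "state": "diagnosed_conventional",
                "weight": 1.0,
            }
            for i, (sex, cond) in enumerate(rows)
        ]
    )


class TestLocalizeWeights:
    def test_two_agent_sex_targets_solved_exactly(self, tokyo_targets):
        seed = _toy_agents([("male", "UC"), ("female", "UC")])
        targets = MarginalTargetSet(
            region_name="toy",
            total_patients=1000.0,
            sex_proportions={"male": 0.561, "female": 0.439},
            condition_proportions={"UC": 1.0, "CD": 0.0},
            age_targets=tokyo_targets.age_targets,
        )
        result = localize_weights(seed, targets, dimensions=("sex",))
        assert np.allclose(sorted(result.weights, reverse=True), [561.0, 439.0], atol=1e-6)
        assert result.objective_value < 1e-6

    def test_perfect_seed_reaches_zero_objective(self, small_targets):
        seed = _toy_agents(
            [(s, c) for s in ("male", "female") for c in ("UC", "CD") for _ in range(3)]
        )
        targets = MarginalTargetSet(
            region_name="toy",
            total_patients=100.0,
            sex_proportions={"male": 0.5, "female": 0.5},
            condition_proportions={"UC": 0.5, "CD": 0.5},
            age_targets=small_targets.age_targets,
        )
        result = localize_weights(seed, targets)
        assert result.objective_value == pytest.approx(0.0, abs=1e-6)
        assert result.weights.sum() == pytest.approx(100.0, rel=1e-9)

    def test_matches_brute_force_on_four_agent_instance(self, small_targets):
        # female patients exist only with CD: the sex and condition targets
        # cannot both be met, so the optimum is a genuine trade-off
        seed = _toy_agents([("male", "UC"), ("male", "UC"), ("male", "CD"), ("female", "CD")])
        targets = MarginalTargetSet(
            region_name="toy",
            total_patients=10.0,
            sex_proportions={"male": 0.5, "female": 0.5},
            condition_proportions={"UC": 0.6, "CD": 0.4},
            age_targets=small_targets.age_targets,
        )
        result = localize_weights(seed, targets)

        # exhaustive simplex grid at step 0.1 patients (0.01 of the total)
        step = 0.1
        n_units = int(round(10.0 / step))
        best = np.inf
        A = np.array(
            [
                [1, 1, 1, 0],  # male
                [0, 0, 0, 1],  # female
                [1, 1, 0, 0],  # UC
                [0, 0, 1, 1],  # CD
            ],
            dtype=float,
        )
        t = np.array([5.0, 5.0, 6.0, 4.0])
        for i in range(n_units + 1):
            for j in range(n_units + 1 - i):
                for k in range(n_units + 1 - i - j):
                    w = np.array([i, j, k, n_units - i - j - k]) * step
                    best = min(best, np.abs(A @ w - t).sum())
        assert result.objective_value <= best + 1e-9
        # the LP optimum can undercut the grid only by the grid resolution
        assert best - result.objective_value <= 4 * step

    def test_unsupported_target_category_is_named(self, small_targets):
        seed = _toy_agents([("male", "UC"), ("male", "CD")])
        targets = MarginalTargetSet(
            region_name="toy",
            total_patients=10.0,
            sex_proportions={"male": 0.5, "female": 0.5},
            condition_proportions={"UC": 0.5, "CD": 0.5},
            age_targets=small_targets.age_targets,
        )
        with pytest.raises(LocalizationError, match="female"):
            localize_weights(seed, targets)

    def test_objective_not_worse_than_uniform_scaling(self, small_targets):
        rng = np.random.default_rng(3)
        rows = [
            (rng.choice(["male", "female"], p=[0.8, 0.2]), rng.choice(["UC", "CD"]))
            for _ in range(30)
        ]
        seed = _toy_agents(rows)
        result = localize_weights(seed, small_targets)
        uniform = np.full(30, small_targets.total_patients / 30)
        dev = 0.0
        for dim, props in [
            ("sex", small_targets.sex_proportions),
            ("condition", small_targets.condition_proportions),
        ]:
            for level, p in props.items():
                ind = (seed[dim] == level).to_numpy(float)
                dev += abs(ind @ uniform - p * small_targets.total_patients)
        assert result.objective_value <= dev + 1e-9


class TestMarginalTargetValidation:
    def test_bad_proportions_listed_by_key(self, small_targets):
        with pytest.raises(ConfigError, match="sex_proportions"):
            MarginalTargetSet(
                region_name="bad",
                total_patients=10.0,
                sex_proportions={"male": 0.7, "female": 0.7},
                condition_proportions={"UC": 0.5, "CD": 0.5},
                age_targets=small_targets.age_targets,
            )

    def test_nonpositive_total_rejected(self, small_targets):
        with pytest.raises(ConfigError, match="total_patients"):
            MarginalTargetSet(
                region_name="bad",
                total_patients=0.0,
                sex_proportions={"male": 0.5, "female": 0.5},
                condition_proportions={"UC": 0.5, "CD": 0.5},
                age_targets=small_targets.age_targets,
            )

    def test_age_mean_outside_bounds_rejected(self, small_targets):
        bad = dict(small_targets.age_targets)
        bad[("UC", "male")] = (80.0, 5.0)
        with pytest.raises(ConfigError, match="age_targets"):
            MarginalTargetSet(
                region_name="bad",
                total_patients=10.0,
                sex_proportions={"male": 0.5, "female": 0.5},
                condition_proportions={"UC": 0.5, "CD": 0.5},
                age_targets=bad,
            )
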