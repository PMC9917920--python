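"""Synthetic IBD population construction and localization.

Agents are weighted representatives: a region with millions of patients is
represented by (default) 100,000 agents whose weights sum exactly to the
regional total, so full-scale aggregates are testable at desk scale.

Three mechanisms are provided:

* deterministic largest-remainder allocation of agents to (sex x condition)
  cells from marginal proportions;
* moment-matched truncated-normal age sampling, so weighted age means and
  SDs per cell reproduce published values on a bounded age interval;
* linear-programming reweighting (``localize_weights``) of an arbitrary seed
  population so its weighted marginals move as close as possible (L1) to the
  regional targets -- the "localization" of a foreign seed population.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq, linprog
from scipy.stats import truncnorm

from ibdsim.errors import ConfigError, InfeasibleMomentsError, LocalizationError

SEXES = ("male", "female")
CONDITIONS = ("UC", "CD")
SEVERITIES = ("mild_moderate", "moderate_severe")

#: canonical (sex, condition) cell order; ties in the largest-remainder
#: allocation are broken in this order (male < female, UC < CD)
CELLS = tuple(itertools.product(SEXES, CONDITIONS))

#: initial pathway-state labels used in agent tables
STATES = (
    "undiagnosed_asymptomatic",
    "symptomatic_seeking_care",
    "diagnosed_conventional",
    "diagnosed_biologic",
)

AGENT_COLUMNS = [
    "agent_id",
    "region",
    "sex",
    "age",
    "condition",
    "severity",
    "state",
    "weight",
]

# Dispersion cap for the nested moment solver.  At sigma = 300 the truncated
# normal on a ~56-year window is within ~1e-3 years of its supremum SD, and
# scipy's truncated-normal routines remain well conditioned.
_SIGMA_CAP = 300.0
_SIGMA_FLOOR = 1e-3


@dataclass(frozen=True)
class MarginalTargetSet:
    """Marginal targets defining one regional synthetic population.

    ``age_targets`` maps (condition, sex) to (mean, sd) in years.  The extra
    initial-state fields control how agents are seeded into the clinical
    pathway; they are simulator initial conditions, not published marginals.
    """

    region_name: str
    total_patients: float
    sex_proportions: Mapping[str, float]
    condition_proportions: Mapping[str, float]
    age_targets: Mapping[tuple[str, str], tuple[float, float]]
    age_bounds: tuple[float, float] = (18.0, 74.0)
    severity_proportions: Mapping[str, float] = field(
        default_factory=lambda: {"mild_moderate": 0.7, "moderate_severe": 0.3}
    )
    initial_diagnosed_fraction: float = 0.7
    initial_biologic_fraction: float = 0.15
    care_seeking_propensity: float = 1.0

    def __post_init__(self) -> None:
        problems: list[str] = []
        if not self.total_patients > 0:
            problems.append(f"total_patients: must be > 0, got {self.total_patients}")
        lo, hi = self.age_bounds
        if not lo < hi:
            problems.append(f"age_bounds: need lo < hi, got {self.age_bounds}")
        for name, props, keys in [
            ("sex_proportions", self.sex_proportions, SEXES),
            ("condition_proportions", self.condition_proportions, CONDITIONS),
            ("severity_proportions", self.severity_proportions, SEVERITIES),
        ]:
            if set(props) != set(keys):
                problems.append(f"{name}: keys must be {set(keys)}, got {set(props)}")
                continue
            vals = [props[k] for k in keys]
            if any(not 0.0 <= v <= 1.0 for v in vals):
                problems.append(f"{name}: values must lie in [0, 1], got {vals}")
            elif abs(sum(vals) - 1.0) > 1e-9:
                problems.append(f"{name}: must sum to 1, got {sum(vals)!r}")
        for cell in itertools.product(CONDITIONS, SEXES):
            if cell not in self.age_targets:
                problems.append(f"age_targets: missing cell {cell}")
                continue
            mean, sd = self.age_targets[cell]
            if not lo < mean < hi:
                problems.append(
                    f"age_targets{cell}: mean {mean} outside age_bounds {self.age_bounds}"
                )
            # distribution-free bound: no distribution on [lo, hi] with this
            # mean can have SD above sqrt((mean-lo)(hi-mean))
            cap = math.sqrt(max(mean - lo, 0.0) * max(hi - mean, 0.0))
            if not 0.0 < sd <= cap:
                problems.append(
                    f"age_targets{cell}: sd {sd} outside (0, {cap:.3f}] attainable on bounds"
                )
        for name, frac in [
            ("initial_diagnosed_fraction", self.initial_diagnosed_fraction),
            ("initial_biologic_fraction", self.initial_biologic_fraction),
        ]:
            if not 0.0 <= frac <= 1.0:
                problems.append(f"{name}: must lie in [0, 1], got {frac}")
        if problems:
            raise ConfigError(
                f"invalid marginal targets for region {self.region_name!r}: "
                + "; ".join(problems)
            )

    def joint_proportion(self, sex: str, condition: str) -> float:
        """Joint cell share under independence of the two printed marginals."""
        return self.sex_proportions[sex] * self.condition_proportions[condition]


@dataclass(frozen=True)
class AgentRecord:
    """One synthetic patient (scalar view of an agent-table row)."""

    agent_id: str
    region: str
    sex: str
    age: float
    condition: str
    severity: str
    state: str
    weight: float


@dataclass(frozen=True)
class WeightVector:
    """Result of LP localization: per-agent weights and achieved L1 deviation."""

    weights: np.ndarray
    objective_value: float


def largest_remainder(proportions: Sequence[float], total: int) -> np.ndarray:
    """Apportion ``total`` integer units to ``proportions`` by largest remainder.

    Conserves the total exactly; remainder ties go to the earliest index.
    """
    if total < 0:
        raise ConfigError(f"total: must be >= 0, got {total}")
    props = np.asarray(proportions, dtype=float)
    if props.size == 0:
        raise ConfigError("proportions: must be nonempty")
    if np.any(props < -1e-12) or abs(props.sum() - 1.0) > 1e-9:
        raise ConfigError(f"proportions: must be nonnegative and sum to 1, got {props}")
    exact = props * total
    base = np.floor(exact).astype(np.int64)
    shortfall = int(round(total - base.sum()))
    remainders = exact - base
    # stable sort descending by remainder -> earliest index wins ties
    order = np.argsort(-remainders, kind="stable")
    base[order[:shortfall]] += 1
    return base


def allocate_cell_counts(targets: MarginalTargetSet, total: int) -> dict[tuple[str, str], int]:
    """Integer agent counts per (sex, condition) cell summing exactly to ``total``."""
    props = [targets.joint_proportion(s, c) for s, c in CELLS]
    counts = largest_remainder(props, total)
    return {cell: int(n) for cell, n in zip(CELLS, counts)}


# ---------------------------------------------------------------------------
# truncated-normal moment matching


def _tn_moments(mu: float, sigma: float, lo: float, hi: float) -> tuple[float, float]:
    a, b = (lo - mu) / sigma, (hi - mu) / sigma
    m, v = truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
    return float(m), float(np.sqrt(v))


def _mu_for_mean(sigma: float, target_mean: float, lo: float, hi: float) -> float:
    """Location parameter whose truncated mean equals ``target_mean``.

    The truncated mean is strictly increasing in mu; for large sigma the
    required |mu| scales like sigma^2 (the density becomes an exponential
    tilt), so the bracket is expanded geometrically.
    """

    def gap(mu: float) -> float:
        return _tn_moments(mu, sigma, lo, hi)[0] - target_mean

    span = max(sigma, 1.0)
    lo_b, hi_b = target_mean - span, target_mean + span
    for _ in range(80):
        if gap(lo_b) <= 0.0:
            break
        lo_b -= span
        span *= 1.6
    span = max(sigma, 1.0)
    for _ in range(80):
        if gap(hi_b) >= 0.0:
            break
        hi_b += span
        span *= 1.6
    return float(brentq(gap, lo_b, hi_b, xtol=1e-11, rtol=8.9e-16, maxiter=200))


def _sd_at(sigma: float, target_mean: float, lo: float, hi: float) -> float:
    mu = _mu_for_mean(sigma, target_mean, lo, hi)
    return _tn_moments(mu, sigma, lo, hi)[1]


def max_attainable_sd(target_mean: float, lo: float, hi: float) -> float:
    """Largest SD a truncated normal with the given truncated mean can reach
    on [lo, hi] (evaluated at the solver's dispersion cap; the true supremum,
    approached as sigma -> infinity, is at most ~1e-3 years larger)."""
    return _sd_at(_SIGMA_CAP, target_mean, lo, hi)


def fit_truncated_normal_moments(
    target_mean: float, target_sd: float, lo: float, hi: float
) -> tuple[float, float]:
    """Solve for (mu, sigma) whose truncation to [lo, hi] has the target moments.

    Nested one-dimensional root finding: for each trial sigma, mu is solved so
    the truncated mean is exact; the truncated SD is then strictly increasing
    in sigma and is bracketed by Brent's method.  Raises
    :class:`InfeasibleMomentsError` when the target SD exceeds the attainable
    bound at this mean (the truncated-normal family cannot be more dispersed
    than an exponentially tilted uniform on the interval).
    """
    if not lo < target_mean < hi:
        raise InfeasibleMomentsError(
            f"target mean {target_mean} outside the open interval ({lo}, {hi})"
        )
    if target_sd <= 0:
        raise InfeasibleMomentsError(f"target SD must be > 0, got {target_sd}")
    sd_cap = max_attainable_sd(target_mean, lo, hi)
    if target_sd >= sd_cap:
        raise InfeasibleMomentsError(
            f"target SD {target_sd} exceeds the maximum SD {sd_cap:.4f} attainable "
            f"by a truncated normal with mean {target_mean} on [{lo}, {hi}]"
        )
    sd_floor = _sd_at(_SIGMA_FLOOR, target_mean, lo, hi)
    if target_sd <= sd_floor:
        raise InfeasibleMomentsError(
            f"target SD {target_sd} below solver floor {sd_floor:.2e}"
        )
    sigma = float(
        brentq(
            lambda s: _sd_at(s, target_mean, lo, hi) - target_sd,
            _SIGMA_FLOOR,
            _SIGMA_CAP,
            xtol=1e-10,
            rtol=8.9e-16,
            maxiter=200,
        )
    )
    mu = _mu_for_mean(sigma, target_mean, lo, hi)
    return mu, sigma


def fit_age_sampler(target_mean: float, target_sd: float, lo: float, hi: float):
    """Frozen truncated-normal age distribution for one population cell.

    Published (mean, SD) pairs are sometimes jointly infeasible on the bounded
    age interval (the SD exceeds what any truncated normal supports at that
    mean).  In that case the mean is matched exactly and the SD is clipped to
    the attainable maximum; the achieved SD is returned alongside.

    Returns (frozen distribution, (mu, sigma), achieved_sd).
    """
    try:
        mu, sigma = fit_truncated_normal_moments(target_mean, target_sd, lo, hi)
    except InfeasibleMomentsError:
        sigma = _SIGMA_CAP
        mu = _mu_for_mean(sigma, target_mean, lo, hi)
    a, b = (lo - mu) / sigma, (hi - mu) / sigma
    dist = truncnorm(a, b, loc=mu, scale=sigma)
    achieved_sd = _tn_moments(mu, sigma, lo, hi)[1]
    return dist, (mu, sigma), achieved_sd


# ---------------------------------------------------------------------------
# population generation


def generate_population(
    targets: MarginalTargetSet,
    n_agents: int,
    seed: int,
    *,
    integer_weights: bool = False,
) -> pd.DataFrame:
    """Generate a weighted agent table reproducing the marginal targets.

    Deterministic in (targets, n_agents, seed).  Each (sex, condition) cell
    receives a largest-remainder share of the ``n_agents`` representatives;
    per-cell summed weight equals ``total_patients`` times the joint cell
    proportion exactly, so totals and categorical shares are reproduced with
    no sampling error.  Ages are drawn by inverse-CDF from the moment-matched
    truncated normal of the cell.  Severity and initial pathway state receive
    exact largest-remainder counts within each cell, independently permuted
    so the two attributes are jointly product-distributed.
    """
    if n_agents < 1:
        raise ConfigError(f"n_agents: must be >= 1, got {n_agents}")
    if integer_weights and n_agents > targets.total_patients:
        raise ConfigError(
            f"n_agents ({n_agents}) exceeds total_patients "
            f"({targets.total_patients}) with integer weights requested"
        )
    lo, hi = targets.age_bounds
    counts = allocate_cell_counts(targets, n_agents)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x1BD]))

    frames: list[pd.DataFrame] = []
    next_id = 0
    for sex, condition in CELLS:
        k = counts[(sex, condition)]
        if k == 0:
            continue
        mean, sd = targets.age_targets[(condition, sex)]
        dist, _, _ = fit_age_sampler(mean, sd, lo, hi)
        ages = dist.ppf(rng.random(k))
        cell_mass = targets.total_patients * targets.joint_proportion(sex, condition)
        weight = cell_mass / k
        n_severe = int(
            largest_remainder(
                [targets.severity_proportions[s] for s in SEVERITIES], k
            )[1]
        )
        severity = rng.permutation(
            np.array([SEVERITIES[0]] * (k - n_severe) + [SEVERITIES[1]] * n_severe)
        )
        n_diag = int(
            largest_remainder(
                [1.0 - targets.initial_diagnosed_fraction, targets.initial_diagnosed_fraction],
                k,
            )[1]
        )
        n_bio = int(
            largest_remainder(
                [1.0 - targets.initial_biologic_fraction, targets.initial_biologic_fraction],
                n_diag,
            )[1]
        ) if n_diag else 0
        # independent permutations keep severity and initial state jointly
        # product-distributed within the cell (exact marginal counts)
        state = rng.permutation(
            np.array(
                ["undiagnosed_asymptomatic"] * (k - n_diag)
                + ["diagnosed_conventional"] * (n_diag - n_bio)
                + ["diagnosed_biologic"] * n_bio
            )
        )
        frames.append(
            pd.DataFrame(
                {
                    "agent_id": [
                        f"{targets.region_name}-{i:07d}" for i in range(next_id, next_id + k)
                    ],
                    "region": targets.region_name,
                    "sex": sex,
                    "age": ages,
                    "condition": condition,
                    "severity": severity,
                    "state": state,
                    "weight": weight,
                }
            )
        )
        next_id += k
    table = pd.concat(frames, ignore_index=True)
    if integer_weights:
        # integer weights per cell by largest remainder over equal shares
        for (sex, condition), k in counts.items():
            if k == 0:
                continue
            mask = (table["sex"] == sex) & (table["condition"] == condition)
            cell_mass = int(round(targets.total_patients * targets.joint_proportion(sex, condition)))
            table.loc[mask, "weight"] = largest_remainder([1.0 / k] * k, cell_mass).astype(float)
    return table[AGENT_COLUMNS]


def records(table: pd.DataFrame) -> Iterable[AgentRecord]:
    """Iterate an agent table as :class:`AgentRecord` objects."""
    for row in table.itertuples(index=False):
        yield AgentRecord(
            agent_id=row.agent_id,
            region=row.region,
            sex=row.sex,
            age=float(row.age),
            condition=row.condition,
            severity=row.severity,
            state=row.state,
            weight=float(row.weight),
        )


# ---------------------------------------------------------------------------
# LP localization of a seed population


def localize_weights(
    seed_population: pd.DataFrame,
    targets: MarginalTargetSet,
    dimensions: Sequence[str] = ("sex", "condition"),
) -> WeightVector:
    """Reweight a seed population to the marginal targets by linear programming.

    Minimizes the total absolute deviation between weighted seed category
    counts and target category counts, subject to nonnegative weights summing
    to ``total_patients``.  This is the localization step that adapts a
    foreign (e.g. US-derived) seed population to a regional target.
    """
    if len(seed_population) == 0:
        raise LocalizationError("seed population is empty")
    n = len(seed_population)
    total = float(targets.total_patients)

    categories: list[tuple[str, str, float]] = []  # (dimension, level, target count)
    prop_maps = {"sex": targets.sex_proportions, "condition": targets.condition_proportions}
    for dim in dimensions:
        if dim not in prop_maps:
            raise ConfigError(f"dimensions: unknown dimension {dim!r}")
        for level, prop in prop_maps[dim].items():
            support = (seed_population[dim] == level).any()
            if prop > 0 and not support:
                raise LocalizationError(
                    f"target category {dim}={level!r} has no support in the seed population"
                )
            categories.append((dim, level, prop * total))

    m = len(categories)
    # variables: [w_1..w_n, e_1..e_m]; minimize sum(e)
    cost = np.concatenate([np.zeros(n), np.ones(m)])
    # |A w - t| <= e  ->  A w - e <= t  and  -A w - e <= -t
    A = np.zeros((m, n))
    t = np.zeros(m)
    for j, (dim, level, target_count) in enumerate(categories):
        A[j] = (seed_population[dim] == level).to_numpy(dtype=float)
        t[j] = target_count
    a_ub = np.block(
        [[A, -np.eye(m)], [-A, -np.eye(m)]]
    )
    b_ub = np.concatenate([t, -t])
    a_eq = np.concatenate([np.ones(n), np.zeros(m)])[None, :]
    res = linprog(
        cost,
        A_ub=a_ub,
        b_ub=b_ub,
        A_eq=a_eq,
        b_eq=[total],
        bounds=(0, None),
        method="highs",
    )
    if not res.success:  # pragma: no cover - HiGHS is robust on these LPs
        raise LocalizationError(f"linear program failed: {res.message}")
    weights = np.asarray(res.x[:n])
    weights = np.clip(weights, 0.0, None)
    # renormalize away solver round-off on the total-weight equality
    weights *= total / weights.sum()
    objective = float(np.abs(A @ weights - t).sum())
    return WeightVector(weights=weights, objective_value=objective)


# ---------------------------------------------------------------------------
# summaries


def _weighted_sd(values: np.ndarray, weights: np.ndarray) -> float | None:
    if len(values) < 2:
        return None
    mean = np.average(values, weights=weights)
    var = np.average((values - mean) ** 2, weights=weights)
    return float(np.sqrt(var))


def population_summary(table: pd.DataFrame) -> dict:
    """Weighted marginal statistics of an agent table.

    Returns total weight, sex/condition shares (summing to 1 within 1e-9),
    and per-(condition, sex) weighted age mean and SD (SD ``None`` for
    single-agent cells).
    """
    if len(table) == 0:
        raise ConfigError("population_summary: empty agent table")
    w = table["weight"].to_numpy(dtype=float)
    total = float(w.sum())
    out: dict = {"total_weight": total, "n_agents": int(len(table))}
    for dim, levels in [("sex", SEXES), ("condition", CONDITIONS)]:
        out[f"{dim}_shares"] = {
            level: float(w[(table[dim] == level).to_numpy()].sum() / total)
            for level in levels
        }
    cells = {}
    for condition in CONDITIONS:
        for sex in SEXES:
            mask = ((table["condition"] == condition) & (table["sex"] == sex)).to_numpy()
            if not mask.any():
                continue
            ages = table["age"].to_numpy(dtype=float)[mask]
            ws = w[mask]
            cells[(condition, sex)] = {
                "weight": float(ws.sum()),
                "age_mean": float(np.average(ages, weights=ws)),
                "age_sd": _weighted_sd(ages, ws),
            }
    out["age_by_cell"] = cells
    return out
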