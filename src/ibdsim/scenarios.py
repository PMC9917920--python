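"""Time-varying demand/supply disruption scenarios.

A scenario is a pair of weekly multiplier tables: demand multipliers scale
patients' attendance propensities per behavioral channel, supply multipliers
scale service capacity per service.  1 means no disruption.  Three crisis
archetypes are provided:

* **pandemic** -- impact follows reported case counts through a saturating
  response, is boosted while a state of emergency is declared, and habituates
  across successive waves (equal later waves provoke strictly smaller
  behavioral reactions);
* **earthquake** -- an immediate step drop on both demand and supply with a
  linear recovery;
* **financial crisis** -- a prolonged demand-side-only depression (supply is
  untouched): ramp down, hold, ramp back.

Earthquake and financial-crisis default magnitudes are hypothetical — no
historical calibration data stand behind them; pandemic-response parameters
are meant to be fitted by the calibration module, not asserted.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ibdsim.errors import ConfigError
from ibdsim.pathway import DEMAND_CHANNELS, SUPPLY_SERVICES


@dataclass(frozen=True)
class ScenarioModifiers:
    """Weekly demand and supply multipliers over a simulation horizon.

    ``demand`` has columns :data:`~ibdsim.pathway.DEMAND_CHANNELS`;
    ``supply`` has columns :data:`~ibdsim.pathway.SUPPLY_SERVICES`;
    both are indexed by 0-based week.
    """

    demand: pd.DataFrame
    supply: pd.DataFrame

    def __post_init__(self) -> None:
        problems = []
        if list(self.demand.columns) != list(DEMAND_CHANNELS):
            problems.append(f"demand columns must be {DEMAND_CHANNELS}")
        if list(self.supply.columns) != list(SUPPLY_SERVICES):
            problems.append(f"supply columns must be {SUPPLY_SERVICES}")
        if len(self.demand) != len(self.supply):
            problems.append("demand and supply must cover the same horizon")
        if not problems and (
            (self.demand.to_numpy() < 0).any() or (self.supply.to_numpy() < 0).any()
        ):
            problems.append("multipliers must be >= 0")
        if problems:
            raise ConfigError("invalid scenario modifiers: " + "; ".join(problems))

    @property
    def horizon(self) -> int:
        return len(self.demand)

    @classmethod
    def identity(cls, horizon: int) -> "ScenarioModifiers":
        """No-disruption scenario: all multipliers 1 for ``horizon`` weeks."""
        if horizon < 1:
            raise ConfigError(f"horizon must be >= 1, got {horizon}")
        return cls(
            demand=pd.DataFrame(1.0, index=range(horizon), columns=list(DEMAND_CHANNELS)),
            supply=pd.DataFrame(1.0, index=range(horizon), columns=list(SUPPLY_SERVICES)),
        )

    @classmethod
    def from_profiles(cls, demand: np.ndarray, supply: np.ndarray) -> "ScenarioModifiers":
        """Build from per-week scalar profiles applied uniformly to all
        channels (services)."""
        return cls(
            demand=pd.DataFrame(
                np.tile(np.asarray(demand, dtype=float)[:, None], (1, len(DEMAND_CHANNELS))),
                columns=list(DEMAND_CHANNELS),
            ),
            supply=pd.DataFrame(
                np.tile(np.asarray(supply, dtype=float)[:, None], (1, len(SUPPLY_SERVICES))),
                columns=list(SUPPLY_SERVICES),
            ),
        )


@dataclass(frozen=True)
class PandemicResponseParams:
    """Behavioral/supply response to reported epidemic waves.

    ``case_saturation`` is the weekly case count at half-maximal impact;
    ``max_demand_impact`` / ``max_supply_impact`` are the saturating impact
    amplitudes; ``emergency_boost`` is added while a state of emergency is
    declared; ``adaptation_halflife`` (weeks of prior nonzero impact) halves
    the response — the habituation that makes later, even larger, waves less
    disruptive than the first.
    """

    case_saturation: float = 200.0
    max_demand_impact: float = 0.4
    max_supply_impact: float = 0.3
    emergency_boost: float = 0.15
    adaptation_halflife: float = 40.0

    def __post_init__(self) -> None:
        problems = []
        for name in ("max_demand_impact", "max_supply_impact", "emergency_boost"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                problems.append(f"{name}: must lie in [0,1], got {v}")
        if not self.case_saturation > 0:
            problems.append(f"case_saturation: must be > 0, got {self.case_saturation}")
        if not self.adaptation_halflife > 0:
            problems.append(
                f"adaptation_halflife: must be > 0, got {self.adaptation_halflife}"
            )
        if problems:
            raise ConfigError("invalid pandemic response parameters: " + "; ".join(problems))


def pandemic_impact_series(
    cases: np.ndarray,
    emergency: np.ndarray,
    params: PandemicResponseParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Weekly (demand_impact, supply_impact) arrays for a wave series.

    raw impact_t = A * c_t / (c_t + saturation) + boost * 1{emergency_t};
    habituation multiplies by 2^(-E_t / halflife) where E_t counts prior
    weeks with nonzero raw impact.
    """
    cases = np.asarray(cases, dtype=float)
    emergency = np.asarray(emergency, dtype=bool)
    if (cases < 0).any():
        raise ConfigError("new_cases must be >= 0")
    sat = cases / (cases + params.case_saturation)
    raw_d = params.max_demand_impact * sat + params.emergency_boost * emergency
    raw_s = params.max_supply_impact * sat + params.emergency_boost * emergency
    exposed = (raw_d > 0) | (raw_s > 0)
    prior_exposure = np.concatenate([[0], np.cumsum(exposed)[:-1]]).astype(float)
    adapt = 2.0 ** (-prior_exposure / params.adaptation_halflife)
    return raw_d * adapt, raw_s * adapt


def build_pandemic_scenario(
    waves: pd.DataFrame, params: PandemicResponseParams
) -> ScenarioModifiers:
    """Scenario modifiers driven by a weekly COVID wave series.

    ``waves`` needs columns ``new_cases`` and ``emergency_declared`` (and
    usually ``week_start``).  Multipliers are 1 - impact, clipped to [0, 1].
    """
    if len(waves) == 0:
        raise ConfigError("wave series is empty")
    for col in ("new_cases", "emergency_declared"):
        if col not in waves.columns:
            raise ConfigError(f"wave series missing column {col!r}")
    imp_d, imp_s = pandemic_impact_series(
        waves["new_cases"].to_numpy(),
        waves["emergency_declared"].to_numpy(dtype=bool),
        params,
    )
    return ScenarioModifiers.from_profiles(
        np.clip(1.0 - imp_d, 0.0, 1.0), np.clip(1.0 - imp_s, 0.0, 1.0)
    )


def build_earthquake_scenario(
    start_week: int, severity: float, recovery_weeks: int, horizon: int
) -> ScenarioModifiers:
    """Immediate step drop on demand and supply with linear recovery.

    Week ``start_week`` has multiplier 1 - severity; week ``start_week + k``
    has 1 - severity * (1 - k / recovery_weeks) until full recovery.  The
    summed disruption integral of this triangular profile is
    severity * (recovery_weeks + 1) / 2.
    """
    if not 0.0 <= severity <= 1.0:
        raise ConfigError(f"severity must lie in [0,1], got {severity}")
    if recovery_weeks < 1:
        raise ConfigError(f"recovery_weeks must be >= 1, got {recovery_weeks}")
    profile = np.ones(horizon)
    for k in range(recovery_weeks + 1):
        w = start_week + k
        if 0 <= w < horizon:
            profile[w] = 1.0 - severity * (1.0 - k / recovery_weeks)
    return ScenarioModifiers.from_profiles(profile, profile.copy())


def build_financial_crisis_scenario(
    start_week: int,
    depth: float,
    duration_weeks: int,
    recovery_weeks: int,
    horizon: int,
) -> ScenarioModifiers:
    """Prolonged demand-side-only depression; supply multipliers stay at 1.

    Demand drops to 1 - depth at ``start_week``, holds through
    ``duration_weeks``, then ramps back linearly over ``recovery_weeks``.
    """
    if not 0.0 <= depth <= 1.0:
        raise ConfigError(f"depth must lie in [0,1], got {depth}")
    if duration_weeks < 0 or recovery_weeks < 0:
        raise ConfigError("duration_weeks and recovery_weeks must be >= 0")
    demand = np.ones(horizon)
    for w in range(start_week, min(start_week + duration_weeks + 1, horizon)):
        if w >= 0:
            demand[w] = 1.0 - depth
    for j in range(1, recovery_weeks + 1):
        w = start_week + duration_weeks + j
        if 0 <= w < horizon:
            demand[w] = 1.0 - depth * (1.0 - j / recovery_weeks)
    return ScenarioModifiers.from_profiles(demand, np.ones(horizon))


def synthetic_covid_waves(
    n_weeks: int,
    peaks: Sequence[tuple[int, float, float]],
    emergency_windows: Sequence[tuple[int, int]] = (),
    start_date: str = "2020-11-02",
) -> pd.DataFrame:
    """Exogenous wave series from Gaussian-bump peaks (center, height, width).

    The simulator never forecasts epidemic prevalence; wave series are inputs
    describing hypothetical trajectories.  ``emergency_windows`` are
    half-open [start, end) week intervals with the emergency flag set.
    """
    weeks = np.arange(n_weeks)
    cases = np.zeros(n_weeks)
    for center, height, width in peaks:
        cases += height * np.exp(-0.5 * ((weeks - center) / width) ** 2)
    cases = np.where(cases < 1.0, 0.0, np.rint(cases))
    emergency = np.zeros(n_weeks, dtype=bool)
    for start, end in emergency_windows:
        emergency[max(start, 0) : max(end, 0)] = True
    return pd.DataFrame(
        {
            "week_start": pd.date_range(start_date, periods=n_weeks, freq="7D"),
            "new_cases": cases,
            "emergency_declared": emergency,
        }
    )


# ---------------------------------------------------------------------------
# crisis suite


def _build_scenario_from_config(cfg: Mapping, horizon: int) -> ScenarioModifiers:
    stype = cfg.get("type")
    if stype == "identity":
        return ScenarioModifiers.identity(horizon)
    if stype == "pandemic":
        wcfg = cfg.get("waves")
        if wcfg is None:
            raise ConfigError("pandemic scenario config needs a 'waves' entry")
        waves = synthetic_covid_waves(
            horizon,
            [tuple(p) for p in wcfg.get("peaks", [])],
            [tuple(w) for w in wcfg.get("emergency_windows", [])],
        )
        params = PandemicResponseParams(**cfg.get("response", {}))
        return build_pandemic_scenario(waves, params)
    if stype == "earthquake":
        p = cfg.get("params", {})
        return build_earthquake_scenario(
            p.get("start_week", 0), p.get("severity", 0.8), p.get("recovery_weeks", 12), horizon
        )
    if stype == "financial_crisis":
        p = cfg.get("params", {})
        return build_financial_crisis_scenario(
            p.get("start_week", 0),
            p.get("depth", 0.3),
            p.get("duration_weeks", 52),
            p.get("recovery_weeks", 26),
            horizon,
        )
    raise ConfigError(f"unknown scenario type {stype!r}")


def plan_crisis_suite(config: Mapping) -> dict:
    """Enumerate the scenario x region x replicate grid without running it."""
    for key in ("scenarios", "regions", "replicates"):
        if key not in config:
            raise ConfigError(f"suite config missing key {key!r}")
    scenarios = [c.get("name", c.get("type")) for c in config["scenarios"]]
    regions = [r.get("name", r.get("population_config")) for r in config["regions"]]
    replicates = int(config["replicates"])
    if replicates < 1:
        raise ConfigError(f"replicates: must be >= 1, got {replicates}")
    combos = [
        {"scenario": s, "region": r, "replicates": replicates}
        for s, r in itertools.product(scenarios, regions)
    ]
    return {
        "scenarios": scenarios,
        "regions": regions,
        "replicates": replicates,
        "combos": combos,
        "total_runs": len(scenarios) * len(regions) * replicates,
    }


def run_crisis_suite(config: Mapping, base_seed: int) -> tuple[dict, dict]:
    """Run the configured scenario x region x replicate grid.

    Returns (summaries, manifest): ``summaries`` maps (scenario, region) to an
    :class:`~ibdsim.engine.EnsembleSummary`; the manifest records the planned
    and executed run counts.  The full-scale study configuration and a
    desk-scale configuration execute this identical code path and differ only
    in replicate count, agent count and horizon.
    """
    from ibdsim import engine  # deferred import to avoid a module cycle
    from ibdsim import interventions as iv
    from ibdsim.io import load_population_config
    from ibdsim.population import generate_population

    manifest = plan_crisis_suite(config)
    horizon = int(config.get("horizon", 156))
    start_date = config.get("start_date", "2020-11-02")
    from ibdsim.pathway import PathwayParameters

    params = PathwayParameters(**config.get("pathway", {}))
    headroom = float(config.get("capacity_headroom", 1.5))

    summaries: dict[tuple[str, str], engine.EnsembleSummary] = {}
    executed = 0
    combo_index = 0
    for scfg in config["scenarios"]:
        sname = scfg.get("name", scfg.get("type"))
        modifiers = _build_scenario_from_config(scfg, horizon)
        if scfg.get("interventions"):
            catalog = iv.load_intervention_catalog()
            active = [
                iv.with_window(catalog[entry["name"]], tuple(entry["active_window"]))
                if "active_window" in entry
                else catalog[entry["name"]]
                for entry in scfg["interventions"]
            ]
            modifiers = iv.apply_interventions(modifiers, active)
        for rcfg in config["regions"]:
            rname = rcfg.get("name", rcfg.get("population_config"))
            targets = load_population_config(rcfg["population_config"])
            n_agents = int(rcfg.get("n_agents", 2000))
            agents = generate_population(targets, n_agents, seed=base_seed + combo_index)
            capacity = engine.CapacityModel.for_population(agents, params, headroom=headroom)
            spec = engine.RunSpec(
                agents=agents,
                params=params,
                modifiers=modifiers,
                capacity=capacity,
                horizon=horizon,
                start_date=start_date,
            )
            n_runs = manifest["replicates"]
            summaries[(sname, rname)] = engine.run_ensemble(
                spec, n_runs, base_seed + 1000 * (combo_index + 1)
            )
            executed += n_runs
            combo_index += 1
    manifest["executed_runs"] = executed
    return summaries, manifest
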