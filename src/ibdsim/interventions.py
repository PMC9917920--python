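"""Recovery interventions that partially restore disrupted multipliers.

The shipped catalog holds six interventions spanning three messaging
interventions (demand-side only: physician outreach 15%, system social
signaling 40%, national confidence building 60%) and three logistics /
infrastructure interventions with both supply and demand effects (simple
navigation assistance 5%/15%, barrier elimination 40%/40%, emergency
response infrastructure 60%/55%).  Small percentages correspond to
individual-level involvement and reach; large ones to high-level,
large-scale delivery.

An impact is interpreted as *fractional closure of the disruption gap*: a
multiplier m becomes m + impact x (1 - m).  Composing several interventions
applies each to the residual gap, which is commutative and bounded —
combined restoration = 1 - prod(1 - impact_i).  (The alternative reading,
impacts scaling the disruption magnitude itself, m' = 1 - (1-m)(1-impact),
is algebraically identical for a single channel value; the residual-gap rule
is stated because it also defines composition.)
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from importlib import resources
from typing import Sequence
import warnings

from ibdsim.errors import ConfigError
from ibdsim.pathway import DEMAND_CHANNELS, SUPPLY_SERVICES
from ibdsim.scenarios import ScenarioModifiers


@dataclass(frozen=True)
class InterventionSpec:
    """One catalog intervention.

    ``supply_impact`` is ``None`` for demand-only (messaging) interventions.
    ``active_window`` is a half-open [start, end) week interval; ``None``
    means active for the whole horizon (defaulting in practice to disruption
    onset onward).
    """

    name: str
    demand_impact: float
    supply_impact: float | None = None
    demand_targets: tuple[str, ...] = DEMAND_CHANNELS
    supply_targets: tuple[str, ...] = ()
    active_window: tuple[int, int] | None = None
    description: str = ""

    def __post_init__(self) -> None:
        problems = []
        if not 0.0 <= self.demand_impact <= 1.0:
            problems.append(f"demand_impact must lie in [0,1], got {self.demand_impact}")
        if self.supply_impact is not None and not 0.0 <= self.supply_impact <= 1.0:
            problems.append(f"supply_impact must lie in [0,1], got {self.supply_impact}")
        if self.demand_impact > 0 and not self.demand_targets:
            problems.append("demand_impact set but no demand_targets")
        if self.supply_impact is not None and self.supply_impact > 0 and not self.supply_targets:
            problems.append("supply_impact set but no supply_targets")
        unknown_d = set(self.demand_targets) - set(DEMAND_CHANNELS)
        unknown_s = set(self.supply_targets) - set(SUPPLY_SERVICES)
        if unknown_d:
            problems.append(f"unknown demand targets {sorted(unknown_d)}")
        if unknown_s:
            problems.append(f"unknown supply targets {sorted(unknown_s)}")
        if problems:
            raise ConfigError(f"invalid intervention {self.name!r}: " + "; ".join(problems))


def load_intervention_catalog() -> dict[str, InterventionSpec]:
    """The packaged six-intervention catalog, keyed by name."""
    raw = json.loads(
        resources.files("ibdsim.data").joinpath("interventions.json").read_text()
    )
    catalog = {}
    for name, entry in raw.items():
        catalog[name] = InterventionSpec(
            name=name,
            demand_impact=entry["demand_impact"],
            supply_impact=entry["supply_impact"],
            demand_targets=tuple(entry["demand_targets"]),
            supply_targets=tuple(entry["supply_targets"]),
            description=entry.get("description", ""),
        )
    return catalog


def with_window(spec: InterventionSpec, window: tuple[int, int]) -> InterventionSpec:
    """Copy of ``spec`` restricted to the [start, end) week window."""
    start, end = window
    if end < start:
        raise ConfigError(f"active_window end {end} before start {start}")
    return replace(spec, active_window=(int(start), int(end)))


def with_impacts(
    spec: InterventionSpec,
    demand_impact: float | None = None,
    supply_impact: float | None = None,
) -> InterventionSpec:
    """Override catalog impact values (warns: these are the study's values)."""
    warnings.warn(
        f"overriding catalog impact values for intervention {spec.name!r}",
        UserWarning,
        stacklevel=2,
    )
    out = spec
    if demand_impact is not None:
        out = replace(out, demand_impact=demand_impact)
    if supply_impact is not None:
        out = replace(out, supply_impact=supply_impact)
    return out


def apply_interventions(
    modifiers: ScenarioModifiers, active: Sequence[InterventionSpec]
) -> ScenarioModifiers:
    """Apply interventions to a disrupted scenario by residual-gap closure.

    For each targeted channel/service within each intervention's active
    window: new = old + impact x (1 - old).  Values already at (or above) 1
    are unchanged.  The composition over interventions is order-independent.
    """
    demand = modifiers.demand.copy()
    supply = modifiers.supply.copy()
    horizon = len(demand)
    for spec in active:
        if spec.active_window is None:
            rows = slice(0, horizon)
        else:
            start, end = spec.active_window
            rows = slice(max(start, 0), min(end, horizon))
        if spec.demand_impact:
            for ch in spec.demand_targets:
                col = demand[ch].to_numpy(copy=True)
                gap = 1.0 - col[rows]
                col[rows] = col[rows] + spec.demand_impact * gap.clip(min=0.0)
                demand[ch] = col
        if spec.supply_impact:
            for svc in spec.supply_targets:
                col = supply[svc].to_numpy(copy=True)
                gap = 1.0 - col[rows]
                col[rows] = col[rows] + spec.supply_impact * gap.clip(min=0.0)
                supply[svc] = col
    return ScenarioModifiers(demand=demand, supply=supply)
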