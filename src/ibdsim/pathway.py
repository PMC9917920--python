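"""Weekly IBD clinical-pathway state machine.

Agents move through three stages: undiagnosed and asymptomatic, symptomatic
and seeking care, and diagnosed in continuous care.  The time step is one
week.  Behavioral events (care seeking, attending a scheduled visit,
collecting a biologic refill) are scaled by per-channel demand multipliers;
disease biology (symptom onset, severity progression) is never scaled.
Events whose attendance draw fails under a reduced multiplier are emitted as
*deferred*: a missed scheduled visit or refill is postponed by a full cycle
(the patient skips the appointment and keeps their periodic rhythm), and a
suppressed care-seeking attempt returns the agent to hazard-driven seeking.
Sustained reductions in served demand therefore track the multipliers, while
catch-up surges after a disruption come from the supply-side backlog queue
and from the enlarged symptomatic pool.

:func:`step_agent` is the scalar, capacity-free reference kernel: it assumes
every demanded service is supplied.  The vectorized engine applies the same
rules over agent arrays and adds finite capacity with a backlog queue; an
equivalence test holds the two paths to identical output under unlimited
capacity and shared random draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy.special import ndtri

from ibdsim.errors import ConfigError

STAGE_UNDIAGNOSED = "undiagnosed_asymptomatic"
STAGE_SYMPTOMATIC = "symptomatic_seeking_care"
STAGE_DIAGNOSED = "diagnosed_continuous_care"

TREAT_NONE = "none"
TREAT_CONVENTIONAL = "conventional"
TREAT_BIOLOGIC = "biologic"

#: demand-multiplier channels (patient behavior)
DEMAND_CHANNELS = ("care_seeking", "continuous_care_visits", "biologic_refill")
#: supply services (medical care capacity)
SUPPLY_SERVICES = ("outpatient_visits", "procedures", "biologic_dispensing")

# Fixed per-agent-per-week uniform draw slots.  The engine generates one
# (n_agents, N_DRAWS) uniform block per week in this column order; the scalar
# kernel consumes the same slots, so the two paths can share randomness.
D_ONSET = 0
D_SEEK = 1
D_ATTEND_VISIT = 2
D_ATTEND_BIO = 3
D_DIAG = 4
D_PROG = 5
D_BIOINIT = 6
D_SERVE_VISIT = 7
D_SERVE_PROC = 8
D_JIT_VISIT = 9
D_JIT_PROC = 10
D_JIT_BIO = 11
N_DRAWS = 12

EVENT_KEYS = (
    "new_patients",
    "outpatient_visits",
    "procedures",
    "biologics",
    "new_vedolizumab_starts",
    "deferred_visits",
    "deferred_biologics",
)


def weekly_hazard(annual_probability: float) -> float:
    """Convert an annual event probability to a per-week hazard."""
    if not 0.0 <= annual_probability <= 1.0:
        raise ConfigError(f"annual probability must lie in [0,1], got {annual_probability}")
    return 1.0 - (1.0 - annual_probability) ** (1.0 / 52.0)


@dataclass(frozen=True)
class PathwayParameters:
    """Per-week pathway hazards and service intervals.

    All hazards are per-week probabilities; ``incidence_growth`` is the
    yearly multiplicative growth factor g of the symptom-onset hazard
    (g = 1 means a stationary incidence).  Intervals are in weeks, keyed by
    severity where clinically relevant: moderate-to-severe patients are seen
    and scoped more often.  ``interval_jitter_sd`` desynchronizes scheduled
    events so a population does not artificially pulse in lockstep.
    """

    symptom_onset_hazard: float = 0.002
    incidence_growth: float = 1.08
    care_seeking_hazard: float = 0.25
    diagnosis_probability_per_visit: float = 0.8
    visit_interval: Mapping[str, float] = field(
        default_factory=lambda: {"mild_moderate": 12.0, "moderate_severe": 6.0}
    )
    procedure_interval: Mapping[str, float] = field(
        default_factory=lambda: {"mild_moderate": 52.0, "moderate_severe": 26.0}
    )
    biologic_interval: float = 8.0
    biologic_initiation_hazard: float = 0.004
    severity_progression_hazard: float = 0.001
    interval_jitter_sd: float = 1.0

    def __post_init__(self) -> None:
        problems = []
        for name in (
            "symptom_onset_hazard",
            "care_seeking_hazard",
            "diagnosis_probability_per_visit",
            "biologic_initiation_hazard",
            "severity_progression_hazard",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                problems.append(f"{name}: must lie in [0,1], got {v}")
        if not self.incidence_growth > 0:
            problems.append(f"incidence_growth: must be > 0, got {self.incidence_growth}")
        for name in ("visit_interval", "procedure_interval"):
            iv = getattr(self, name)
            for sev in ("mild_moderate", "moderate_severe"):
                if sev not in iv:
                    problems.append(f"{name}: missing severity {sev!r}")
                elif iv[sev] < 1:
                    problems.append(f"{name}[{sev}]: must be >= 1 week, got {iv[sev]}")
        if self.biologic_interval < 1:
            problems.append(f"biologic_interval: must be >= 1 week, got {self.biologic_interval}")
        if self.interval_jitter_sd < 0:
            problems.append(f"interval_jitter_sd: must be >= 0, got {self.interval_jitter_sd}")
        if problems:
            raise ConfigError("invalid pathway parameters: " + "; ".join(problems))


@dataclass(frozen=True)
class PatientState:
    """Dynamic pathway state of one agent.

    ``procedure_threshold`` and ``biologic_threshold`` are the jittered cycle
    lengths currently in force for the two since-counters; they are redrawn
    each time the corresponding event fires.
    """

    stage: str = STAGE_UNDIAGNOSED
    severity: str = "mild_moderate"
    treatment: str = TREAT_NONE
    weeks_since_symptom_onset: int = 0
    next_visit_due: float = 0.0
    weeks_since_last_procedure: int = 0
    weeks_since_last_biologic: int = 0
    pending_diagnosis: bool = False
    procedure_threshold: float = 52.0
    biologic_threshold: float = 8.0

    def __post_init__(self) -> None:
        if self.stage == STAGE_UNDIAGNOSED and self.treatment != TREAT_NONE:
            raise ConfigError("undiagnosed agents must have treatment 'none'")
        if self.treatment == TREAT_BIOLOGIC and self.stage != STAGE_DIAGNOSED:
            raise ConfigError("biologic treatment implies diagnosed continuous care")
        for name in (
            "weeks_since_symptom_onset",
            "weeks_since_last_procedure",
            "weeks_since_last_biologic",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name}: timers must be nonnegative")


class AgentDraws:
    """One week's uniform draws for one agent (the ``N_DRAWS`` slot vector)."""

    __slots__ = ("u",)

    def __init__(self, u: np.ndarray):
        self.u = np.asarray(u, dtype=float)
        if self.u.shape != (N_DRAWS,):
            raise ConfigError(f"draw vector must have shape ({N_DRAWS},)")

    @classmethod
    def from_rng(cls, rng: np.random.Generator) -> "AgentDraws":
        return cls(rng.random(N_DRAWS))


def advance_incidence(params: PathwayParameters, week: int) -> float:
    """Effective symptom-onset hazard at ``week``: base x g^(week/52)."""
    if week < 0:
        raise ConfigError(f"week must be >= 0, got {week}")
    return params.symptom_onset_hazard * params.incidence_growth ** (week / 52.0)


def jittered_interval(base: float, jitter_sd: float, u: float) -> float:
    """Cycle length ``base`` perturbed by a rounded normal draw, floor 1 week."""
    if jitter_sd == 0.0:
        return float(base)
    return max(1.0, float(np.rint(base + ndtri(u) * jitter_sd)))


def step_agent(
    state: PatientState,
    params: PathwayParameters,
    demand_multiplier: Mapping[str, float],
    week: int,
    rng,
    *,
    onset_hazard: float | None = None,
) -> tuple[PatientState, dict[str, float]]:
    """Advance one agent by one week; capacity-free reference kernel.

    ``rng`` is either a numpy Generator or an :class:`AgentDraws` (the latter
    lets callers share draws with the vectorized engine).  ``onset_hazard``
    overrides :func:`advance_incidence` when the caller renormalizes the
    hazard for a finite undiagnosed sample.  Returns the new state and unit
    event counts (callers weight them by the agent's weight).
    """
    draws = rng if isinstance(rng, AgentDraws) else AgentDraws.from_rng(rng)
    u = draws.u
    d_care = demand_multiplier.get("care_seeking", 1.0)
    d_visit = demand_multiplier.get("continuous_care_visits", 1.0)
    d_bio = demand_multiplier.get("biologic_refill", 1.0)
    for name, v in (("care_seeking", d_care), ("continuous_care_visits", d_visit),
                    ("biologic_refill", d_bio)):
        if v < 0:
            raise ConfigError(f"demand multiplier {name} must be >= 0, got {v}")
    events = dict.fromkeys(EVENT_KEYS, 0.0)
    js = params.interval_jitter_sd

    stage = state.stage
    severity = state.severity
    treatment = state.treatment
    since_onset = state.weeks_since_symptom_onset
    next_visit_due = state.next_visit_due
    since_proc = state.weeks_since_last_procedure
    since_bio = state.weeks_since_last_biologic
    pending = state.pending_diagnosis
    proc_thresh = state.procedure_threshold
    bio_thresh = state.biologic_threshold

    if stage == STAGE_UNDIAGNOSED:
        hazard = advance_incidence(params, week) if onset_hazard is None else onset_hazard
        if u[D_ONSET] < min(hazard, 1.0):
            stage = STAGE_SYMPTOMATIC
            since_onset = 0
    elif stage == STAGE_SYMPTOMATIC:
        intent = pending or (u[D_SEEK] < params.care_seeking_hazard)
        if intent:
            if u[D_ATTEND_VISIT] < min(d_care, 1.0):
                events["outpatient_visits"] += 1.0
                events["procedures"] += 1.0  # diagnostic work-up at the visit
                if u[D_DIAG] < params.diagnosis_probability_per_visit:
                    stage = STAGE_DIAGNOSED
                    treatment = TREAT_CONVENTIONAL
                    pending = False
                    events["new_patients"] += 1.0
                    next_visit_due = week + jittered_interval(
                        params.visit_interval[severity], js, u[D_JIT_VISIT]
                    )
                    since_proc = 0
                    proc_thresh = jittered_interval(
                        params.procedure_interval[severity], js, u[D_JIT_PROC]
                    )
                else:
                    pending = True
            else:
                events["deferred_visits"] += 1.0
                pending = False  # suppressed; re-seeks via the hazard
        since_onset += 1

    if stage == STAGE_DIAGNOSED and state.stage == STAGE_DIAGNOSED:
        # progression and initiation are biology/clinical decisions: unscaled
        if severity == "mild_moderate" and u[D_PROG] < params.severity_progression_hazard:
            severity = "moderate_severe"
        if (
            treatment == TREAT_CONVENTIONAL
            and severity == "moderate_severe"
            and u[D_BIOINIT] < params.biologic_initiation_hazard
        ):
            treatment = TREAT_BIOLOGIC
            events["new_vedolizumab_starts"] += 1.0
            bio_thresh = jittered_interval(params.biologic_interval, js, u[D_JIT_BIO])
            since_bio = int(bio_thresh)  # first dispense due immediately

        if week >= next_visit_due:
            if u[D_ATTEND_VISIT] < min(d_visit, 1.0):
                events["outpatient_visits"] += 1.0
                if since_proc >= proc_thresh:
                    events["procedures"] += 1.0
                    since_proc = 0
                    proc_thresh = jittered_interval(
                        params.procedure_interval[severity], js, u[D_JIT_PROC]
                    )
                next_visit_due = week + jittered_interval(
                    params.visit_interval[severity], js, u[D_JIT_VISIT]
                )
            else:
                events["deferred_visits"] += 1.0
                # appointment skipped; next one a full cycle later
                next_visit_due = week + jittered_interval(
                    params.visit_interval[severity], js, u[D_JIT_VISIT]
                )

        if treatment == TREAT_BIOLOGIC and since_bio >= bio_thresh:
            if u[D_ATTEND_BIO] < min(d_bio, 1.0):
                events["biologics"] += 1.0
                since_bio = 0
                bio_thresh = jittered_interval(params.biologic_interval, js, u[D_JIT_BIO])
            else:
                events["deferred_biologics"] += 1.0
                # missed dose; next refill a full cycle later
                since_bio = 0
                bio_thresh = jittered_interval(params.biologic_interval, js, u[D_JIT_BIO])

        since_proc += 1
        if treatment == TREAT_BIOLOGIC:
            since_bio += 1

    return (
        replace(
            state,
            stage=stage,
            severity=severity,
            treatment=treatment,
            weeks_since_symptom_onset=since_onset,
            next_visit_due=next_visit_due,
            weeks_since_last_procedure=since_proc,
            weeks_since_last_biologic=since_bio,
            pending_diagnosis=pending,
            procedure_threshold=proc_thresh,
            biologic_threshold=bio_thresh,
        ),
        events,
    )
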