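"""Demand simulator: run weighted agent populations through the clinical
pathway under time-varying disruption modifiers with finite service capacity.

The engine is the vectorized counterpart of the scalar kernel in
:mod:`ibdsim.pathway`: agents live in numpy state arrays and one uniform draw
block of shape (N_DRAWS, n_agents) is generated per week in the same slot
order the scalar kernel uses (one row per slot, float32), so the two paths
produce identical output under unlimited capacity and shared draws.

Supply is modelled per service as a weekly capacity, scaled by the scenario's
supply multipliers.  Demand that exceeds effective capacity joins a backlog
queue; during recovery a fraction ``backlog_service_rate`` of the queue is
admitted each week and a fraction ``abandonment_rate`` of what remains is
dropped.  The queue satisfies an exact conservation identity every week:

    cumulative demanded = cumulative served + backlog + cumulative abandoned

Rapid backlog alleviation (high service rate) releases pent-up demand in a
burst and, through the natural periodicity of visits and refills, produces
larger post-recovery oscillations than gradual alleviation.

Incidence note: with a finite agent sample the undiagnosed reservoir would
deplete and bend the exponential incidence trend, so the weekly onset hazard
is renormalized by (initial / current) undiagnosed weight.  Expected weekly
onsets then follow base x g^(week/52) exactly — an open-population
approximation justified by the at-risk general population being orders of
magnitude larger than the IBD population.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import ndtri

from ibdsim.errors import ConfigError
from ibdsim.pathway import (
    D_ATTEND_BIO,
    D_ATTEND_VISIT,
    D_BIOINIT,
    D_DIAG,
    D_JIT_BIO,
    D_JIT_PROC,
    D_JIT_VISIT,
    D_ONSET,
    D_PROG,
    D_SEEK,
    D_SERVE_PROC,
    D_SERVE_VISIT,
    N_DRAWS,
    SUPPLY_SERVICES,
    PathwayParameters,
    PatientState,
    STAGE_DIAGNOSED,
    STAGE_SYMPTOMATIC,
    STAGE_UNDIAGNOSED,
    TREAT_BIOLOGIC,
    TREAT_CONVENTIONAL,
    TREAT_NONE,
    advance_incidence,
)
from ibdsim.scenarios import ScenarioModifiers

#: canonical demand-series channels, in CSV column order
CHANNELS = (
    "new_patients",
    "total_patients",
    "outpatient_visits",
    "procedures",
    "biologics",
    "vedolizumab_infusions",
    "new_vedolizumab_starts",
)

SERIES_COLUMNS = ["week_start", *CHANNELS]


@dataclass(frozen=True)
class CapacityModel:
    """Weekly service capacities and backlog-queue behavior.

    Capacities may be ``inf`` (unconstrained).  ``backlog_service_rate`` is
    the fraction of the queued backlog admitted for service each week;
    ``abandonment_rate`` is the fraction of the remaining queue dropped each
    week (patients who stop waiting).
    """

    weekly_capacity: Mapping[str, float] = field(
        default_factory=lambda: {s: np.inf for s in SUPPLY_SERVICES}
    )
    backlog_service_rate: float = 0.25
    abandonment_rate: float = 0.05

    def __post_init__(self) -> None:
        problems = []
        for svc in SUPPLY_SERVICES:
            if svc not in self.weekly_capacity:
                problems.append(f"weekly_capacity: missing service {svc!r}")
            elif self.weekly_capacity[svc] < 0:
                problems.append(f"weekly_capacity[{svc}]: must be >= 0")
        for name in ("backlog_service_rate", "abandonment_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                problems.append(f"{name}: must lie in [0,1], got {v}")
        if problems:
            raise ConfigError("invalid capacity model: " + "; ".join(problems))

    @classmethod
    def unlimited(cls) -> "CapacityModel":
        return cls()

    @classmethod
    def for_population(
        cls,
        agents: pd.DataFrame,
        params: PathwayParameters,
        headroom: float = 1.5,
        backlog_service_rate: float = 0.25,
        abandonment_rate: float = 0.05,
    ) -> "CapacityModel":
        """Finite capacities sized at ``headroom`` times the population's
        expected steady-state weekly demand (so baseline runs are unclogged
        but supply shocks bite)."""
        w = agents["weight"].to_numpy(dtype=float)
        diag = agents["state"].str.startswith("diagnosed").to_numpy()
        severe = (agents["severity"] == "moderate_severe").to_numpy()
        bio = (agents["state"] == "diagnosed_biologic").to_numpy()
        visit_rate = np.where(
            severe,
            1.0 / params.visit_interval["moderate_severe"],
            1.0 / params.visit_interval["mild_moderate"],
        )
        proc_rate = np.where(
            severe,
            1.0 / params.procedure_interval["moderate_severe"],
            1.0 / params.procedure_interval["mild_moderate"],
        )
        visits = float((w * visit_rate)[diag].sum())
        procs = float((w * proc_rate)[diag].sum())
        bios = float(w[bio].sum() / params.biologic_interval)
        floor = max(w.sum() * 1e-4, 1.0)
        return cls(
            weekly_capacity={
                "outpatient_visits": max(visits, floor) * headroom,
                "procedures": max(procs, floor) * headroom,
                "biologic_dispensing": max(bios, floor) * headroom,
            },
            backlog_service_rate=backlog_service_rate,
            abandonment_rate=abandonment_rate,
        )


@dataclass(frozen=True)
class CapacityStep:
    """Outcome of one week of one service queue."""

    served: float
    fresh_served: float
    backlog_served: float
    abandoned: float
    backlog: float  # queue after the update


def apply_capacity_single(
    demanded: float,
    capacity: float,
    supply_multiplier: float,
    backlog: float,
    backlog_service_rate: float,
    abandonment_rate: float,
) -> CapacityStep:
    """One week of the capacity/backlog queue for a single service.

    Fresh demand is served first, then the admitted share of the backlog;
    served = min(demanded + admitted, capacity x multiplier).  Unserved
    demand and the unadmitted backlog carry forward, minus abandonment.
    """
    if demanded < 0:
        raise ConfigError(f"demanded must be >= 0, got {demanded}")
    if supply_multiplier == 0.0:
        cap_eff = 0.0
    else:
        cap_eff = capacity * supply_multiplier
    admitted = backlog * backlog_service_rate
    fresh_served = min(demanded, cap_eff)
    backlog_served = min(admitted, cap_eff - fresh_served)
    remaining = (backlog - backlog_served) + (demanded - fresh_served)
    abandoned = remaining * abandonment_rate
    return CapacityStep(
        served=fresh_served + backlog_served,
        fresh_served=fresh_served,
        backlog_served=backlog_served,
        abandoned=abandoned,
        backlog=remaining - abandoned,
    )


def apply_capacity(
    demanded: Mapping[str, float],
    capacity: CapacityModel,
    supply_multiplier: Mapping[str, float],
    backlog: Mapping[str, float],
) -> tuple[dict[str, CapacityStep], dict[str, float]]:
    """Apply the weekly capacity/backlog update to every service.

    Returns per-service :class:`CapacityStep` results and the new backlog.
    """
    steps: dict[str, CapacityStep] = {}
    new_backlog: dict[str, float] = {}
    for svc in SUPPLY_SERVICES:
        step = apply_capacity_single(
            demanded.get(svc, 0.0),
            capacity.weekly_capacity[svc],
            supply_multiplier.get(svc, 1.0),
            backlog.get(svc, 0.0),
            capacity.backlog_service_rate,
            capacity.abandonment_rate,
        )
        steps[svc] = step
        new_backlog[svc] = step.backlog
    return steps, new_backlog


@dataclass
class DemandSeries:
    """Weekly demand-channel counts anchored to calendar weeks.

    ``frame`` holds one row per week with a ``week_start`` date column and
    the channels of :data:`CHANNELS`.  ``deferred`` and ``backlog`` carry the
    demand-side deferral and supply-side queue traces of a simulation run
    (absent for observed/claims series).
    """

    frame: pd.DataFrame
    region: str = ""
    deferred: pd.DataFrame | None = None
    backlog: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        missing = [c for c in SERIES_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ConfigError(f"demand series missing columns: {missing}")
        self.frame = self.frame[SERIES_COLUMNS].reset_index(drop=True)
        self.frame["week_start"] = pd.to_datetime(self.frame["week_start"])

    @property
    def start_date(self) -> pd.Timestamp:
        return self.frame["week_start"].iloc[0]

    def __len__(self) -> int:
        return len(self.frame)


@dataclass(frozen=True)
class EnsembleSummary:
    """Per-week five-number summary (min, Q1, median, Q3, max) over runs."""

    frame: pd.DataFrame  # columns: channel, week_start, min, q1, median, q3, max
    n_runs: int


@dataclass(frozen=True)
class RunSpec:
    """Everything defining one simulation run except its seed."""

    agents: pd.DataFrame
    params: PathwayParameters
    modifiers: ScenarioModifiers
    capacity: CapacityModel
    horizon: int
    start_date: str = "2020-01-06"


class _StateArrays:
    """Vectorized agent state (internal)."""

    __slots__ = (
        "stage", "severe", "treat", "pending", "next_visit_due",
        "since_proc", "proc_thresh", "since_bio", "bio_thresh", "weight",
    )

    def __init__(self, n: int):
        self.stage = np.zeros(n, dtype=np.int8)
        self.severe = np.zeros(n, dtype=bool)
        self.treat = np.zeros(n, dtype=np.int8)
        self.pending = np.zeros(n, dtype=bool)
        self.next_visit_due = np.zeros(n, dtype=np.float64)
        self.since_proc = np.zeros(n, dtype=np.float64)
        self.proc_thresh = np.zeros(n, dtype=np.float64)
        self.since_bio = np.zeros(n, dtype=np.float64)
        self.bio_thresh = np.zeros(n, dtype=np.float64)
        self.weight = np.zeros(n, dtype=np.float64)


def initialize_state(
    agents: pd.DataFrame, params: PathwayParameters, rng: np.random.Generator
) -> _StateArrays:
    """Build state arrays from an agent table, staggering scheduled timers.

    Diagnosed agents receive uniformly staggered next-visit dates and
    since-counters so the population does not pulse in lockstep at week 0.
    Deterministic given the generator state.
    """
    n = len(agents)
    st = _StateArrays(n)
    st.weight[:] = agents["weight"].to_numpy(dtype=float)
    state_col = agents["state"].to_numpy()
    st.stage[state_col == "undiagnosed_asymptomatic"] = 0
    st.stage[state_col == "symptomatic_seeking_care"] = 1
    diag = np.char.startswith(state_col.astype(str), "diagnosed")
    st.stage[diag] = 2
    st.severe[:] = (agents["severity"] == "moderate_severe").to_numpy()
    st.treat[diag] = 1
    st.treat[state_col == "diagnosed_biologic"] = 2

    visit_iv = np.where(
        st.severe,
        params.visit_interval["moderate_severe"],
        params.visit_interval["mild_moderate"],
    )
    proc_iv = np.where(
        st.severe,
        params.procedure_interval["moderate_severe"],
        params.procedure_interval["mild_moderate"],
    )
    u = rng.random((n, 3))
    st.next_visit_due[:] = np.where(diag, np.floor(u[:, 0] * visit_iv), 0.0)
    st.since_proc[:] = np.where(diag, np.floor(u[:, 1] * proc_iv), 0.0)
    st.proc_thresh[:] = proc_iv
    st.since_bio[:] = np.where(st.treat == 2, np.floor(u[:, 2] * params.biologic_interval), 0.0)
    st.bio_thresh[:] = params.biologic_interval
    return st


def state_of(st: _StateArrays, i: int) -> PatientState:
    """Scalar :class:`PatientState` view of agent ``i`` (for cross-checks)."""
    stage = {0: STAGE_UNDIAGNOSED, 1: STAGE_SYMPTOMATIC, 2: STAGE_DIAGNOSED}[int(st.stage[i])]
    treat = {0: TREAT_NONE, 1: TREAT_CONVENTIONAL, 2: TREAT_BIOLOGIC}[int(st.treat[i])]
    return PatientState(
        stage=stage,
        severity="moderate_severe" if st.severe[i] else "mild_moderate",
        treatment=treat,
        weeks_since_symptom_onset=0,
        next_visit_due=float(st.next_visit_due[i]),
        weeks_since_last_procedure=int(st.since_proc[i]),
        weeks_since_last_biologic=int(st.since_bio[i]),
        pending_diagnosis=bool(st.pending[i]),
        procedure_threshold=float(st.proc_thresh[i]),
        biologic_threshold=float(st.bio_thresh[i]),
    )


def _jitter_vec(base: np.ndarray, sd: float, u: np.ndarray) -> np.ndarray:
    if sd == 0.0:
        return base.astype(float)
    return np.maximum(1.0, np.rint(base + ndtri(u) * sd))


def run_simulation(
    agents: pd.DataFrame,
    params: PathwayParameters,
    modifiers: ScenarioModifiers,
    capacity: CapacityModel,
    horizon: int,
    seed: int,
    start_date: str = "2020-01-06",
) -> DemandSeries:
    """Simulate ``horizon`` weeks of demand for one weighted population.

    Deterministic in all inputs plus ``seed``.  Weekly update order: disease
    biology (onset, progression, biologic initiation), demand generation
    (care seeking, scheduled visits, refills) under the week's demand
    multipliers, capacity/backlog resolution under the week's supply
    multipliers, then diagnosis resolution (a new patient is diagnosed only
    if both their first visit and the diagnostic procedure were actually
    served that week).
    """
    if horizon < 1:
        raise ConfigError(f"horizon must be >= 1, got {horizon}")
    if modifiers.horizon < horizon:
        raise ConfigError(
            f"modifier series covers {modifiers.horizon} weeks < horizon {horizon}"
        )
    n = len(agents)
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([int(seed), 0x51D])))
    st = initialize_state(agents, params, rng)

    dem = modifiers.demand.to_numpy(dtype=float)  # columns: care_seeking, visits, bio
    sup = modifiers.supply.to_numpy(dtype=float)  # columns follow SUPPLY_SERVICES

    js = params.interval_jitter_sd
    und_weight0 = float(st.weight[st.stage == 0].sum())

    backlog = {svc: 0.0 for svc in SUPPLY_SERVICES}
    cum_demanded = dict.fromkeys(SUPPLY_SERVICES, 0.0)
    cum_served = dict.fromkeys(SUPPLY_SERVICES, 0.0)
    cum_abandoned = dict.fromkeys(SUPPLY_SERVICES, 0.0)

    out = np.zeros((horizon, len(CHANNELS)))
    deferred_rows = np.zeros((horizon, 2))  # visits, biologics
    backlog_rows = np.zeros((horizon, len(SUPPLY_SERVICES) * 4))

    for week in range(horizon):
        u = rng.random((N_DRAWS, n), dtype=np.float32)
        d_care, d_visit, d_bio = dem[week]
        sup_mult = dict(zip(SUPPLY_SERVICES, sup[week]))

        # --- biology -------------------------------------------------------
        und = st.stage == 0
        onset = np.zeros(n, dtype=bool)
        if und.any():
            und_now = float(st.weight[und].sum())
            hazard = advance_incidence(params, week)
            if und_now > 0:
                hazard = min(hazard * und_weight0 / und_now, 1.0)
            onset = und & (u[D_ONSET] < hazard)
            st.stage[onset] = 1

        dia0 = st.stage == 2  # diagnosed before this week
        prog = dia0 & ~st.severe & (u[D_PROG] < params.severity_progression_hazard)
        st.severe |= prog
        visit_iv = np.where(
            st.severe,
            params.visit_interval["moderate_severe"],
            params.visit_interval["mild_moderate"],
        )
        proc_iv = np.where(
            st.severe,
            params.procedure_interval["moderate_severe"],
            params.procedure_interval["mild_moderate"],
        )
        init = (
            dia0
            & (st.treat == 1)
            & st.severe
            & (u[D_BIOINIT] < params.biologic_initiation_hazard)
        )
        if init.any():
            st.treat[init] = 2
            st.bio_thresh[init] = _jitter_vec(
                np.full(int(init.sum()), params.biologic_interval), js, u[D_JIT_BIO][init]
            )
            st.since_bio[init] = st.bio_thresh[init]
        new_starts = float(st.weight[init].sum())

        # --- demand generation ---------------------------------------------
        sym = (st.stage == 1) & ~onset
        intent = sym & (st.pending | (u[D_SEEK] < params.care_seeking_hazard))
        attend_new = intent & (u[D_ATTEND_VISIT] < min(d_care, 1.0))
        defer_new = intent & ~attend_new
        st.pending[defer_new] = False  # suppressed; re-seeks via the hazard

        visit_due = dia0 & (week >= st.next_visit_due)
        attend_vis = visit_due & (u[D_ATTEND_VISIT] < min(d_visit, 1.0))
        defer_vis = visit_due & ~attend_vis
        if defer_vis.any():
            # appointment skipped; next one a full cycle later
            st.next_visit_due[defer_vis] = week + _jitter_vec(
                visit_iv[defer_vis], js, u[D_JIT_VISIT][defer_vis]
            )

        bio_due = dia0 & (st.treat == 2) & (st.since_bio >= st.bio_thresh)
        attend_bio = bio_due & (u[D_ATTEND_BIO] < min(d_bio, 1.0))
        defer_bio = bio_due & ~attend_bio

        # --- capacity: outpatient visits -----------------------------------
        out_demand = float(st.weight[attend_new].sum() + st.weight[attend_vis].sum())
        step_out = apply_capacity_single(
            out_demand,
            capacity.weekly_capacity["outpatient_visits"],
            sup_mult["outpatient_visits"],
            backlog["outpatient_visits"],
            capacity.backlog_service_rate,
            capacity.abandonment_rate,
        )
        p_out = step_out.fresh_served / out_demand if out_demand > 0 else 1.0
        served_new_visit = attend_new & (u[D_SERVE_VISIT] < p_out)
        st.pending[attend_new & ~served_new_visit] = True

        # continuing-care attendance resets schedules regardless of queueing:
        # the unserved share is owned by the backlog queue (served later as
        # catch-up appointments), while the patient keeps their usual rhythm
        if attend_vis.any():
            st.next_visit_due[attend_vis] = week + _jitter_vec(
                visit_iv[attend_vis], js, u[D_JIT_VISIT][attend_vis]
            )

        # --- capacity: procedures ------------------------------------------
        proc_due = attend_vis & (st.since_proc >= st.proc_thresh)
        proc_demand = float(st.weight[served_new_visit].sum() + st.weight[proc_due].sum())
        step_proc = apply_capacity_single(
            proc_demand,
            capacity.weekly_capacity["procedures"],
            sup_mult["procedures"],
            backlog["procedures"],
            capacity.backlog_service_rate,
            capacity.abandonment_rate,
        )
        p_proc = step_proc.fresh_served / proc_demand if proc_demand > 0 else 1.0
        served_new_proc = served_new_visit & (u[D_SERVE_PROC] < p_proc)

        diagnose = served_new_proc & (u[D_DIAG] < params.diagnosis_probability_per_visit)
        undiagnosed_attendees = served_new_visit & ~diagnose
        st.pending[undiagnosed_attendees] = True
        if diagnose.any():
            st.stage[diagnose] = 2
            st.treat[diagnose] = 1
            st.pending[diagnose] = False
            st.next_visit_due[diagnose] = week + _jitter_vec(
                visit_iv[diagnose], js, u[D_JIT_VISIT][diagnose]
            )
            st.since_proc[diagnose] = 0.0
            st.proc_thresh[diagnose] = _jitter_vec(
                proc_iv[diagnose], js, u[D_JIT_PROC][diagnose]
            )
        if proc_due.any():
            st.since_proc[proc_due] = 0.0
            st.proc_thresh[proc_due] = _jitter_vec(proc_iv[proc_due], js, u[D_JIT_PROC][proc_due])

        # --- capacity: biologic dispensing ---------------------------------
        bio_demand = float(st.weight[attend_bio].sum())
        step_bio = apply_capacity_single(
            bio_demand,
            capacity.weekly_capacity["biologic_dispensing"],
            sup_mult["biologic_dispensing"],
            backlog["biologic_dispensing"],
            capacity.backlog_service_rate,
            capacity.abandonment_rate,
        )
        cycled_bio = bio_due  # attended or skipped, the cycle restarts
        if cycled_bio.any():
            st.since_bio[cycled_bio] = 0.0
            st.bio_thresh[cycled_bio] = _jitter_vec(
                np.full(int(cycled_bio.sum()), params.biologic_interval),
                js,
                u[D_JIT_BIO][cycled_bio],
            )

        # --- timers ---------------------------------------------------------
        st.since_proc[dia0] += 1.0
        st.since_bio[dia0 & (st.treat == 2)] += 1.0

        # --- bookkeeping -----------------------------------------------------
        for svc, step in zip(SUPPLY_SERVICES, (step_out, step_proc, step_bio)):
            demand_val = {"outpatient_visits": out_demand, "procedures": proc_demand,
                          "biologic_dispensing": bio_demand}[svc]
            cum_demanded[svc] += demand_val
            cum_served[svc] += step.served
            cum_abandoned[svc] += step.abandoned
        backlog = {
            "outpatient_visits": step_out.backlog,
            "procedures": step_proc.backlog,
            "biologic_dispensing": step_bio.backlog,
        }

        new_pat = float(st.weight[diagnose].sum())
        total_diag = float(st.weight[st.stage == 2].sum())
        out[week] = (
            new_pat,
            total_diag,
            step_out.served,
            step_proc.served,
            step_bio.served,
            step_bio.served,  # biologic = vedolizumab; same event, both channels
            new_starts,
        )
        deferred_rows[week] = (
            float(st.weight[defer_new].sum() + st.weight[defer_vis].sum()),
            float(st.weight[defer_bio].sum()),
        )
        backlog_rows[week] = [
            v
            for svc in SUPPLY_SERVICES
            for v in (backlog[svc], cum_demanded[svc], cum_served[svc], cum_abandoned[svc])
        ]

    week_start = pd.date_range(start_date, periods=horizon, freq="7D")
    frame = pd.DataFrame(out, columns=list(CHANNELS))
    frame.insert(0, "week_start", week_start)
    deferred = pd.DataFrame(
        deferred_rows, columns=["deferred_visits", "deferred_biologics"]
    )
    deferred.insert(0, "week_start", week_start)
    backlog_frame = pd.DataFrame(
        backlog_rows,
        columns=[
            f"{svc}_{kind}"
            for svc in SUPPLY_SERVICES
            for kind in ("backlog", "cum_demanded", "cum_served", "cum_abandoned")
        ],
    )
    backlog_frame.insert(0, "week_start", week_start)
    region = str(agents["region"].iloc[0]) if n else ""
    return DemandSeries(frame=frame, region=region, deferred=deferred, backlog=backlog_frame)


def run_ensemble(spec: RunSpec, n_runs: int, base_seed: int) -> EnsembleSummary:
    """Run ``n_runs`` seeded replicates and summarize weekly five-number stats.

    Replicate r uses seed ``base_seed + r``; identical (spec, n_runs,
    base_seed) give identical summaries.
    """
    if n_runs < 1:
        raise ConfigError(f"n_runs must be >= 1, got {n_runs}")
    stack = np.zeros((n_runs, spec.horizon, len(CHANNELS)))
    week_start = None
    for r in range(n_runs):
        series = run_simulation(
            spec.agents,
            spec.params,
            spec.modifiers,
            spec.capacity,
            spec.horizon,
            seed=base_seed + r,
            start_date=spec.start_date,
        )
        stack[r] = series.frame[list(CHANNELS)].to_numpy()
        week_start = series.frame["week_start"]
    q = np.quantile(stack, [0.0, 0.25, 0.5, 0.75, 1.0], axis=0)
    rows = []
    for ci, channel in enumerate(CHANNELS):
        block = pd.DataFrame(
            {
                "channel": channel,
                "week_start": week_start,
                "min": q[0, :, ci],
                "q1": q[1, :, ci],
                "median": q[2, :, ci],
                "q3": q[3, :, ci],
                "max": q[4, :, ci],
            }
        )
        rows.append(block)
    return EnsembleSummary(frame=pd.concat(rows, ignore_index=True), n_runs=n_runs)


def aggregate_monthly(series: DemandSeries) -> pd.DataFrame:
    """Calendar-month means of the weekly channels.

    Weeks are assigned to the month containing their start date; the result
    is indexed by month period with one column per channel.
    """
    frame = series.frame.copy()
    months = frame["week_start"].dt.to_period("M")
    return frame.groupby(months)[list(CHANNELS)].mean()
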