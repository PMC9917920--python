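# Methods

`ibdsim` couples two models: a **population model** that constructs weighted
synthetic cohorts of inflammatory bowel disease (IBD) patients matching
published regional marginals, and a **demand model** that pushes those agents
through a weekly clinical pathway under disruption scenarios with finite
service capacity. This note records the modelling assumptions, the numerical
choices, and what the shipped tests do and do not demonstrate.

## 1. Synthetic populations

A region is described by a `MarginalTargetSet`: a patient total, sex shares,
ulcerative-colitis/Crohn's-disease (UC/CD) shares, and per-(condition × sex)
age mean and SD on a closed age interval (default 18–74 years). Agents are
*weighted representatives*: a region of millions is represented by 100,000
agents whose weights sum exactly to the regional total, so full-scale
aggregates are testable at desk scale.

**Cell allocation.** Joint (sex × condition) shares are the product of the
two printed marginal vectors — only marginals are published, so independence
is the minimal assumption. Agents are apportioned to cells by
largest-remainder rounding with ties broken in a fixed canonical cell order
(male before female, UC before CD), which conserves the total exactly and is
reproducible. Per-cell summed weight equals the *real-valued* cell mass
(total × joint share), so weighted totals and categorical shares carry no
rounding or sampling error at all.

**Age sampling.** Ages are drawn by inverse-CDF from a truncated normal
whose *truncated* mean and SD equal the published values. The location and
scale are solved by nested Brent root finding: for each trial scale the
location is solved so the truncated mean is exact (the mean is strictly
increasing in the location), and the truncated SD is then bracketed in the
scale (it is strictly increasing in the scale). Tolerances are 1e-10 on both
brackets; an independent quadrature oracle in the tests confirms moments to
1e-6 years.

A subtlety worth stating plainly: the truncated-normal family on a bounded
interval cannot be arbitrarily dispersed. As the scale grows the density
tends to an exponentially tilted uniform, so the attainable SD at a given
mean is capped (about 16.2 years at the interval midpoint of [18, 74],
less off-center). Several published (mean, SD) cells exceed this cap —
e.g. an SD of 19.0 years at mean 58.6 on [18, 74] is unattainable by *any*
truncated normal (the cap there is ≈ 13.1). The strict fitter raises an
explicit infeasibility error naming the bound; population generation then
falls back to the maximally dispersed member with the mean matched exactly
(solved at a dispersion cap of σ = 300, within ~1e-3 years of the
supremum). Consequently weighted cell age *means* are always exact, while a
few cell SDs are reported at the attainable maximum rather than the
published value. Validation of target sets uses the distribution-free bound
sqrt((mean−lo)(hi−mean)) so such configurations load rather than fail.

**Localization.** `localize_weights` adapts an arbitrary seed population
(e.g. a foreign synthetic cohort) to regional targets by linear programming:
minimize the summed absolute deviation between weighted seed category counts
and target counts, subject to nonnegative weights summing to the regional
total. Absolute values are linearized with auxiliary variables and solved
with HiGHS. A brute-force simplex grid search verifies optimality on small
instances. Since no proprietary seed dataset ships with the package, this
path is exercised against in-repo synthetic seeds; behavioral/consumer
attributes beyond demographics are reduced to a single care-seeking
propensity scalar (default 1), as no usable detail on them is published.

## 2. Clinical pathway

The time step is one week; all hazards are per-week probabilities (annual
inputs convert by 1 − (1 − p)^(1/52)). Agents occupy three stages:
undiagnosed/asymptomatic, symptomatic and seeking care, and diagnosed in
continuous care. Severity (mild-to-moderate vs moderate-to-severe) and
treatment (conventional vs biologic) differentiate diagnosed agents; the
biologic is modelled as vedolizumab, and a dispensed refill is counted both
as a biologic prescription and an infusion (the outputs do not distinguish
the two events).

Weekly update order: disease biology (symptom onset, severity progression,
biologic initiation — never scaled by behavior), demand generation (care
seeking, scheduled visits, refills — scaled by the scenario's demand
multipliers), capacity resolution, diagnosis resolution.

Key rules and their rationale:

- **Onset** occurs at hazard h·g^(week/52): g is the yearly growth factor of
  incidence, the driver of the pre-pandemic growth in all demand channels.
  Because a finite agent sample would deplete its undiagnosed reservoir and
  bend the exponential, the engine renormalizes the weekly hazard by
  (initial/current) undiagnosed weight — an open-population approximation,
  justified because the at-risk general population is three orders of
  magnitude larger than the IBD cohort.
- **Diagnosis** requires a completed new-patient visit *and* a served
  diagnostic procedure in the same week, plus a per-visit diagnosis
  probability; supply shortages therefore lengthen time to diagnosis.
  Attendees who are not diagnosed keep actively seeking (they retry
  attendance weekly).
- **Scheduled events** (continuous-care visits per severity, monitoring
  procedures per severity, biologic refills every 8 weeks — the maintenance
  cadence of vedolizumab) run on per-agent cycle timers with normal jitter
  (SD 1 week, rounded, floor 1) so the population does not pulse in
  lockstep.
- **Deferral semantics.** An event that fails its attendance draw under a
  reduced demand multiplier is recorded as *deferred* and postponed by a
  full cycle — the patient skips the appointment but keeps their rhythm.
  This makes the served rate of a scheduled channel track its demand
  multiplier one-for-one in steady state. (The alternative — retry next
  week — lets queued intent fully compensate within a few weeks, which
  erases the sustained dips these multipliers exist to represent.)
  Suppressed care-seeking attempts return the agent to hazard-driven
  seeking, so new-patient dips are deepest at onset and partially refill
  from the growing symptomatic pool — a delay, not a loss.

Default pathway parameters (onset hazard 0.002/wk per at-risk agent, growth
1.08/yr, care seeking 0.25/wk, diagnosis probability 0.8/visit, visit
intervals 12/6 weeks by severity, procedure intervals 52/26 weeks, biologic
interval 8 weeks, initiation 0.004/wk, progression 0.001/wk) are documented
order-of-magnitude defaults intended as *calibration starting points*, not
as published facts.

## 3. Supply, backlog, and oscillation

Each service (outpatient visits, procedures, biologic dispensing) has a
weekly capacity scaled by the scenario's supply multiplier. Fresh demand is
served first; a fraction `backlog_service_rate` of the queued backlog is
admitted behind it; unserved demand and unadmitted backlog carry forward
minus an `abandonment_rate`. The queue satisfies, exactly, every week:

    cumulative demanded = cumulative served + backlog + cumulative abandoned

Continuing-care patients keep their rhythm when their demand is queued (the
queue "owns" the catch-up appointment); only diagnosis is hard-gated on
being served. `CapacityModel.for_population` sizes finite capacities at a
headroom multiple (default 1.5×) of the population's expected steady-state
demand so baseline runs are unclogged but supply shocks bite.

This structure reproduces the backlog-oscillation effect: after a deep
supply shock, releasing the backlog quickly (rate 0.9) produces a served
peak pinned at capacity followed by a trough once the queue drains, a
strictly larger post-recovery amplitude than gradual release (rate 0.1).
The effect is asserted on fixed seeds with a 5,000-agent fully diagnosed
population.

## 4. Scenarios and interventions

Scenarios are weekly multiplier tables (demand: care seeking, continuous
visits, refills; supply: the three services); 1 = no disruption.

- **Pandemic**: impact(t) = [A·c(t)/(c(t)+K) + b·1{emergency}] ·
  2^(−E(t)/τ), where c(t) is the weekly case count, K the half-saturation
  case count, A the maximal impact (separately for demand and supply), b an
  additive boost while a state of emergency is declared, and E(t) the count
  of prior weeks with nonzero raw impact. The exponential habituation term
  makes equal later waves strictly less impactful — the qualitative
  signature of observed behavior, where the first, smallest wave caused the
  largest disruption. The functional form is this package's reconstruction
  (no formula is published); its parameters are meant to be *fitted*, not
  asserted.
- **Earthquake**: an immediate step drop of `severity` on demand and supply
  with linear weekly recovery over R weeks (week k carries impact
  severity·(1 − k/R)); the summed disruption integral of this triangle is
  severity·(R+1)/2 exactly.
- **Financial crisis**: demand-side only (supply stays at 1): drop to
  1 − depth, hold, linear ramp back. Earthquake and crisis magnitudes are
  hypothetical placeholders — no historical calibration data exist for
  them — and are labelled as such in the configs.

**Interventions** close a fraction of the disruption gap on their target
channels: new = old + impact·(1 − old). The shipped catalog has six entries
(three demand-only messaging interventions at 15/40/60%, three logistics
interventions at 5/15, 40/40, 60/55% supply/demand). Composition applies
each impact to the residual gap, which is commutative and bounded: combined
restoration = 1 − Π(1 − impact_i). Whether impacts should instead scale the
disruption magnitude is ambiguous in the source material; for a single
application the two readings coincide, and the residual-gap rule is chosen
because it also defines a well-behaved composition. Per-intervention active
windows implement the timing guidance that supply-side interventions act on
the immediate fallout.

## 5. Calibration

Two phases: the pre-pandemic phase fits incidence level and growth g; the
pandemic phase holds the baseline fixed and fits the response parameters
(A_demand, A_supply, and where identifiable the habituation half-life).

The objective aggregates both series to calendar months (damping weekly
Monte-Carlo noise), drops months covered by fewer than 4 weeks (a
single-week month is one noisy draw), normalizes each channel's residuals
by the observed channel mean, and sums weighted per-channel MSEs. Channel
weights are chosen roughly inverse to observation noise: the baseline phase
leans on the patient-stock channel, because cumulative diagnoses integrate
the growth signal while averaging weekly claims noise to the percent level,
with the new-diagnosis flow as a level anchor; the pandemic phase scores
continuous-care visits (whose served rate tracks the demand multiplier
one-for-one under the skip-a-cycle deferral rule) together with biologic
refills and new diagnoses — scoring several channels with different
demand/supply sensitivities is what separates the behavioral amplitude from
the capacity amplitude. Each evaluation averages
3 seeded replicates with *common random numbers* (the same replicate seeds
at every evaluation), so the optimizer sees a smooth surface. Search is
Nelder-Mead from 5 Latin-hypercube starts inside a bound box, with clipped
out-of-bounds proposals smoothly penalized; equal-endpoint bounds pin a
parameter, and the best of all starts is returned with its optimizer trace.

**Recovery harness.** Real claims panels are proprietary, so the shipped
harness generates targets from the synthetic claims module with known
ground truth and asserts recovery — the strongest available check. Scale:
20,000 unit-weight agents (30% prevalent diagnosed, 70% at-risk reservoir),
a 5-year baseline window after a half-year burn-in (the burn-in lets the
symptomatic pool reach steady state; the harness target's starting stock is
level-matched with a ramp factor of 0.9 on the burn-in onset flow), a
44-week pandemic window driven by a single sustained case wave, negative-
binomial observation noise at the generator's default dispersion of 10.
The acceptance suite asserts growth-factor recovery within 2% relative and
demand-impact recovery within ±0.1 absolute at fixed seeds. Identifiability
is respected, not papered over: with no emergency declared the boost
parameter is reported unidentifiable; a single wave identifies the
habituation half-life only weakly (pinned in the harness fit); and because
the harness target is a purely behavioral disruption in which served
volumes never reach capacity, the supply amplitude carries no signal and is
pinned at zero — left free, it opens a flat ridge where reduced attendance
and reduced capacity explain the same served dip, degrading the
demand-amplitude estimate. The phase-1 (incidence level, growth) pair is
itself a ridge: level errors of a few percent at the projection horizon
propagate into phase 2, which the multi-channel objective tolerates.

## 6. Synthetic claims generator

Weekly channel means: new(w) = B·g^(w/52)·(1 − dip); total(w) = T₀ +
cumulative new (stock-flow consistent, as a claims panel would be); visits,
procedures and biologics are the stock divided by their intervals, biologics
carrying a configurable share of the stock. Disruptions are trapezoids
(onset, full-depth duration, linear recovery) per channel, an optional
second wave scaled by a ratio in [0, 1], and an optional transient biologic
*rise* before its dip — the stock-up pattern seen in regional supply chains.
Observation noise is negative-binomial (variance μ + μ²/k, default
dispersion k = 10, overdispersed as claims counts are); the stock channel
accumulates the sampled flow rather than being noised independently. The
Tokyo-like and Hokkaido-like fixture presets differ in scale, in recovery
(the regional preset starts later and recovers more slowly), and in the
biologic transient. Monte-Carlo replicate means converge on the analytic
curves (checked at 600 replicates).

What the generator does *not* emulate: seasonality, reporting lags,
patient-level records, surgery channels, or differentiated pre-biologic
drug classes. Passing recovery tests therefore demonstrate that the
machinery can invert data generated by this family of curves — not fidelity
to any particular real claims panel.

## 7. Reproducibility and problem sizes

Every stochastic entry point takes an explicit seed; one PCG64 generator
per run is derived via `SeedSequence`, draws are made in a fixed per-week
block order over a fixed agent ordering, and ensemble replicate r uses
seed base+r — identical inputs give bitwise-identical outputs. The scalar
single-agent kernel and the vectorized engine are held to *identical*
output under shared draws and unlimited capacity by a dedicated test.

Shipped problem sizes: regional populations use 100,000 agents (totals and
shares are exact at any agent count; only age-sampling noise scales with
it); the recovery harness uses 20,000 agents; the desk-scale crisis suite
runs 3 scenarios × 2 regions × 5 replicates at 2,000 agents over 104 weeks,
exercising the identical code path as the full 3 × 2 × 300 = 1,800-run
study configuration, which is enumerated (and its manifest verified)
without being executed in the test suite. Ensemble summaries report
min/Q1/median/Q3/max of raw weekly counts (no smoothing).

## 8. Known limitations

- Truncated-normal age models cannot honor every published cell SD (see §1);
  means are exact, clipped SDs are reported.
- No mortality, remission exit, emigration, or aging within the ≤3-year
  horizon; no surgery channel; pre-biologic therapy is a single class.
- The pandemic response form is a reconstruction; only its fitted behavior,
  not its algebraic form, is anchored to data.
- Demand/supply multipliers act uniformly within a channel; there is no
  hospital-level geography or patient heterogeneity in disruption response
  beyond the care-seeking propensity scalar.
- The simulator takes epidemic wave series as exogenous inputs and never
  forecasts epidemic prevalence.
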