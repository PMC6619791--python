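# Methods

## Model

An ED visit is a realization of a multistate process on seven states with
six permitted transitions: competing exits from Registration (to Left,
Redirect, or Exam Room) followed by the deterministic sequence Exam Room →
First Contact → Disposition → Departure. States Left, Redirect and Departure
are absorbing. All times are hours since registration on a single forward
clock (clock-forward convention), so later transitions are subject to
delayed entry (left truncation): a visit contributes to the Contact →
Disposition risk set only from its own first-contact time onward.

Each transition has a cause-specific proportional-hazards intensity
λ_qr(t | Z) = λ_qr,0(t) exp(β_qr′ Z(t)). Covariates are age (years, linear),
gender, ethnicity, race, ESI acuity (5 levels, 1 most urgent), season,
time-of-day block at registration, and the number of ED physicians on staff
at registration (linear). Season, time of day and the physician count are
frozen at registration. Acuity is time-varying through a single optional
revision at triage; it enters purely by splitting the at-risk interval at
the triage time (no functional-form time interactions in the fitted model).

## Data preparation

Validation is rule-explicit: every exclusion is counted and attributed
(unparseable fields, unknown category levels, incomplete covariates, missing
or duplicate terminal outcomes, inconsistent path times, reversed
orderings). Exactly tied consecutive timestamps (e.g. room time equal to
contact time) are not unambiguously invalid, so the default policy shifts
the later stamp forward by ε = 1e-6 h with a warning; a strict mode excludes
instead. A triage stamp after the exit from Registration cannot carry an
acuity revision, so the revision is dropped with a warning and the visit
kept. Validation is idempotent.

Expansion to counting-process form follows the standard event-history
layout: per visit, one row per transition at risk with (Tstart, Tstop,
status]. The three competing Registration rows share an identical span with
status 1 only on the realized exit; an acuity revision splits each
Registration row at the triage time, the first segment carrying the initial
ESI with status 0. Row-count law: 6 rows for a departure path, 3 for
Left/Redirect, +3 for a revision.

Categoricals are indicator-coded against fixed references (Male, Not
Hispanic, White, ESI 1, Spring, 0:00–4:00). A level with zero events on a
transition has a non-estimable contrast (monotone partial likelihood), so it
is merged into the baseline group — or into the level its merge map
designates (ESI 1 merges with ESI 2, preserving the ordinal adjacency) —
with a logged notice. The merge is decided per transition from the observed
events, which reproduces the known ESI 1+2 baseline on the two transitions
where no ESI-1 visit ever exits (Left, Redirect).

## Estimation

The partial likelihood for (start, stop] data defines the risk set at event
time t as {rows: Tstart < t ≤ Tstop}. Ties use the Efron approximation by
default (Breslow optional); with no ties the two coincide. Newton–Raphson
with step-halving runs to a gradient-sup-norm tolerance of 1e-8 (maximum 50
iterations, error with the iteration trace on failure), with an additional
stop when the step or log-likelihood change reaches the floating-point
floor. Continuous covariates are rescaled to unit variance internally for
conditioning and back-transformed on output (the partial likelihood is
centering-invariant, so no centering is applied). Constant or collinear
design columns are rejected by name before iteration. The baseline
cumulative hazard is the Breslow step-function estimator, with the
tie-matched Efron correction Σ_l 1/(S0 − (l/d)D0) at tied times; at β = 0 it
reduces exactly to Nelson–Aalen.

Risk-set sums are computed by sorted cumulative sums evaluated at event
times (O((n+k) log n) per Newton iteration), which is what makes the
simulation suite and 20k-visit runs cheap on one core.

## Diagnostics

Three complementary proportional-hazards checks per transition:

* the headline global test is a likelihood-ratio test of the model augmented
  with covariate × log(t) interactions against the base model (the
  interaction model is genuinely time-varying, evaluated risk-set by
  risk-set, not a row-split approximation);
* a Grambsch–Therneau-type score test on the scaled Schoenfeld residuals
  with the log-time transform, as a cross-check;
* log(−log S(t)) versus log t curves per level of a chosen categorical
  covariate from a stratified refit (shared coefficients, per-level
  baselines); under proportional hazards the curves are vertically parallel
  with offset equal to the log hazard ratio.

Simulated at n = 1000 per replicate, the LR test's null rejection rate at
α = 0.05 is ≈5% (measured 4.5% over 400 dev replicates); the calibration
experiment in the acceptance suite uses 200 replicates at that size.

## Prediction

Conditional cumulative hazards accumulate baseline increments scaled by
exp(β̂′z(u)), with z(u) read from the (possibly piecewise-in-time) profile
at each event time. The Aalen-Johansen product integral multiplies
(I + ΔA(u)) over the union grid of all six transitions' event times;
Chapman–Kolmogorov holds exactly on the grid by associativity. For
prediction the profile's ESI is held fixed (matching per-acuity panel
displays). Expected sojourn times integrate the right-continuous occupation
step functions exactly; the horizon τ defaults to the last event time of the
grid, and the sojourns always partition [0, τ].

Numerical guardrails in the product integral: a diagonal of I + ΔA below
zero is floored at zero with the off-diagonals rescaled to keep the row
stochastic (logged). An off-diagonal increment above 1 is invalid and raises
by default; `increment_policy="clip"` (used by the high-level estimator)
clips it to 1 with a warning, because conditional increments exceed 1
generically at the last few event times when the profile's hazard ratio is
above 1 and the risk set has shrunk to a handful of rows — a region where
occupancy of the source state is already negligible, so clipping has no
visible effect on the curves.

## Synthetic cohort generator

The generator draws visits from exactly the process the model assumes:
covariates from configurable category frequencies, competing latent exit
times from Registration under proportional hazards (minimum wins; equivalent
to cause-specific hazards), then sequential in-room sojourns with delayed
entry. Acuity revisions make the Registration-exit multipliers piecewise in
time, exercising the time-varying path end to end. Baselines are constant
or Weibull; deliberate PH violations for power studies are generated with
piecewise effects. Three named random substreams (covariates, acuity,
times) keep time draws stable under covariate-model changes; a config plus
seed determines the cohort byte-for-byte.

Default conditions were calibrated once, at design time, to the modelled
population: the emulated cohort's demographic frequencies (51.5% male, 91.2% not
Hispanic, 48.0% White, ESI mass on levels 2–5, ~21.6% summer arrivals),
lognormal age (median 5 y, IQR ≈ 2–12), per-block physician medians
(7/3/5/6/8/8 across the six time-of-day blocks, ±1 jitter), published
hazard-ratio effects on the two Registration transitions and
direction-consistent effects on the in-room transitions, and constant
baseline rates chosen so the simulated cohort reproduces the marginal
outcome split (≈94.4 / 4.6 / 1.0 %) and mean stage waits (≈1.06 / 0.5 / 1.4
/ 1.2 h). An optional administrative cut-off drops visits still in the ED
at that time, emulating a complete-followup registry; by default no visit
is censored, as in a registry covering every completed visit.

What the generator does *not* emulate: queueing/server dynamics (physician
counts are covariates, not resources), arrival-process structure, day-to-day
volume correlation, measurement error in timestamps, or informative missing
data. Passing tests therefore demonstrate correctness of the estimators
under the model's own assumptions, not robustness to real-world recording
artifacts.

## Problem sizes

The test suite fits cohorts of 1,200–3,000 visits for unit checks; the
statistical acceptance checks use 20 replicates of 10,000 visits for
coefficient recovery (|β̂ − β| < 3·SE for ≥95% of 240 coefficients), a
20,000-visit constant-hazard cohort for the Aalen-Johansen versus
matrix-exponential comparison (sup error < 2/√n), and 200 replicates of
n = 1000 for PH-test calibration. The acceptance script mirrors these sizes.

## Known limitations

* No confidence bands for transition/occupation probabilities or sojourn
  times; hazard-ratio inference is Wald-based, unadjusted for multiplicity
  (per-covariate p-values are reported as-is).
* Markov (clock-forward) prediction only; no clock-reset (semi-Markov)
  variant.
* The Efron-corrected baseline uses the event-time Schoenfeld layout without
  a tie correction inside the residual series itself; residual-based
  diagnostics at heavily tied times are approximate.
* Zero-event level merging is automatic; with very sparse transitions the
  merged baseline group can grow large, changing the interpretation of the
  remaining contrasts (each merge is logged).
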