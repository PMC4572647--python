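# Methods

`clinicflow` models the weekday operation of a women's-health (OB/GYN)
outpatient clinic and searches its appointment template and nurse staffing
for the configuration minimizing patients' total waiting time.  This note
records the model, its parameters and defaults, the synthetic-data design,
and the judgement calls made where the clinic's internal flow is not fully
determined by public information.

## The clinic model

Patients are scheduled on a per-provider template: 16 morning patients
(5 new) from 7:45 with the last four classes continuing the printed column
order, and 12 afternoon patients (2 new) from 12:45.  The *baseline*
template contains double bookings (two patients at one clock time); the
*modified* template splits every double into single slots spaced `t_am`
(morning) and `t_pm` (afternoon) minutes apart, preserving the class mix.
Two same-day slots close the afternoon and resolve 50/50 to return-OB or
return-GYN at simulation time.

The weekly roster runs two full-day providers on Monday, Tuesday, and
Friday; Thursday combines one full-day provider with one AM-only and one
PM-only provider; Wednesday runs two PM half-days (hence 56 scheduled
patients on the four full days and 24 on Wednesday).  Show-up probabilities
are provider-, day-, and kind-specific (0.50–1.00); the mapping of printed
values to weekdays follows each provider's working days in roster order and
every cell is overridable in the scenario file.

Arrivals are `appointment + Normal(0, 7 min)`, minus 15 min for new
patients (paperwork), clamped at the 7:30 opening.  Lab routing is drawn
per patient: 100 % of new OB, 30 % of return OB, 60 % of new/return GYN.

A day is a queueing network with single check-in and check-out desks (one
access coordinator each), seven single-capacity exam rooms shared across
providers, an RN+LPN escort pool, one single-capacity lab room, and a pool
of medical assistants (MAs):

1. check-in (service law by patient kind);
2. waiting room; escort starts when an exam room **and** an escorting staff
   member are simultaneously free, in appointment order (ties by arrival,
   then id); lowest-numbered free room is taken;
3. escort + vitals by an RN/LPN (the MA escorts only if no RN/LPN is free);
4. the patient holds the room while waiting for *her own* provider and
   through the visit; the room is released when the provider finishes;
5. lab, if routed: requires the lab room and an MA; shared FIFO queue with
   the internal-medicine load; after the patient leaves, the MA remains
   busy for a specimen-processing time;
6. check-out.  The day runs until the last patient departs; departures
   after 17:00 are overtime, recorded rather than truncated.

Service times follow the fitted location-shifted laws packaged in
`data/service_time_distributions.csv` (triangular, 3-parameter Weibull /
gamma / Erlang / log-normal / log-logistic, 4-parameter Pearson-6 and
beta); raw second-scale parameters are divided by 60.  All 18 unique laws
have means between 1 and 30 minutes.

Providers see patients only from their session start (7:45 AM-session,
12:45 PM-only).  Staff utilization is patient-contact time over scheduled
minutes (570 for a full day, 330 AM-only, 255 PM-only); room and lab
utilization divide occupied time by the 570-minute clinic day.  Throughput
counts patients fully checked out by 17:00 (13:00 for an AM-only
provider's list).

### Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| `x1`, `x2`, `x3` | 2 LPN, 1 RN, 1 MA | head-count | current staffing |
| `t_am`, `t_pm` | — (modified template only) | min | search variables, 10–16 / 10–21 |
| exam rooms / lab rooms | 7 / 1 | rooms | clinic layout |
| arrival jitter SD | 7 | min | punctuality estimated from tracker data |
| new-patient early arrival | 15 | min | front-desk instruction |
| `im_lab_rate_per_hour` | 2.0 | visits/h | internal-medicine background lab load |
| `im_new_frac` | 0.5 | — | share of new-patient lab laws in that load |
| `lab_processing` | Triangular(2, 4, 6) | min | MA specimen handling per draw |

The internal-medicine clinic itself is out of scope; its only coupling to
the OB/GYN flow is the shared lab, so it is reduced to a Poisson stream of
lab visits.  The default rate (2/h over the day, ~19 visits) was chosen
once so that total lab-room utilization is moderate (~0.6), matching a lab
that is busy but not the system bottleneck; it is a free scenario
parameter.

The MA specimen-processing stage deserves a note.  If the MA's only duty
were serving patients inside the single-capacity lab room, MA head-count
could never affect performance — lab throughput would be capped by the
room, and one MA would always suffice.  That contradicts the observation
motivating the staffing search: adding one MA measurably reduces total
waits because lab work (labelling, logging, hand-off) exceeds patient
face time.  The processing stage represents exactly that excess: it
occupies the MA after the room frees, so a single MA saturates under the
combined OB/GYN + IM load while a second MA restores lab flow.  The
default of 2–6 minutes per specimen is a realism judgement, set once;
processing time counts toward MA workload but not toward the
(face-to-face) utilization statistic.

### Patient-tracker log

The synthetic patient-tracker (PT) log is the study's observable: one CSV
row per arrived patient with milestone stamps `check_in_start, check_in,
escorted, vitals_done, provider_in, provider_out, lab_in, lab_out,
check_out, check_out_done` (UTF-8, header row, minutes past midnight as
decimals, empty cell = milestone did not occur).  `check_in` is stamped
when check-in processing *finishes* and `check_out` when the patient
reaches the check-out desk, so consecutive stamps of different stations
bracket pure waits, each staff role's service is bracketed by two stamps,
and total spent time is `check_out − check_in`.  Extractors recover
service-time samples per role, per-patient waits (exam-room wait for the
provider WT, total wait TWT, total spent TST), and show-up ratios.

What the generator emulates: milestone timestamps, no-shows, punctuality
jitter, lab routing, and class mix, with realistic congestion produced by
the engine rather than drawn independently.  What it does not emulate:
data-entry noise, missing or mis-ordered stamps, walk-ins beyond the
same-day slots, staff breaks, or the ultrasound visit itself (only its
arrival-time consequence).  Tests passing on this log therefore validate
the pipeline's arithmetic and the model's internal consistency, not the
fidelity of any real clinic's records.

### Distribution fitting

Fitting is maximum likelihood with the location profiled on a 16-point
grid strictly below the sample minimum (plus one local refinement pass);
the boundary `location → min(sample)` is the classic pathology of shifted
laws and is excluded by construction.  Goodness of fit is screened with
Kolmogorov–Smirnov and Anderson–Darling p-values computed *as if the
fitted parameters were known* (the AD tail uses the Marsaglia & Marsaglia
short-series approximation of the parameter-free asymptotic law).  This
inflates p-values relative to estimated-parameter corrections; it mirrors
screening practice and is documented on the API.  Candidate families are
ranked by the average of the two p-values, ties broken by log-likelihood.

## Performance measures and comparisons

WT is the exam-room wait for the provider (`provider_in − vitals_done`);
TWT adds the waiting-room, lab-queue, and pre-check-out waits; TST is
check-in to check-out.  Waiting-room time is decomposed exactly into
room-blocked minutes (no exam room free) and staff-blocked minutes (room
free, no escorting staff free) — at every instant a waiting patient is in
one of the two states.  Scenario comparisons use Welch two-sample t tests
on replication means; validation against observed values uses a one-sample
t test of replication means.  The "Overall" row of a comparison table is
the unweighted mean of per-key means, and the overall improvement is the
unweighted mean of per-key improvement percentages — *not* the improvement
of the pooled means.

Thirty replications is the default reporting sample size (large enough for
the replication-mean CLT that the t tests rely on).

## Optimization

The search minimizes the patient-weighted mean TWT pooled over
Mon/Tue/Thu/Fri (Wednesday's half load is excluded) over
`x1, x2, x3 ∈ {1..4}`, `t_am ∈ {10..16}`, `t_pm ∈ {10..21}` — 5,376
integer points — subject to the clinic closing on time.

*Deadline rule.*  The closing constraint is evaluated per weekday as
`E[last check-out] ≤ 17:00` (the `mean` rule).  A strict
every-replication rule and a quantile rule are implemented, but under the
heavy-tailed fitted laws the strict rule is violated occasionally at any
afternoon spacing wide enough to matter, which contradicts the observed
operating point and the clinic's tolerance of occasional overtime; the
expectation rule is the default.

*Variance reduction.*  All configurations share per-replication random
streams (common random numbers): every slot consumes the same draws
whether or not the patient shows, so configuration differences are not
masked by sampling noise.  Because RNs and LPNs form one interchangeable
escort pool, outcomes depend on `x1 + x2` only, and grid evaluations are
cached on `(x1 + x2, x3, t_am, t_pm)` — an exact reduction of the grid
from 5,376 to 2,352 simulations.

*Two-stage selection.*  After the sweep at a small replication count
(default 5), the leading feasible points *and* any borderline-infeasible
points — those whose worst-day mean close-out is within its 95 % CI of the
deadline — are re-evaluated at six times the replications before the
final argmin (at most one borderline candidate per spacing pair, since the
deadline verdict is driven by the spacings).  Without the re-screening, feasibility noise at 5
replications systematically truncates the afternoon spacing.  Ties prefer
fewer staff, then lexicographic order, so a reported optimum of
`(x1, x2) = (1, 2)` is the same operating point as `(2, 1)`.

The evolutionary strategy (integer GA: population 24, tournament size 3,
uniform crossover, reset mutation at rate 0.2, elitism 2, overtime-penalized
infeasibility) shares the cached evaluator and is cross-checked against the
exhaustive grid on small spaces.

## Numerical choices and degenerate inputs

* Seeds: replication r, weekday d uses
  `SeedSequence(base_seed, spawn_key=(r, day_index, k))`, k = 0 for the
  patient stream, 1 for the background lab stream.
* Degenerate triangular laws (min = mode = max) are deterministic service
  times, used by the hand-computed oracles.
* Early arrivals before 7:30 are clamped to opening; a zero-variance
  sample refuses to fit; fewer than 30 observations refuse to fit.
* Event ties are resolved by insertion order (a monotone sequence number),
  making every run reproducible.
* Lab-before-provider routing is not implemented (the flow models
  lab-after-provider; the configuration flag exists and rejects the
  unimplemented value explicitly).

## Problem sizes used in the shipped analyses

The packaged acceptance analysis runs the exhaustive grid at 5
replications per configuration (with the two-stage re-screening above),
estimates the lab-routing percentage from 20,000 routing draws, and the
arrival-jitter SD from 50,000 arrivals.  The validation-style experiments
use 30-replication samples against reference values taken from 200
independent replications.

## Known limitations

* The engine's flow details (escort discipline, shared room pool, room
  held through the provider visit, dedicated check-in/check-out desks) are
  deliberate choices where the source system is under-documented; absolute
  simulated wait times therefore carry model risk, and analyses emphasize
  comparisons, decompositions, and trends rather than absolute levels.
* KS/AD p-values use the parameters-known approximation (screening only).
* No staff breaks, chaperoning (rate defaults to zero), walk-ins,
  rescheduling, or multi-day carryover.
* The ultrasound station is not simulated; its effect is already folded
  into the arrival-time model.
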