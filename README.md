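# clinicflow

Discrete-event simulation and appointment-template optimization for an
OB/GYN outpatient clinic.

## The problem

A women's-health clinic schedules 56 patients across two providers on full
weekdays (16 per provider in the morning, 12 in the afternoon, with several
double-booked slots) and suffers long patient waits that peak around noon
and mid-afternoon.  Management wants to know which *cheap* levers actually
reduce waiting: the spacing between appointments, or the number of nurses
(LPNs, RNs) and medical assistants (MAs)?

`clinicflow` is for operations analysts asking that kind of question.  It

* fits **location-shifted service-time distributions** (3-parameter
  Weibull, gamma, Erlang, log-normal, log-logistic; 4-parameter Pearson-6
  and beta) to patient-tracker milestone logs, with KS/AD screening and
  ranking;
* **synthesizes patient-tracker logs** — per-patient milestone timestamps
  from check-in to check-out — as the study's observable data;
* runs a **process-level discrete-event simulation** of one clinic day:
  scheduled arrivals with no-shows and Normal(0, 7 min) punctuality jitter,
  check-in, nurse escort + vitals into one of seven shared exam rooms, the
  provider visit, a single shared lab (with a background internal-medicine
  load), and check-out;
* computes the study's **micro and macro measures** — WT (exam-room wait
  for the provider), TWT (total wait across locations), TST (total time in
  clinic), throughput 𝒯, staff/room utilizations, wait-cause
  decomposition, and time-of-day curves — with replication statistics,
  Welch comparisons, and validation tests;
* solves the **constrained simulation-optimization problem**

  minimize TWT  subject to  1 ≤ x₁,x₂,x₃ ≤ 4, 10 ≤ t_am ≤ 16,
  10 ≤ t_pm ≤ 21, and all patients checked out by 5 pm,

  where x₁/x₂/x₃ are LPN/RN/MA counts and t_am/t_pm the slot spacings of
  the de-double-booked template — by exhaustive grid search with common
  random numbers (or an evolutionary search), with two-stage re-screening
  of the deadline constraint.

## Worked example

Compare the current template and staffing against the modified template
with 16-minute morning slots, 19-minute afternoon slots, and one added MA:

```python
import dataclasses
import clinicflow as cf
from clinicflow import engine, metrics

baseline = cf.ScenarioConfig()            # current template, 2 LPN / 1 RN / 1 MA
best = dataclasses.replace(baseline, template_kind="modified",
                           t_am=16.0, t_pm=19.0, x3=2)

base_reps = engine.run_replications(baseline, n_reps=30, base_seed=7)
best_reps = engine.run_replications(best, n_reps=30, base_seed=7)

res = metrics.compare_scenarios(
    {m: [getattr(r, m) for r in base_reps] for m in ("wt", "twt", "tst")},
    {m: [getattr(r, m) for r in best_reps] for m in ("wt", "twt", "tst")},
)
print(res.round())
```

```
         baseline   best  improvement_pct             p
wt          13.49   7.15            46.98  2.652283e-15
twt         39.11  15.37            60.69  9.400454e-16
tst         65.77  42.04            36.08  3.743622e-15
Overall     39.46  21.52            47.92  0.000000e+00
```

Each row is a performance measure in minutes, averaged over 30 paired
replications of the four full clinic days: the average exam-room wait for
the provider (`wt`) drops from 13.5 to 7.2 min, the average total wait
(`twt`) from 39.1 to 15.4 min, and the average total visit (`tst`) from
65.8 to 42.0 min; the Welch p-values show the improvements are far beyond
replication noise.  The `Overall` row aggregates the per-measure
improvements by their unweighted mean.

The same machinery is scriptable from the shell:

```bash
clinicflow tracker generate --days 20 --seed 1 --out log.csv
clinicflow tracker fit --log log.csv --role nurse --kind new
clinicflow simulate --day Mon --reps 30 --seed 1 --out-metrics mon.csv
clinicflow optimize --strategy grid --reps 5 --seed 1 --out result.json
```

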