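# edflow

Multistate survival modelling of patient flow through a pediatric emergency
department (ED).

## The problem

An ED visit is a sequence of timed milestones: a patient registers, is
(eventually) placed in an exam room, first sees a physician, receives a
disposition decision, and departs — or instead leaves without being seen, or
is redirected elsewhere straight from the waiting room. Modelling only the
total length of stay hides *where* time is lost and cannot handle patients
who leave before being seen. `edflow` treats the visit as a **multistate
process** on seven states and six transitions,

```
1 Registration ──► 2 Left (without being seen)
              ──► 3 Redirect
              ──► 4 Exam Room ──► 5 First Contact ──► 6 Disposition ──► 7 Departure
```

with all clocks measured in hours since registration (clock-forward).

Each transition q→r gets its own Cox proportional-hazards model on
counting-process data,

λ_qr(t | Z) = λ_qr,0(t) · exp(β_qr′ Z(t)),

fit by maximizing the partial likelihood with **delayed entry** (a visit
enters the Room→Contact risk set only at its room time) and Efron handling of
tied event times. Acuity (ESI, 1 = most urgent) is **time-varying**: an
update at triage splits each at-risk interval at the triage time. From the
fitted cumulative hazards Λ̂_qr(t | Z) the **Aalen-Johansen product
integral**

P(s, t | Z) = ∏_{u ∈ (s,t]} ( I + dA(u | Z) )

yields the transition-probability matrices, the state occupation
probabilities p(t) = e₁′P(0, t), and expected sojourn times (expected length
of stay per state) ∫₀^τ p_k(t) dt.

The package is aimed at biostatisticians and ED operations researchers who
want per-transition covariate effects (acuity, season, time of day, staffing,
demographics) and covariate-conditional flow predictions, plus a fully
synthetic cohort generator so every stage is testable without patient data.

## Worked example

```python
from edflow import MultistateCox, expand_to_long, sample_cohort, SimulationConfig
from edflow import summarize_dataset

# synthetic cohort under the default study-like conditions
records = sample_cohort(SimulationConfig(n=20_000, seed=7))
s = summarize_dataset(records)
print({k: round(v, 2) for k, v in s.outcome_pct.items()})
print({k: round(v, 3) for k, v in s.mean_waits_hours.items()})

model = MultistateCox().fit(expand_to_long(records))
profile = {"age": 1, "gender": "Male", "ethnicity": "Not Hispanic",
           "race": "White", "time_of_day": "16:00-20:00", "season": "Winter",
           "n_physicians": 8, "esi": 3}
print(model.expected_sojourn(profile)[["label", "sojourn_minutes"]].round(1))
```

prints

```
{'departure': 94.42, 'left': 4.57, 'redirect': 1.0}
{'registration_to_room': 1.044, 'room_to_contact': 0.503,
 'contact_to_disposition': 1.364, 'disposition_to_departure': 1.208}
```

— 94.4% of visits end in a physician-attended discharge, 4.6% leave without
being seen, 1.0% are redirected, and the mean stage waits are ≈1.04 h
(registration→room), 0.50 h, 1.36 h and 1.21 h — followed by the
ESI-3-conditional expected minutes spent in each state (the sojourn table),
e.g. how long a 1-year-old male patient arriving on a winter evening with
8 physicians on staff is expected to spend waiting for a room versus waiting
for a disposition.

A command-line interface wraps the same pipeline:

```bash
edflow simulate --n 5000 --seed 1 --out visits.csv
edflow validate --input visits.csv
edflow fit --input visits.csv --outdir out/          # 6 hazard-ratio tables
edflow run --config run.yaml                         # validate → … → predict
```

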