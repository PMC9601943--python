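# Methods

## The simulated emergency department

`edsurrogate.simulate` implements a process-interaction discrete-event
model of a 24/7 ED, executed on a binary-heap event queue with an internal
clock in minutes.  Each simulated day is an independent 24 h replication
that starts empty; patients still in the system at the day boundary are
neither completed nor balked and are excluded from the waiting-time
dataset.  The two outputs are

- `pnt` — patients completing check-out within the day, and
- `wt` — per-patient total waiting time in hours: the waiting-room dwell
  plus every queueing delay (stage start minus ready time), with service
  times excluded.

### Patient flow and service processes

| stage | resources | duration (min) |
|---|---|---|
| waiting-room dwell | seat | Triangular(min 0, max 100.8, mode 10.8) (= 0–1.68 h, mode 0.18 h) |
| check-in | clerk | Uniform(3, 5) |
| triage | nurse + triage area | Triangular(3, 15, 5) |
| bed preparation | nurse + bed | Triangular(3, 15, 5) |
| physician exam | physician + bed | Uniform(10, 30) |
| extra nurse operations (p = 0.5) | nurse + bed | Triangular(3, 15, 5) |
| check-out | clerk | Uniform(3, 5) |

Triangular triples are read as (min, max, mode), the convention of the
commercial healthcare-simulation tools this model mirrors.  The
waiting-room triple is given in hours and is modelled as a dwell every
admitted patient spends before joining the check-in queue; it is counted
as waiting time.  This is the only reading under which realistic mean
waits (~0.6 h) arise at the fully staffed reference configuration, where
queueing delays alone are minutes.  The probability of needing extra
nurse operations is 0.5 by default (configurable): roughly half of ED
patients need injections, serum or similar follow-up work.

Queues are FIFO per stage; a stage starts only when every required
resource is simultaneously free, and the dispatcher scans stages
downstream-first so patients already in flow reclaim shared resources
(beds, nurses) before newly arriving ones — this avoids starving mid-flow
patients when beds are scarce.  A patient occupies a waiting-room seat
whenever they are not in service; an arrival finding all 50 seats taken
balks: it is counted, recorded, and excluded from both `pnt` and the
`wt` dataset.

### Arrivals and calibration

The default arrival process is homogeneous Poisson at 3.0 patients/hour.
The rate is the one calibrated constant of the model: it makes the
reference staffing (3 physicians, 3 nurses, 2 clerks, 5 beds, 2 triage
areas) treat ≈ 68.6 patients/day with a mean wait of ≈ 0.6 h, the
operating point of the ED the model emulates.  An alternative
"triangular" arrival mode draws i.i.d. interarrival gaps from
Triangular(0, 0.18, 1.68) h for users who prefer the literal
interarrival reading of that triple; its mean gap (0.62 h ≈ 38.7
patients/day) is inconsistent with the ≈ 68.6/day operating point, which
is why it is not the default.

### Seeding and common random numbers

All randomness flows from numpy `SeedSequence`s.  Every patient's dwell,
stage durations and extra-operations coin are pre-drawn from a
patient-indexed stream at arrival, and replicate day *r* of every scenario
shares the same day stream.  Consequences: (i) runs are bit-reproducible;
(ii) scenarios are compared under common random numbers, so adding a
resource unit can only shorten queues day by day — the paired
monotonicity tests exploit this; (iii) the within-scenario variance of the
campaign reduces to a single shared "day effect" (the difference between
the global day streams), so the achievable training R² of any surrogate —
bounded by 1 − SS_within/SS_total because replicate days have identical
features — fluctuates with the base seed.  At the default test seed the
best surrogate reaches training R² ≈ 0.97 (`pnt`) / 0.94 (`wt`); seeds
whose day streams differ more can drop this bound to ≈ 0.7–0.85.

### What the generator does and does not emulate

The simulator reproduces the emulated ED's operating point (≈ 68.6
treated/day, mean wait ≈ 0.6 h at reference staffing), its resource
structure and its service-time distributions.  It does not reproduce the
very wide scenario spread reported for the original study (daily
throughput 9–149, sd 37.5): with ≈ 69 arrivals/day and every
configuration retaining ≥ ~46 patients/day of service capacity, no
queueing reading of the published service times can produce 9 treated
patients per day.  Campaign-level spreads here are narrower (roughly
39–75/day), driven mostly by bed and physician contention.  Tests passing
on this generator therefore validate the mechanics and the analysis
pipeline, not the original study's exact output distribution; conclusions
about a real ED require recalibration to that ED's data.

## Scenario design and cost model

`build_grid` enumerates the full factorial over the resource levels
(3·3·2·3·2 = 108 scenarios, lexicographic, 2 replicates → 216 balanced
rows; every input column then has the textbook summary statistics, e.g.
sd 0.818 for three-level factors).  `escalate_coefficients` applies the
cost recursion cost_k = cost_{k−1}(1 + p_k) per resource with p = (0.20,
0.30, 0.50); coefficients are kept unrounded internally and reported
half-up at 2 decimals.  A scenario's cost at a level is the
count-weighted coefficient sum (`scenario_cost`), and `cost_benefit`
forms throughput-scaled cost (Σpnt · cost), waiting-scaled cost
(Σ(wt/pnt) · cost) and the net position against a configurable
`revenue_per_patient` (default 1.0 cost-units, so breakeven analysis is
expressible without a currency); days with zero throughput make the
waiting term undefined and are flagged rather than imputed.

## Surrogate models and evaluation

`SurrogateModel(data, target).fit(seed)` fits three regressors with the
study's hyperparameters: random forest (500 trees by default within the
studied 10–2000 range, 5 candidate features per split), gradient boosting
(3 trees, learning rate 0.1, depth 3, min-split 2, full subsample — an
intentionally weak published setting that underfits), and AdaBoost.R2 (50
depth-3 trees, learning rate 1.0, linear loss).  `pnt` predictions are
rounded to integers on output.  Evaluation is a single 85/15 random split
plus shuffled (unstratified — the targets are continuous) 10-fold
cross-validation; rows are sorted canonically before splitting so the
partition depends on the seed, not the caller's row order.  Metrics are
MSE, RMSE, MAE and R² = 1 − SS_res/SS_tot; a printed source formula for
the correlation-style accuracy is not a valid definition, so the standard
coefficient of determination is used, matching the 0–1 accuracy scale of
the reported tables.  R² is flagged not-computable on constant targets.

Cost levels enter the feature set as the scenario cost at one δ level
(`attach_cost_feature`), one model set per level.  Because every level
scales all coefficients by a common multiplier, the cost feature is a
monotone rescaling across levels and tree-based fits are identical up to
estimator randomness; the per-level view exercises the reporting
structure rather than changing the physics.

### SAMME and SAMME.R

`edsurrogate.boosting` implements both multi-class AdaBoost variants
directly from their pseudocode, with depth-1 `DecisionTreeClassifier`
weak learners by default.  Numerical choices: probabilities are clipped
at 1e-10 before logs (a non-finite log still raises, naming the round); a
zero-error round receives the large finite vote weight log(1e10) and
terminates boosting; a round no better than chance (err ≥ 1 − 1/K) is
discarded and boosting stops; sample weights are re-normalised to a
probability distribution every round and the full weight history is
retained for inspection.  An optional class-frequency-inverse initial
weighting is available for imbalanced classification experiments.  The
package also ships `DecisionStump`, a weighted one-split learner with
tolerance-based deterministic tie-breaking (prefer lower error by more
than 1e-12, then lower feature index, then lower threshold); it exists
because exact cross-implementation comparisons — e.g. SAMME at K = 2
against classical AdaBoost — are only meaningful when the weak learner
cannot flip between equally good splits on floating-point noise.

## Pipeline and reporting

`run_pipeline` chains campaign → cost table → descriptives/correlations →
per-level model evaluation → cost–benefit → improvement report, writing
CSVs plus a run log with stage timings and the seed; any stage failure
deletes the partial bundle and re-raises with the stage name.  The
improvement report compares, per model × δ level, the best predicted
scenario (maximum `pnt`, minimum `wt` over the design) against the
simulated current situation — the reference staffing at δ0.0, averaged
over 30 independently seeded days — as signed percentage changes.

## Known limitations

- Single-class patient population: no triage acuity classes or
  priority queueing.
- Homogeneous arrivals: no diurnal or weekly demand profile.
- Beds are released between consecutive bed stages (preparation, exam,
  extra operations); downstream-first dispatch makes a waiting mid-flow
  patient first in line to reclaim one, but brief bed handovers can occur
  that a hold-the-bed model would not show.
- The per-δ surrogate accuracies are structurally near-identical across
  levels (see above); differences reported between levels by similar
  studies cannot be attributed to the cost feature under this design.
- `revenue_per_patient` is a free scalar; absolute net positions are
  meaningful only relative to a chosen revenue scale.
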