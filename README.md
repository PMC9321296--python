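# edcast

Probabilistic short-horizon forecasting of emergency admissions from
patient-level emergency-department (ED) data.

Bed managers plan against the number of emergency admissions expected in
the next few hours, and most hospitals still forecast it with a same-weekday
rolling average. When an electronic health record streams each ED patient's
observations, locations, consults and pathology in real time, one can do
much better: score every patient currently in the department, aggregate
those probabilities into a full count distribution, and add the patients who
have not arrived yet. `edcast` implements that seven-step pipeline together
with a synthetic ED generator, so every stage is testable without access to
hospital data.

## The model

At each prediction time *t* (06:00, 12:00, 16:00, 22:00) with window *w*
(4 or 8 h):

1. **Snapshot** — take the patients present in the ED at *t*.
2. **Classify** — each patient *i* gets an admission probability
   `p_i` from a gradient-boosted classifier chosen by elapsed visit time:
   12 models T0…T720 are trained on left-aligned datasets (model T60 sees
   only visits longer than 60 min and events within 60 min of arrival), and
   at prediction time the largest cutoff not exceeding the patient's elapsed
   time picks the model, so inference rows match the training distribution.
3. **Aggregate** — the number of admissions among present patients is
   Poisson-binomial: `P(N = k)` is computed by exact convolution of the
   Bernoulli(p_i).
4. **Window** — a Cox proportional-hazards model of time-to-admission among
   admitted patients (covariates: arrival time-of-day band, weekend, quarter,
   ED occupancy at arrival) gives each patient the probability of being
   admitted *within w* conditional on admission:
   `c_i = 1 − S(e_i + w | x_i) / S(e_i | x_i)` at elapsed time `e_i`.
5. **Aggregate again** — Poisson-binomial over the products `p_i · c_i`.
6. **Not yet arrived** — a log-link Poisson regression (prediction
   time-of-day, quarter, weekend) forecasts the count of patients who will
   arrive after *t* and be admitted within *w*.
7. **Convolve** — the distributions from steps 5 and 6 are convolved into
   the final forecast, reported as a mean and a 10th–90th centile band.

Forecast calibration is checked with midpoint probability-integral
transforms (PIT) of the observed counts, and accuracy against the
operational heuristic: the six-week same-weekday rolling average of daily
admissions minus admissions already observed by 16:00.

The synthetic generator emulates the statistical structure this pipeline
relies on: diurnal nonhomogeneous Poisson arrivals, a ~20.7% admitted
fraction from a logistic model on arrival characteristics, log-normal visit
durations whose time-to-admission depends on arrival time, weekend, quarter
and ED crowding, and event streams whose density itself carries admission
signal.

## Worked example

```bash
edcast simulate --out stream --days 90 --seed 5
edcast train    --stream stream --out models
edcast predict  --stream stream --models models --at 116160 --window 8
edcast benchmark --stream stream --models models --out bench
```

prints

```
wrote 12895 visits to stream
trained on 63 days; saved to models
expected 11.2 admissions in 8h (10-90% band 8-15), 33 patients in ED
model MAE 1.81 (MPE 16%) vs benchmark MAE 4.45 (MPE 38%)
```

Timestamp 116160 is 16:00 on day 80 (minutes since the simulation start),
a held-out day. The forecast says: of the 33 patients currently in the ED
plus those yet to arrive, expect 11.2 admissions by midnight, with an 80%
central band of 8–15. Over all held-out days the pipeline's 16:00 + 8 h
forecasts have a mean absolute error of 1.81 admissions (16% of observed),
versus 4.45 (38%) for the rolling-average heuristic.

The same machinery is available as a library:

```python
from edcast import SimConfig, simulate_stream, train_pipeline, run_pipeline

stream = simulate_stream(SimConfig(horizon_days=90, seed=5))
pipe = train_pipeline(stream)
result = run_pipeline(stream, pipe, prediction_ts=80 * 1440 + 960, window_hours=8)
print(result.expected_admissions, result.band_10_90, result.step7_dist.pmf)
```

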