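# Methods

## The forecasting problem

The quantity forecast is the number of emergency admissions within a 4- or
8-hour window after one of four daily prediction times. It decomposes into
admissions among patients already in the ED at the prediction instant and
admissions among patients yet to arrive. The first part is patient-level:
each present patient contributes a Bernoulli admission-within-window event
with probability `p_i · c_i`, where `p_i` is their probability of eventual
admission and `c_i` the probability of being admitted within the window
conditional on admission. Treating these events as independent given the
probabilities, their sum is Poisson-binomial and is computed exactly by
convolution. The second part is a Poisson count. The final forecast is the
convolution of the two.

### Temporal framing

Training examples are left-aligned at ED arrival: the model with cutoff
`c ∈ {0, 15, 30, 60, 90, 120, 180, 240, 300, 360, 480, 720}` minutes is
trained on all visits lasting strictly more than `c` minutes, with features
computed only from events timestamped within `c` minutes of arrival.
Prediction rows are right-aligned at the prediction instant: each present
patient is assigned the largest cutoff not exceeding their elapsed time and
their features are computed as of arrival + assigned cutoff, which makes the
inference rows exchangeable with the assigned model's training rows. Elapsed
times beyond 720 minutes clamp to the last model. Features never use events
after min(prediction instant, arrival + cutoff), so no future information
can leak; this is asserted by a metamorphic test that perturbs post-cutoff
events and requires bit-identical feature rows.

Nine of the twelve cutoffs are the ones the operational system names
explicitly; 300, 480 and 720 complete a roughly geometric ladder and are
configurable.

### Features

Four groups, with missingness carrying meaning:

- **visit**: age band, ambulance arrival, prior admission count, arrival
  time-of-day band, weekend flag;
- **location**: current location category (one-hot over a fixed vocabulary),
  number of location changes;
- **observations and consults**: per-type counts and latest values (triage
  score, NEWS-like score, heart rate, respiratory rate), pressure-area
  checks, total recording events, distinct types, consult count;
- **pathology**: battery-ordered flags, latest values of five tests, counts
  of results above and below the reference range.

Latest-value features are missing (NaN), never zero, when no such event has
occurred; count features are zero. Tree models consume NaN natively; the
random-forest and lasso-logistic comparators impute at the training median.

### Classifiers

The default algorithm is gradient-boosted trees with a binary log-loss
objective; log loss is the tuning target because the downstream aggregation
needs accurate probabilities, not good classification. The default
hyperparameters (depth 3, learning rate 0.1, 250 rounds, subsample 0.9,
minimum child weight 5) sit at the point where held-out calibration curves
stop being shrunk toward the base rate without yet becoming over-confident;
an optional 10-fold stratified cross-validation over a small declared grid
is available, as are the comparator algorithms. The lasso-logistic
comparator fits a regularisation path and supports the minimum-CV-error
penalty plus 2/3/4-standard-error sparser choices. Probabilities are clipped
to [1e-15, 1-1e-15] before log loss. No class rebalancing is applied by
default; a `class_weight="balanced"` switch exists.

### Survival windowing

Time from arrival to admission, among admitted visits only, is modelled
with Cox proportional hazards (Breslow baseline via lifelines); because the
model conditions on eventual admission there is no censoring. Covariates:
arrival time-of-day banded into the four report-time intervals (24 hourly
dummies would be unstable at synthetic scale), weekend, quarter dummies, and
ED occupancy at arrival standardised on the training set. Constant or
linearly dependent columns (e.g. complementary quarter dummies when the
horizon spans two quarters) are dropped with a warning. The baseline
cumulative hazard is a step function; beyond its last step survival is
extrapolated as constant, and a patient whose elapsed time exceeds the
largest fitted duration is assigned conditional probability 1 — the model
has no mass left, so admission is treated as imminent. An optional rolling
window restricts the fit to visits departing within the trailing w weeks,
the drift-robust variant for rapidly changing operating conditions.

The Cox fit is a working model: the generator's durations are log-normal
with multiplicative covariate effects (an accelerated-failure-time
structure), under which proportional hazards holds only approximately. The
in-sample mean midpoint-PIT of the final forecasts is nevertheless 0.5 to
within Monte-Carlo error (the test suite computes this), so the
approximation is adequate at the covariate effect sizes used.

### Arrivals and the benchmark

Counts of patients arriving after the prediction instant and admitted
within the window, one observation per (training day, prediction time), are
fitted per window length with a log-link Poisson GLM (statsmodels) on
prediction time-of-day, quarter and weekend dummies; at least eight weeks of
counts are required. The forecast distribution is the Poisson at the
predicted mean, truncated at tail mass 1e-9 and renormalised.

The benchmark is the incumbent heuristic: the six-week same-weekday rolling
average of daily admissions minus admissions already observed by the report
time, floored at zero (the floor is this package's choice; the heuristic is
undefined when the day is already ahead of its average). Accuracy is
compared at 16:00 with the 8-hour window, the one pipeline window that ends
at midnight like the heuristic does. MAE is the mean absolute per-day error;
MPE is Σ|error|/Σobserved as a percentage (an aggregate ratio, avoiding
division by near-zero days; a per-day-ratio mode is available).

### Distribution algebra conventions

Quantiles use q(α) = smallest k with F(k) ≥ α; the reported band is
[q(0.1), q(0.9)]. On integer counts such a band covers 0.8 *plus* the
partial pmf mass at both edges — approximately 0.175/σ for count standard
deviation σ — so empirical coverage a little above 80% is expected behaviour,
not miscalibration. The midpoint PIT maps an observed count k to
(F(k−1)+F(k))/2, the conditional expectation of the randomised PIT, which is
uniform in expectation under a correct forecast. Convolutions are exact in
double precision; truncated Poisson tails are below 1e-9 before
renormalisation.

## The synthetic generator

The generator defines the package's reference study conditions. Defaults:

| parameter | default | rationale |
| --- | --- | --- |
| horizon | 140 days | ~20,000 visits, enough for all 12 cutoffs to train |
| arrival rate | 6/h daily average | a mid-size ED, scaled from the ~300/day system the pipeline targets so a full cycle runs on a workstation |
| diurnal profile | trough ~0.35 at 04:00, peak ~1.6 at 11:00–12:00, evening shoulder | the canonical ED arrival shape |
| admitted fraction | 0.207 | the intercept is calibrated by Monte-Carlo so the marginal admission probability over the covariate mix equals 20.7% |
| admission logit | ambulance +2.0, age 45–64 +0.6, 65+ +1.8, per prior admission +0.65, overnight arrival +0.5 | chosen once so the implied Bayes AUROC of arrival information is ≈0.8, the discrimination triage-data admission models typically reach |
| admitted durations | log-normal, median 240 min, σ=0.75; band/weekend/quarter effects; +0.12 log-minutes per 10 patients of occupancy at arrival | right-skewed boarding times; crowding slows admission |
| discharged durations | log-normal, median 150 min, σ=0.75 | stochastically dominated by admitted durations, so the admitted share rises with cutoff |
| event rates (per hour) | observations 2.0 vs 1.2, consults 0.30 vs 0.02, pathology orders 0.50 vs 0.25 (admitted vs discharged) | event density itself predicts admission |
| out-of-range tail | 0.35 vs 0.12 | out-of-range result counts carry signal |

The covariate mix (30% ambulance, age mix 35/40/25, prior admissions
Poisson(0.6)) is arbitrary but fixed; the target system does not publish its
distributions. Occupancy at arrival is computed sequentially during
generation so the crowding feedback is causal (earlier arrivals lengthen
later admitted stays). Timestamps are integer minutes from midnight of a
configurable start date; occupancy uses half-open intervals
[arrival, departure), so a patient departing at the query instant is not
counted. Pathology results whose return lag passes the departure time are
dropped — they would never reach the ED record.

What the generator does **not** emulate: clinical content (diagnoses,
NEWS physiology coupling, free-text complaints), HL7 messaging, same-day
re-visits, site-specific pathway semantics, or pandemic-scale regime
shifts. Passing tests therefore demonstrate that the pipeline machinery is
correct and calibrated *given* the assumed statistical structure, not that
the models would reach any particular accuracy on real hospital data.

### Drift in the reference conditions

The generator's quarter effects make time-to-admission drift between a
chronologically earlier training block and a later test block, and all
prediction times in one evaluation share the same 50 test days and the same
fitted components, so their PIT values are strongly dependent. Out-of-sample
mean PIT consequently scatters around 0.5 from seed to seed far more than an
independence calculation suggests, typically on the side of slight
under-forecasting — the same signature the deployed system this package
models reported. The test suite asserts exact calibration in-sample and
absence of gross bias out-of-sample.

## Evaluation protocol sizes

Chronological splits assign whole days: the most recent 20% of days to
test, the 10% before that to validation. End-to-end evaluations train on
63–84 days and forecast 50 held-out days (400 prediction-time/window pairs);
classifier evaluations use ~20,000-visit streams. These sizes are the
package's reference protocol and keep a full run in minutes.

## Known limitations

- Patient admission events are treated as independent given their
  probabilities; shared-shock dependence (e.g. a mass-casualty incident)
  would make the Poisson-binomial band too narrow.
- The Cox step is a proportional-hazards approximation to an AFT
  duration process; conditional window probabilities for extreme covariate
  combinations inherit the approximation error.
- Discharge is not modelled as a competing risk; the survival model simply
  conditions on eventual admission.
- The arrivals regression assumes a homogeneous Poisson count per
  (time-of-day, quarter, weekend) cell; intra-window arrival dynamics are
  not modelled.
- The 10–90% band's discrete over-coverage (above) should be kept in mind
  when comparing empirical coverage with the nominal 80%.
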