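"""Time-to-admission survival modelling for patients already in the ED.

Among patients who end up admitted, the time from ED arrival to admission
is modelled with Cox proportional hazards; covariates are the arrival
time-of-day band, a weekend flag, quarter of year and the ED occupancy at
arrival (standardised). Because the fit conditions on eventual admission
there is no censoring: every included visit experiences the event.

The fitted model answers the operational question: for a patient who has
already been in the department ``elapsed`` minutes, what is the
probability they are admitted within the next ``window`` minutes, given
they will be admitted at all?  That is

    1 - S(elapsed + window | x) / S(elapsed | x)

with S the covariate-adjusted survival function. Multiplying by the
classifier's admission probability gives the within-window admission
probability that Step 5 aggregates.
"""

from __future__ import annotations

import json
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, NelsonAalenFitter
from sklearn.base import BaseEstimator

from . import schema
from .simulate import MINUTES_PER_DAY, VisitStream

__all__ = [
    "CoxWindowModel",
    "duration_design_frame",
    "encode_covariates",
    "fit_time_to_admission",
    "conditional_window_probability",
    "window_admission_probability",
]

DESIGN_COLUMNS = (
    "band_06_12", "band_12_16", "band_16_22",
    "weekend", "quarter_2", "quarter_3", "quarter_4",
    "occupancy",
)
_SURVIVAL_FLOOR = 1e-12


def encode_covariates(arrival_ts: int, occupancy: int, stream: VisitStream) -> dict:
    """Raw design-row values for one patient's arrival circumstances."""
    hour = (arrival_ts % MINUTES_PER_DAY) // 60
    band = schema.hour_band(int(hour))
    quarter = int(stream.quarter_of_ts(arrival_ts)[0])
    return {
        "band_06_12": float(band == "06-12"),
        "band_12_16": float(band == "12-16"),
        "band_16_22": float(band == "16-22"),
        "weekend": float(stream.weekday_of_ts(arrival_ts) >= 5),
        "quarter_2": float(quarter == 2),
        "quarter_3": float(quarter == 3),
        "quarter_4": float(quarter == 4),
        "occupancy": float(occupancy),
    }


def duration_design_frame(stream: VisitStream, rolling_weeks: int | None = None,
                          fit_date_ts: int | None = None) -> pd.DataFrame:
    """Admitted-visit durations plus encoded covariates, ready for fitting.

    With ``rolling_weeks`` set, only visits departing within the last w
    weeks before ``fit_date_ts`` are kept (the drift-robust refinement used
    when operating conditions change quickly).
    """
    v = stream.visits
    adm = v[v["outcome"] == "admitted"].copy()
    if rolling_weeks is not None:
        if fit_date_ts is None:
            fit_date_ts = int(v["departure_ts"].max()) + 1
        lo = fit_date_ts - rolling_weeks * 7 * MINUTES_PER_DAY
        adm = adm[(adm["departure_ts"] >= lo) & (adm["departure_ts"] < fit_date_ts)]
    arr = adm["arrival_ts"].to_numpy()
    hours = (arr % MINUTES_PER_DAY) // 60
    bands = np.array([schema.hour_band(int(h)) for h in hours])
    quarter = stream.quarter_of_ts(arr)
    if "occupancy_at_arrival" in adm.columns:
        occ = adm["occupancy_at_arrival"].to_numpy(dtype=float)
    else:
        all_arr = v["arrival_ts"].to_numpy()
        all_dep = v["departure_ts"].to_numpy()
        occ = np.array(
            [np.count_nonzero((all_arr <= t) & (t < all_dep)) - 1 for t in arr], dtype=float
        )
    df = pd.DataFrame(
        {
            "duration_minutes": (adm["departure_ts"] - adm["arrival_ts"]).to_numpy(dtype=float),
            "band_06_12": (bands == "06-12").astype(float),
            "band_12_16": (bands == "12-16").astype(float),
            "band_16_22": (bands == "16-22").astype(float),
            "weekend": (stream.weekday_of_ts(arr) >= 5).astype(float),
            "quarter_2": (quarter == 2).astype(float),
            "quarter_3": (quarter == 3).astype(float),
            "quarter_4": (quarter == 4).astype(float),
            "occupancy": occ,
        }
    )
    return df.reset_index(drop=True)


class CoxWindowModel(BaseEstimator):
    """Cox PH model of time-to-admission with a step-function baseline.

    ``fit`` takes a frame with a ``duration_minutes`` column and any subset
    of covariate columns; constant covariates are dropped with a warning,
    continuous ones are standardised on the training set. With no usable
    covariates the model degrades gracefully to the nonparametric baseline
    (Nelson–Aalen) cumulative hazard.

    Beyond the last observed duration the survival function is
    extrapolated as constant, and a patient whose elapsed time already
    exhausts the survival support (S below 1e-12) is treated as certain to
    be admitted within any positive window.
    """

    def __init__(self, min_visits: int = 100, penalizer: float = 0.0):
        self.min_visits = min_visits
        self.penalizer = penalizer

    def fit(self, df: pd.DataFrame, y=None):
        df = df.reset_index(drop=True)
        if "duration_minutes" not in df.columns:
            raise ValueError("design frame must contain duration_minutes")
        if len(df) < self.min_visits:
            raise ValueError(f"need >= {self.min_visits} admitted visits, got {len(df)}")
        if (df["duration_minutes"] <= 0).any():
            raise ValueError("durations must be strictly positive")

        covs = [c for c in df.columns if c != "duration_minutes"]
        kept, dropped = [], []
        for c in covs:
            if df[c].nunique() <= 1:
                dropped.append(c)
            else:
                kept.append(c)
        # a complementary dummy pair (e.g. only two quarters in the horizon)
        # is perfectly collinear under Cox's interceptless parameterisation
        centered = df[kept].to_numpy(dtype=float)
        if kept:
            centered = centered - centered.mean(axis=0)
            full = []
            for j, c in enumerate(kept):
                trial = centered[:, [*(kept.index(k) for k in full), j]]
                if np.linalg.matrix_rank(trial) == len(full) + 1:
                    full.append(c)
                else:
                    dropped.append(c)
            kept = full
        if dropped:
            warnings.warn(f"dropping constant or collinear covariates: {dropped}", stacklevel=2)

        work = df[["duration_minutes", *kept]].copy()
        self.standardize_: dict = {}
        for c in kept:
            values = work[c]
            if values.nunique() > 2:  # continuous, e.g. occupancy
                mu, sd = float(values.mean()), float(values.std(ddof=0))
                sd = sd if sd > 0 else 1.0
                work[c] = (values - mu) / sd
                self.standardize_[c] = (mu, sd)

        if kept:
            cph = CoxPHFitter(penalizer=self.penalizer)
            cph.fit(work, duration_col="duration_minutes")
            self.params_ = cph.params_.copy()
            self.se_ = cph.standard_errors_.copy()
            self.center_ = work[kept].mean()
            base = cph.baseline_cumulative_hazard_
            self.baseline_times_ = base.index.to_numpy(dtype=float)
            self.baseline_cumhaz_ = base.iloc[:, 0].to_numpy(dtype=float)
        else:
            naf = NelsonAalenFitter()
            naf.fit(work["duration_minutes"])
            self.params_ = pd.Series(dtype=float)
            self.se_ = pd.Series(dtype=float)
            self.center_ = pd.Series(dtype=float)
            ch = naf.cumulative_hazard_
            self.baseline_times_ = ch.index.to_numpy(dtype=float)
            self.baseline_cumhaz_ = ch.iloc[:, 0].to_numpy(dtype=float)
        self.columns_ = kept
        self.n_fitted_ = len(work)
        return self

    # -- survival machinery --------------------------------------------
    def _partial_hazard(self, covariates: dict | None) -> float:
        if not self.columns_:
            return 1.0
        covariates = covariates or {}
        x = []
        for c in self.columns_:
            v = float(covariates.get(c, 0.0))
            if c in self.standardize_:
                mu, sd = self.standardize_[c]
                v = (v - mu) / sd
            x.append(v)
        delta = np.asarray(x) - self.center_.to_numpy()
        return float(np.exp(self.params_.to_numpy() @ delta))

    def cumulative_hazard(self, t: float) -> float:
        """Baseline cumulative hazard at t (step lookup, constant beyond support)."""
        idx = np.searchsorted(self.baseline_times_, t, side="right") - 1
        if idx < 0:
            return 0.0
        return float(self.baseline_cumhaz_[idx])

    def survival(self, t: float, covariates: dict | None = None) -> float:
        return float(np.exp(-self.cumulative_hazard(t) * self._partial_hazard(covariates)))

    def conditional_window_probability(self, elapsed_minutes: float, window_minutes: float,
                                       covariates: dict | None = None) -> float:
        if elapsed_minutes < 0 or window_minutes < 0:
            raise ValueError("elapsed and window must be non-negative")
        if window_minutes == 0:
            return 0.0
        # overdue: the patient has outlasted every training duration, so the
        # model has no mass left to spend — treat admission as imminent
        if elapsed_minutes >= self.baseline_times_[-1]:
            return 1.0
        s_now = self.survival(elapsed_minutes, covariates)
        if s_now < _SURVIVAL_FLOOR:
            return 1.0
        s_later = self.survival(elapsed_minutes + window_minutes, covariates)
        return float(np.clip(1.0 - s_later / s_now, 0.0, 1.0))

    def hazard_ratio(self, covariate: str) -> float:
        """exp(beta) on the raw covariate scale."""
        if covariate not in self.columns_:
            raise KeyError(covariate)
        beta = float(self.params_[covariate])
        if covariate in self.standardize_:
            beta /= self.standardize_[covariate][1]
        return float(np.exp(beta))

    # -- export ----------------------------------------------------------
    def coefficient_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "covariate": self.columns_,
                "coef": [float(self.params_[c]) for c in self.columns_],
                "hazard_ratio": [self.hazard_ratio(c) for c in self.columns_],
            }
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "columns": self.columns_,
                "params": {c: float(self.params_[c]) for c in self.columns_},
                "center": {c: float(self.center_[c]) for c in self.columns_},
                "standardize": {c: list(v) for c, v in self.standardize_.items()},
                "baseline_times": self.baseline_times_.tolist(),
                "baseline_cumhaz": self.baseline_cumhaz_.tolist(),
                "n_fitted": self.n_fitted_,
            }
        )

    @classmethod
    def from_json(cls, payload: str) -> "CoxWindowModel":
        obj = json.loads(payload)
        model = cls()
        model.columns_ = list(obj["columns"])
        model.params_ = pd.Series(obj["params"], dtype=float)
        model.center_ = pd.Series(obj["center"], dtype=float)
        model.standardize_ = {c: tuple(v) for c, v in obj["standardize"].items()}
        model.baseline_times_ = np.asarray(obj["baseline_times"], dtype=float)
        model.baseline_cumhaz_ = np.asarray(obj["baseline_cumhaz"], dtype=float)
        model.n_fitted_ = obj["n_fitted"]
        return model


def fit_time_to_admission(admitted_visits, rolling_weeks: int | None = None,
                          fit_date_ts: int | None = None,
                          min_visits: int = 100, penalizer: float = 0.0) -> CoxWindowModel:
    """Fit the Cox time-to-admission model from a visit stream or design frame."""
    if isinstance(admitted_visits, pd.DataFrame):
        df = admitted_visits
    else:
        stream = admitted_visits if isinstance(admitted_visits, VisitStream) \
            else VisitStream.from_records(list(admitted_visits))
        df = duration_design_frame(stream, rolling_weeks=rolling_weeks, fit_date_ts=fit_date_ts)
    return CoxWindowModel(min_visits=min_visits, penalizer=penalizer).fit(df)


def conditional_window_probability(model: CoxWindowModel, elapsed_minutes: float,
                                   window_minutes: float,
                                   covariates: dict | None = None) -> float:
    return model.conditional_window_probability(elapsed_minutes, window_minutes, covariates)


def window_admission_probability(p_admit: float, conditional_prob: float) -> float:
    """P(admitted within window) = P(admitted) * P(within window | admitted)."""
    if not (0.0 <= p_admit <= 1.0 and 0.0 <= conditional_prob <= 1.0):
        raise ValueError("both probabilities must lie in [0, 1]")
    return p_admit * conditional_prob
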