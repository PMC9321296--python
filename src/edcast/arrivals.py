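"""Patients not yet arrived: Poisson regression on within-window admissions.

The aggregate forecast must include patients who are not in the ED at the
prediction time but will arrive and be admitted before the window closes.
For each historical prediction instant a count of such patients is made;
a log-link Poisson regression with prediction time-of-day, quarter-of-year
and weekend terms is fitted per window length, and its predicted mean
parameterises a (truncated) Poisson distribution that is convolved with
the in-department forecast.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator

from .distributions import DiscreteDistribution, convolve, truncated_poisson
from .simulate import MINUTES_PER_DAY, VisitStream

__all__ = [
    "ArrivalCountModel",
    "count_not_yet_arrived_admissions",
    "arrival_count_frame",
    "fit_arrivals",
    "arrivals_distribution",
    "final_distribution",
]

_COVARIATE_COLUMNS = ("hour_12", "hour_16", "hour_22", "quarter_2", "quarter_3", "quarter_4", "weekend")


def count_not_yet_arrived_admissions(visits, prediction_ts: int, window_minutes: int) -> int:
    """Patients arriving after the prediction time who are admitted within it.

    Counts visits with arrival_ts > prediction_ts, outcome admitted and
    admission (ED departure) in the half-open window
    (prediction_ts, prediction_ts + window_minutes].
    """
    if isinstance(visits, VisitStream):
        v = visits.visits
        arr = v["arrival_ts"].to_numpy()
        dep = v["departure_ts"].to_numpy()
        adm = (v["outcome"] == "admitted").to_numpy()
    else:
        arr = np.array([r.arrival_ts for r in visits])
        dep = np.array([r.departure_ts for r in visits])
        adm = np.array([r.outcome == "admitted" for r in visits])
    end = prediction_ts + window_minutes
    return int(np.count_nonzero(adm & (arr > prediction_ts) & (dep > prediction_ts) & (dep <= end)))


def _encode(prediction_hour: int, quarter: int, weekend: bool) -> dict:
    return {
        "hour_12": float(prediction_hour == 12),
        "hour_16": float(prediction_hour == 16),
        "hour_22": float(prediction_hour == 22),
        "quarter_2": float(quarter == 2),
        "quarter_3": float(quarter == 3),
        "quarter_4": float(quarter == 4),
        "weekend": float(weekend),
    }


def arrival_count_frame(stream: VisitStream, days, prediction_times,
                        window_minutes: int) -> pd.DataFrame:
    """One training row per (day, prediction time): the observed count plus covariates."""
    rows = []
    for day in days:
        for tod in prediction_times:
            ts = day * MINUTES_PER_DAY + tod
            count = count_not_yet_arrived_admissions(stream, ts, window_minutes)
            quarter = int(stream.quarter_of_ts(ts)[0])
            weekend = bool(stream.weekday_of_ts(ts) >= 5)
            rows.append(
                {"day": day, "prediction_hour": tod // 60, "quarter": quarter,
                 "weekend": weekend, "count": count,
                 **_encode(tod // 60, quarter, weekend)}
            )
    return pd.DataFrame(rows)


class ArrivalCountModel(BaseEstimator):
    """Log-link Poisson regression for yet-to-arrive admission counts.

    Fitted on a frame from :func:`arrival_count_frame`; constant covariate
    columns (e.g. quarters absent from a short training span) are dropped.
    ``min_days`` enforces a floor on the amount of history (the default is
    eight weeks of counts).
    """

    def __init__(self, window_hours: int = 8, min_days: int = 56):
        self.window_hours = window_hours
        self.min_days = min_days

    def fit(self, counts: pd.DataFrame, y=None):
        c = counts["count"].to_numpy()
        if np.any(c < 0) or not np.allclose(c, np.round(c)):
            raise ValueError("counts must be non-negative integers")
        if "day" in counts.columns and counts["day"].nunique() < self.min_days:
            raise ValueError(
                f"need counts from >= {self.min_days} days, got {counts['day'].nunique()}"
            )
        cols = [col for col in _COVARIATE_COLUMNS if col in counts.columns
                and counts[col].nunique() > 1]
        # drop covariates collinear with the intercept + earlier columns
        # (e.g. complementary quarter dummies in a short horizon)
        kept: list = []
        for col in cols:
            trial = np.column_stack(
                [np.ones(len(counts))] + [counts[k].to_numpy(float) for k in [*kept, col]]
            )
            if np.linalg.matrix_rank(trial) == len(kept) + 2:
                kept.append(col)
        cols = kept
        X = sm.add_constant(counts[cols].astype(float), has_constant="add")
        self.result_ = sm.GLM(c.astype(float), X, family=sm.families.Poisson()).fit()
        self.columns_ = cols
        self.params_ = self.result_.params.copy()
        return self

    def predict_mean(self, prediction_hour: int, quarter: int, weekend: bool) -> float:
        raw = _encode(prediction_hour, quarter, weekend)
        eta = float(self.params_["const"])
        eta += sum(float(self.params_[c]) * raw[c] for c in self.columns_)
        return float(np.exp(eta))

    def coefficient_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "covariate": self.params_.index,
                "coef": self.params_.to_numpy(),
                "se": self.result_.bse.to_numpy(),
            }
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "window_hours": self.window_hours,
                "columns": self.columns_,
                "params": {k: float(v) for k, v in self.params_.items()},
            }
        )

    @classmethod
    def from_json(cls, payload: str) -> "ArrivalCountModel":
        obj = json.loads(payload)
        model = cls(window_hours=obj["window_hours"])
        model.columns_ = list(obj["columns"])
        model.params_ = pd.Series(obj["params"], dtype=float)
        model.result_ = None
        return model


def fit_arrivals(counts: pd.DataFrame, window_hours: int = 8, min_days: int = 56) -> ArrivalCountModel:
    """Maximum-likelihood Poisson regression; one model per window length."""
    return ArrivalCountModel(window_hours=window_hours, min_days=min_days).fit(counts)


def arrivals_distribution(model: ArrivalCountModel, prediction_hour: int,
                          quarter: int, weekend: bool) -> DiscreteDistribution:
    """Truncated-and-renormalised Poisson pmf at the model's predicted mean."""
    return truncated_poisson(model.predict_mean(prediction_hour, quarter, weekend))


def final_distribution(step5: DiscreteDistribution, arrivals: DiscreteDistribution) -> DiscreteDistribution:
    """Total admissions within the window: present patients plus future arrivals."""
    return convolve(step5, arrivals)
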