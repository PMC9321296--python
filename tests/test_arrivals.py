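"""Poisson regression for not-yet-arrived admissions and final convolution."""

import numpy as np
import pandas as pd
import pytest

from edcast.arrivals import (
    ArrivalCountModel,
    arrival_count_frame,
    arrivals_distribution,
    count_not_yet_arrived_admissions,
    final_distribution,
    fit_arrivals,
)
from edcast.distributions import DiscreteDistribution, convolve, poisson_binomial, truncated_poisson
from tests.test_framing import make_visit


class TestCounting:
    def test_no_future_arrivals(self):
        visits = [make_visit(arrival=100, duration=60, outcome="admitted")]
        assert count_not_yet_arrived_admissions(visits, 1000, 240) == 0

    def test_window_boundary_arithmetic(self):
        ts = 960
        visits = [make_visit(arrival=ts + 30, duration=150, outcome="admitted")]
        assert count_not_yet_arrived_admissions(visits, ts, 4 * 60) == 1
        assert count_not_yet_arrived_admissions(visits, ts, 2 * 60) == 0

    def test_discharged_arrivals_never_counted(self):
        ts = 960
        visits = [
            make_visit("a", arrival=ts + 10, duration=60, outcome="discharged"),
            make_visit("b", arrival=ts + 10, duration=60, outcome="admitted"),
        ]
        assert count_not_yet_arrived_admissions(visits, ts, 240) == 1

    def test_matches_brute_force_everywhere(self, small_stream):
        v = small_stream.visits
        arr, dep = v["arrival_ts"].to_numpy(), v["departure_ts"].to_numpy()
        adm = (v["outcome"] == "admitted").to_numpy()
        for day in range(0, 30, 3):
            for tod in (360, 720, 960, 1320):
                ts = day * 1440 + tod
                for w in (240, 480):
                    oracle = int((adm & (arr > ts) & (dep > ts) & (dep <= ts + w)).sum())
                    assert count_not_yet_arrived_admissions(small_stream, ts, w) == oracle


class TestFitting:
    @staticmethod
    def _poisson_counts(n_days, b0, b_weekend, seed):
        rng = np.random.default_rng(seed)
        rows = []
        for day in range(n_days):
            weekend = day % 7 >= 5
            for hour in (6, 12, 16, 22):
                mean = np.exp(b0 + b_weekend * weekend)
                rows.append(
                    {"day": day, "prediction_hour": hour, "quarter": 1,
                     "weekend": weekend, "count": rng.poisson(mean),
                     "hour_12": float(hour == 12), "hour_16": float(hour == 16),
                     "hour_22": float(hour == 22),
                     "quarter_2": 0.0, "quarter_3": 0.0, "quarter_4": 0.0,
                     "weekend": float(weekend)}
                )
        return pd.DataFrame(rows)

    def test_coefficient_recovery_within_3_se(self):
        """360 observations recover the weekend effect of a known Poisson model."""
        counts = self._poisson_counts(90, b0=2.0, b_weekend=0.3, seed=0)
        model = fit_arrivals(counts, min_days=56)
        table = model.coefficient_table().set_index("covariate")
        assert abs(table.loc["const", "coef"] - 2.0) < 3 * table.loc["const", "se"]
        assert abs(table.loc["weekend", "coef"] - 0.3) < 3 * table.loc["weekend", "se"]

    def test_intercept_only_mle_is_sample_mean(self):
        counts = self._poisson_counts(60, b0=1.5, b_weekend=0.0, seed=1)
        for col in ("hour_12", "hour_16", "hour_22", "weekend"):
            counts[col] = 0.0
        model = fit_arrivals(counts, min_days=56)
        assert model.predict_mean(16, 1, False) == pytest.approx(
            counts["count"].mean(), rel=1e-9
        )

    def test_positive_means_everywhere(self):
        counts = self._poisson_counts(60, b0=0.5, b_weekend=-0.4, seed=2)
        model = fit_arrivals(counts, min_days=56)
        for hour in (6, 12, 16, 22):
            for quarter in (1, 2, 3, 4):
                for weekend in (False, True):
                    assert model.predict_mean(hour, quarter, weekend) > 0

    def test_invalid_counts_rejected(self):
        counts = self._poisson_counts(60, 1.0, 0.0, seed=3)
        bad = counts.copy()
        bad.loc[0, "count"] = -1
        with pytest.raises(ValueError, match="non-negative integers"):
            fit_arrivals(bad, min_days=56)
        bad2 = counts.copy()
        bad2["count"] = bad2["count"] + 0.5
        with pytest.raises(ValueError, match="non-negative integers"):
            fit_arrivals(bad2, min_days=56)

    def test_too_little_history_rejected(self):
        counts = self._poisson_counts(20, 1.0, 0.0, seed=4)
        with pytest.raises(ValueError, match="days"):
            fit_arrivals(counts, min_days=56)

    def test_count_frame_from_stream(self, small_stream):
        frame = arrival_count_frame(small_stream, range(5), (360, 960), 240)
        assert len(frame) == 10
        assert (frame["count"] >= 0).all()
        oracle = count_not_yet_arrived_admissions(small_stream, 2 * 1440 + 960, 240)
        row = frame[(frame["day"] == 2) & (frame["prediction_hour"] == 16)]
        assert int(row["count"].iloc[0]) == oracle


class TestArrivalsDistribution:
    @staticmethod
    def _model_with_mean(mean):
        model = ArrivalCountModel(window_hours=8)
        model.columns_ = []
        model.params_ = pd.Series({"const": np.log(mean) if mean > 0 else -20.0})
        model.result_ = None
        return model

    def test_pmf_zero_closed_form(self):
        dist = arrivals_distribution(self._model_with_mean(4.0), 16, 2, False)
        assert dist.pmf[0] == pytest.approx(np.exp(-4.0), abs=1e-9)

    def test_vanishing_mean_is_point_mass(self):
        model = ArrivalCountModel(window_hours=8)
        model.columns_ = []
        model.params_ = pd.Series({"const": -20.0})
        dist = arrivals_distribution(model, 16, 2, False)
        assert dist.pmf[0] == pytest.approx(1.0, abs=1e-8)

    def test_mean_conserved(self):
        dist = arrivals_distribution(self._model_with_mean(7.3), 6, 1, True)
        assert dist.mean == pytest.approx(7.3, abs=1e-6)

    def test_poisson_additivity_of_fitted_distributions(self):
        a = arrivals_distribution(self._model_with_mean(2.5), 6, 1, False)
        b = arrivals_distribution(self._model_with_mean(4.0), 12, 1, False)
        combined = convolve(a, b)
        target = truncated_poisson(6.5)
        k = min(combined.support_max, target.support_max) + 1
        np.testing.assert_allclose(combined.pmf[:k], target.pmf[:k], atol=1e-8)


class TestFinalDistribution:
    def test_point_mass_identity(self):
        step5 = poisson_binomial([0.4, 0.9])
        out = final_distribution(step5, DiscreteDistribution.point_mass(0))
        np.testing.assert_allclose(out.pmf, step5.pmf, atol=1e-12)

    def test_point_masses_add(self):
        out = final_distribution(
            DiscreteDistribution.point_mass(3), DiscreteDistribution.point_mass(4)
        )
        assert out.pmf.argmax() == 7
        assert out.pmf[7] == pytest.approx(1.0)

    def test_json_round_trip_of_model(self):
        model = TestArrivalsDistribution._model_with_mean(3.0)
        again = ArrivalCountModel.from_json(model.to_json())
        assert again.predict_mean(16, 1, False) == pytest.approx(3.0, rel=1e-12)
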