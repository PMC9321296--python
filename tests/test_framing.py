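"""Temporal framing: cutoff selection, leakage control, splits, snapshots."""

import numpy as np
import pandas as pd
import pytest

from edcast.framing import (
    FEATURE_COLUMNS,
    FramingConfig,
    build_left_aligned,
    build_snapshot,
    chronological_split,
    select_model_cutoff,
)
from edcast.simulate import SimConfig, VisitRecord, VisitStream, occupancy_at, simulate_stream


def make_visit(visit_id="v0", arrival=600, duration=120, outcome="discharged",
               observations=(), consults=(), pathology_results=(), locations=None):
    dep = arrival + duration
    return VisitRecord(
        visit_id=visit_id, arrival_ts=arrival, departure_ts=dep, outcome=outcome,
        age_band="18-44", arrival_method="walk-in", prior_admissions=0,
        locations=locations if locations is not None else [(arrival, "waiting")],
        observations=list(observations), consults=list(consults),
        pathology_orders=[], pathology_results=list(pathology_results),
    )


class TestSelectModelCutoff:
    @pytest.mark.parametrize(
        "elapsed,expected",
        [(29, 15), (31, 30), (0, 0), (1440, 720), (720, 720), (89, 60)],
    )
    def test_assignment(self, elapsed, expected):
        assert select_model_cutoff(elapsed, FramingConfig().cutoffs_minutes) == expected

    def test_negative_elapsed_rejected(self):
        with pytest.raises(ValueError):
            select_model_cutoff(-1, FramingConfig().cutoffs_minutes)


class TestBuildLeftAligned:
    def test_short_visit_only_in_earliest_dataset(self):
        # a visit lasting under 15 minutes trains only the time-zero model
        visits = [make_visit(duration=10), make_visit("v1", duration=100)]
        assert set(build_left_aligned(visits, 0)["visit_id"]) == {"v0", "v1"}
        assert set(build_left_aligned(visits, 15)["visit_id"]) == {"v1"}

    def test_duration_strictly_greater_than_cutoff(self):
        visits = [make_visit(duration=60)]
        assert len(build_left_aligned(visits, 60)) == 0
        assert len(build_left_aligned(visits, 30)) == 1

    def test_pathology_results_filtered_by_cutoff(self):
        arrival = 600
        results = [(arrival + m, "crp", 50.0, 0.0, 5.0) for m in (50, 70, 200)]
        visits = [make_visit(duration=300, pathology_results=results)]
        row = build_left_aligned(visits, 60).iloc[0]
        assert row["n_results_above_range"] == 1
        assert row["latest_crp"] == 50.0
        row_full = build_left_aligned(visits, 240).iloc[0]
        assert row_full["n_results_above_range"] == 3

    def test_unknown_cutoff_rejected(self):
        with pytest.raises(ValueError, match="unknown cutoff"):
            build_left_aligned([make_visit()], 45)

    def test_row_count_matches_brute_force(self, small_stream):
        rows = build_left_aligned(small_stream, 90)
        v = small_stream.visits
        oracle = int(((v["departure_ts"] - v["arrival_ts"]) > 90).sum())
        assert len(rows) == oracle

    def test_missing_latest_values_are_nan_counts_zero(self):
        visits = [make_visit(duration=120)]
        row = build_left_aligned(visits, 0).iloc[0]
        assert np.isnan(row["latest_news"])
        assert row["n_obs_news"] == 0
        assert row["n_consults"] == 0

    def test_monotone_shrinkage_and_admitted_enrichment(self, small_stream):
        fc = FramingConfig()
        sizes, fracs = [], []
        for cutoff in fc.cutoffs_minutes:
            rows = build_left_aligned(small_stream, cutoff, fc)
            sizes.append(len(rows))
            fracs.append(rows["admitted"].mean())
        assert all(b <= a for a, b in zip(sizes, sizes[1:]))
        # admitted durations stochastically dominate discharged ones, so the
        # admitted share rises with cutoff (small slack for sampling noise)
        assert all(b >= a - 0.03 for a, b in zip(fracs, fracs[1:]))
        assert fracs[-1] > fracs[0]


class TestAntiLeakage:
    def test_events_after_cutoff_never_change_features(self):
        rng = np.random.default_rng(0)
        stream = simulate_stream(SimConfig(horizon_days=10, seed=13))
        cutoff = 60
        baseline = build_left_aligned(stream, cutoff)
        # perturb every event strictly after arrival + cutoff
        mutated = VisitStream(
            visits=stream.visits.copy(),
            locations=stream.locations.copy(),
            observations=stream.observations.copy(),
            consults=stream.consults.copy(),
            pathology_orders=stream.pathology_orders.copy(),
            pathology_results=stream.pathology_results.copy(),
            start_date=stream.start_date,
        )
        arrivals = mutated.visits.set_index("visit_id")["arrival_ts"]
        for name in ("observations", "pathology_results"):
            df = getattr(mutated, name)
            late = df["ts"].to_numpy() > (arrivals.reindex(df["visit_id"]).to_numpy() + cutoff)
            df.loc[late, "value"] = rng.normal(1e6, 1.0, size=int(late.sum()))
        out = build_left_aligned(mutated, cutoff)
        pd.testing.assert_frame_equal(out, baseline)


class TestBuildSnapshot:
    def test_empty_snapshot(self):
        snap = build_snapshot([make_visit(arrival=0, duration=10)], 5000)
        assert len(snap) == 0

    def test_cutoff_assignment_at_elapsed_100(self):
        snap = build_snapshot([make_visit(arrival=600, duration=300)], 700)
        assert snap.rows.iloc[0]["cutoff_minutes"] == 90
        assert snap.rows.iloc[0]["elapsed_minutes"] == 100

    def test_membership_equals_occupancy(self, small_stream):
        for ts in (5 * 1440 + 960, 12 * 1440 + 360, 20 * 1440 + 1320):
            snap = build_snapshot(small_stream, ts)
            assert len(snap) == occupancy_at(small_stream, ts)

    def test_snapshot_matches_left_aligned_at_exact_cutoff(self):
        obs = [(600 + 40, "news", 5.0)]
        visits = [make_visit(arrival=600, duration=400, observations=obs)]
        snap = build_snapshot(visits, 600 + 90)  # elapsed exactly 90
        left = build_left_aligned(visits, 90)
        snap_feats = snap.rows[FEATURE_COLUMNS].reset_index(drop=True)
        left_feats = left[FEATURE_COLUMNS].reset_index(drop=True)
        pd.testing.assert_frame_equal(snap_feats, left_feats)


class TestChronologicalSplit:
    @staticmethod
    def _one_per_day(n_days):
        return [make_visit(f"d{d}", arrival=d * 1440 + 600, duration=60) for d in range(n_days)]

    def test_70_10_20_over_100_days(self):
        split = chronological_split(self._one_per_day(100), (0.7, 0.1, 0.2))
        assert split.train_days == list(range(70))
        assert split.validation_days == list(range(70, 80))
        assert split.test_days == list(range(80, 100))

    def test_all_train(self):
        split = chronological_split(self._one_per_day(10), (1.0, 0.0, 0.0))
        assert len(split.train_days) == 10 and not split.test_days

    def test_partition_property(self, small_stream):
        split = chronological_split(small_stream, (0.6, 0.2, 0.2))
        parts = [set(split.train_days), set(split.validation_days), set(split.test_days)]
        assert not (parts[0] & parts[1] or parts[0] & parts[2] or parts[1] & parts[2])
        days = set(small_stream.visits["arrival_ts"] // 1440)
        assert parts[0] | parts[1] | parts[2] == days

    def test_too_few_days_rejected(self):
        with pytest.raises(ValueError):
            chronological_split(self._one_per_day(2), (0.7, 0.1, 0.2))

    def test_visit_follows_arrival_day(self, small_stream):
        split = chronological_split(small_stream, (0.7, 0.1, 0.2))
        train, _, test = split.assign(small_stream)
        assert set(train.visits["arrival_ts"] // 1440) <= set(split.train_days)
        assert set(test.visits["arrival_ts"] // 1440) <= set(split.test_days)
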