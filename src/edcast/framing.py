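"""Temporal framing: left-aligned training sets and right-aligned snapshots.

Training samples are anchored at each patient's arrival: the model with
cutoff c is trained on every visit lasting strictly more than c minutes,
using only events timestamped within c minutes of arrival.  Prediction
samples are anchored at the prediction instant: each patient present is
assigned the largest cutoff not exceeding their elapsed time, and their
features are computed as of arrival + assigned cutoff, so the inference
rows match the training distribution of the model that scores them.

Features come in four groups — visit, location, observations-and-consults,
pathology — and latest-value features are missing (NaN), not zero, when no
such event has happened yet; count features are zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import schema
from .simulate import MINUTES_PER_DAY, VisitStream

__all__ = [
    "FramingConfig",
    "Snapshot",
    "SplitDays",
    "select_model_cutoff",
    "build_left_aligned",
    "build_snapshot",
    "chronological_split",
    "FEATURE_GROUPS",
    "FEATURE_COLUMNS",
]

DEFAULT_CUTOFFS = (0, 15, 30, 60, 90, 120, 180, 240, 300, 360, 480, 720)
DEFAULT_PREDICTION_TIMES = (360, 720, 960, 1320)  # 06:00 12:00 16:00 22:00, minutes of day


@dataclass
class FramingConfig:
    cutoffs_minutes: Sequence[int] = DEFAULT_CUTOFFS
    prediction_times: Sequence[int] = DEFAULT_PREDICTION_TIMES
    split_fractions: tuple = (0.7, 0.1, 0.2)

    def validate(self) -> None:
        cuts = list(self.cutoffs_minutes)
        if not cuts or cuts[0] != 0:
            raise ValueError("first cutoff must be 0")
        if any(b <= a for a, b in zip(cuts, cuts[1:])):
            raise ValueError("cutoffs must be strictly increasing")
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


def _feature_groups() -> dict:
    visit = ["age_45_64", "age_65_plus", "arrival_ambulance", "prior_admissions",
             "arrival_band_06_12", "arrival_band_12_16", "arrival_band_16_22",
             "arrival_weekend"]
    location = [f"loc_{c}" for c in schema.LOCATIONS] + ["n_location_changes"]
    obs = []
    for t in schema.NUMERIC_OBS:
        obs += [f"n_obs_{t}", f"latest_{t}"]
    obs += ["n_pressure_checks", "n_obs_events", "n_obs_types", "n_consults"]
    path = [f"ordered_{b}" for b in schema.BATTERIES] + ["n_orders"]
    path += [f"latest_{t}" for t in schema.TESTS]
    path += ["n_results_above_range", "n_results_below_range"]
    return {"visit": visit, "location": location, "observations_consults": obs, "pathology": path}


FEATURE_GROUPS = _feature_groups()
FEATURE_COLUMNS = [c for cols in FEATURE_GROUPS.values() for c in cols]
# latest-value features may legitimately be missing; everything else is a count/flag
MISSABLE_COLUMNS = [c for c in FEATURE_COLUMNS if c.startswith("latest_")]


@dataclass
class Snapshot:
    """The roomful of patients present at a prediction instant.

    ``rows`` has one row per patient with visit_id, elapsed_minutes,
    cutoff_minutes and the full feature schema as known at
    arrival + assigned cutoff.
    """

    prediction_ts: int
    rows: pd.DataFrame

    def __len__(self) -> int:
        return len(self.rows)


def select_model_cutoff(elapsed_minutes: float, cutoffs: Sequence[int]) -> int:
    """Largest cutoff <= elapsed; elapsed beyond the last cutoff clamps to it."""
    if elapsed_minutes < 0:
        raise ValueError("elapsed time must be non-negative")
    eligible = [c for c in cutoffs if c <= elapsed_minutes]
    if not eligible:
        raise ValueError("cutoff list must start at 0")
    return max(eligible)


def _as_stream(visits) -> VisitStream:
    if isinstance(visits, VisitStream):
        return visits
    return VisitStream.from_records(list(visits))


def _compute_features(stream: VisitStream, members: pd.DataFrame) -> pd.DataFrame:
    """Feature matrix for the given visits at the given per-visit limit.

    ``members`` needs columns visit_id, arrival_ts and limit_ts; only events
    with ts <= limit_ts contribute.
    """
    vis = stream.visits.set_index("visit_id")
    ids = members["visit_id"].to_numpy()
    limit = pd.Series(members["limit_ts"].to_numpy(), index=ids)
    out = pd.DataFrame(index=pd.Index(ids, name="visit_id"))

    # ---- visit group ----
    sub = vis.loc[ids]
    out["age_45_64"] = (sub["age_band"] == schema.AGE_BANDS[1]).astype(float).to_numpy()
    out["age_65_plus"] = (sub["age_band"] == schema.AGE_BANDS[2]).astype(float).to_numpy()
    out["arrival_ambulance"] = (sub["arrival_method"] == "ambulance").astype(float).to_numpy()
    out["prior_admissions"] = sub["prior_admissions"].astype(float).to_numpy()
    arr = sub["arrival_ts"].to_numpy()
    hours = (arr % MINUTES_PER_DAY) // 60
    bands = np.array([schema.hour_band(int(h)) for h in hours])
    for b in ("06-12", "12-16", "16-22"):
        out[f"arrival_band_{b.replace('-', '_')}"] = (bands == b).astype(float)
    out["arrival_weekend"] = (stream.weekday_of_ts(arr) >= 5).astype(float)

    def visible(df: pd.DataFrame) -> pd.DataFrame:
        d = df[df["visit_id"].isin(limit.index)]
        return d[d["ts"].to_numpy() <= limit.reindex(d["visit_id"]).to_numpy()]

    # ---- location group ----
    loc = visible(stream.locations).sort_values("ts", kind="stable")
    current = loc.groupby("visit_id")["location"].last()
    counts = loc.groupby("visit_id").size()
    cur = current.reindex(out.index)
    for c in schema.LOCATIONS:
        out[f"loc_{c}"] = (cur == c).astype(float).to_numpy()
    out["n_location_changes"] = (counts.reindex(out.index).fillna(0) - 1).clip(lower=0).to_numpy()

    # ---- observations and consults ----
    obs = visible(stream.observations).sort_values("ts", kind="stable")
    type_counts = obs.groupby(["visit_id", "obs_type"]).size().unstack(fill_value=0)
    latest = obs.groupby(["visit_id", "obs_type"])["value"].last().unstack()
    for t in schema.NUMERIC_OBS:
        out[f"n_obs_{t}"] = (
            type_counts[t] if t in type_counts else pd.Series(dtype=float)
        ).reindex(out.index).fillna(0).to_numpy()
        out[f"latest_{t}"] = (
            latest[t] if t in latest else pd.Series(dtype=float)
        ).reindex(out.index).to_numpy()
    out["n_pressure_checks"] = (
        type_counts["pressure_check"] if "pressure_check" in type_counts else pd.Series(dtype=float)
    ).reindex(out.index).fillna(0).to_numpy()
    out["n_obs_events"] = obs.groupby("visit_id").size().reindex(out.index).fillna(0).to_numpy()
    out["n_obs_types"] = obs.groupby("visit_id")["obs_type"].nunique().reindex(out.index).fillna(0).to_numpy()
    cons = visible(stream.consults)
    out["n_consults"] = cons.groupby("visit_id").size().reindex(out.index).fillna(0).to_numpy()

    # ---- pathology ----
    orders = visible(stream.pathology_orders)
    bat_flags = (orders.groupby(["visit_id", "battery"]).size() > 0).unstack(fill_value=False)
    for b in schema.BATTERIES:
        col = bat_flags[b] if b in bat_flags else pd.Series(dtype=bool)
        out[f"ordered_{b}"] = col.reindex(out.index, fill_value=False).astype(float).to_numpy()
    out["n_orders"] = orders.groupby("visit_id").size().reindex(out.index).fillna(0).to_numpy()
    res = visible(stream.pathology_results).sort_values("ts", kind="stable")
    latest_res = res.groupby(["visit_id", "test"])["value"].last().unstack()
    for t in schema.TESTS:
        out[f"latest_{t}"] = (
            latest_res[t] if t in latest_res else pd.Series(dtype=float)
        ).reindex(out.index).to_numpy()
    if len(res):
        above = res[res["value"] > res["range_high"]].groupby("visit_id").size()
        below = res[res["value"] < res["range_low"]].groupby("visit_id").size()
    else:
        above = below = pd.Series(dtype=float)
    out["n_results_above_range"] = above.reindex(out.index).fillna(0).to_numpy()
    out["n_results_below_range"] = below.reindex(out.index).fillna(0).to_numpy()

    return out[FEATURE_COLUMNS]


def build_left_aligned(visits, cutoff_minutes: int,
                       config: FramingConfig | None = None) -> pd.DataFrame:
    """Left-aligned training rows for one cutoff.

    Includes exactly the visits with duration strictly greater than the
    cutoff, with features from events timestamped within ``cutoff_minutes``
    of arrival. Returns a frame with visit_id, cutoff_minutes, the feature
    columns and the admitted label.
    """
    config = config or FramingConfig()
    config.validate()
    if cutoff_minutes not in set(config.cutoffs_minutes):
        raise ValueError(f"unknown cutoff {cutoff_minutes}; configured: {list(config.cutoffs_minutes)}")
    stream = _as_stream(visits)
    v = stream.visits
    keep = v[(v["departure_ts"] - v["arrival_ts"]) > cutoff_minutes]
    members = pd.DataFrame(
        {
            "visit_id": keep["visit_id"].to_numpy(),
            "arrival_ts": keep["arrival_ts"].to_numpy(),
            "limit_ts": keep["arrival_ts"].to_numpy() + cutoff_minutes,
        }
    )
    feats = _compute_features(stream, members).reset_index()
    feats.insert(1, "cutoff_minutes", cutoff_minutes)
    feats["admitted"] = (
        keep.set_index("visit_id")["outcome"].reindex(feats["visit_id"]) == "admitted"
    ).astype(int).to_numpy()
    return feats


def build_snapshot(visits, prediction_ts: int,
                   config: FramingConfig | None = None) -> Snapshot:
    """Right-aligned snapshot of patients present at ``prediction_ts``.

    Each included visit satisfies arrival <= prediction_ts < departure and
    is assigned the largest cutoff not exceeding its elapsed time; features
    are computed as of arrival + assigned cutoff.
    """
    config = config or FramingConfig()
    config.validate()
    stream = _as_stream(visits)
    v = stream.visits
    present = v[(v["arrival_ts"] <= prediction_ts) & (prediction_ts < v["departure_ts"])]
    if present.empty:
        cols = ["visit_id", "elapsed_minutes", "cutoff_minutes", *FEATURE_COLUMNS]
        return Snapshot(prediction_ts, pd.DataFrame(columns=cols))
    elapsed = (prediction_ts - present["arrival_ts"]).to_numpy()
    cutoffs = np.array([select_model_cutoff(e, config.cutoffs_minutes) for e in elapsed])
    members = pd.DataFrame(
        {
            "visit_id": present["visit_id"].to_numpy(),
            "arrival_ts": present["arrival_ts"].to_numpy(),
            "limit_ts": np.minimum(prediction_ts, present["arrival_ts"].to_numpy() + cutoffs),
        }
    )
    feats = _compute_features(stream, members).reset_index()
    feats.insert(1, "elapsed_minutes", elapsed)
    feats.insert(2, "cutoff_minutes", cutoffs)
    return Snapshot(prediction_ts, feats)


@dataclass
class SplitDays:
    """Chronological day partition; a visit belongs with its arrival day."""

    train_days: list
    validation_days: list
    test_days: list

    def all_days(self) -> list:
        return sorted([*self.train_days, *self.validation_days, *self.test_days])

    def assign(self, stream: VisitStream) -> tuple:
        v = stream.visits
        day = v["arrival_ts"] // MINUTES_PER_DAY

        def pick(days):
            return stream.subset(v.loc[day.isin(set(days)), "visit_id"])

        return pick(self.train_days), pick(self.validation_days), pick(self.test_days)


def chronological_split(visits, split_fractions: tuple = (0.7, 0.1, 0.2)) -> SplitDays:
    """Contiguous train/validation/test partition of calendar days.

    The test set holds the most recent fraction of days and the validation
    set the block immediately before it, mirroring a deployment in which
    only the past is available at training time.
    """
    if abs(sum(split_fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    stream = _as_stream(visits)
    days = sorted(set(stream.visits["arrival_ts"] // MINUTES_PER_DAY))
    n = len(days)
    if n < 3:
        raise ValueError("need at least 3 days to split")
    n_test = int(round(split_fractions[2] * n))
    n_val = int(round(split_fractions[1] * n))
    n_train = n - n_val - n_test
    if min(n_train, 0) < 0:
        raise ValueError("split fractions leave no training days")
    return SplitDays(
        train_days=days[:n_train],
        validation_days=days[n_train:n_train + n_val],
        test_days=days[n_train + n_val:],
    )


def write_feature_table(rows: pd.DataFrame, path, schema_path=None) -> None:
    """CSV + JSON-sidecar export of a feature table (missing -> empty field)."""
    path = Path(path)
    rows.to_csv(path, index=False)
    sidecar = Path(schema_path) if schema_path else path.with_suffix(".schema.json")
    groups = {g: [c for c in cols if c in rows.columns] for g, cols in FEATURE_GROUPS.items()}
    sidecar.write_text(json.dumps({"feature_groups": groups}, indent=2))
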