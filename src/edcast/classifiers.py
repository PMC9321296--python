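"""Per-cutoff admission classifiers.

One probabilistic classifier is trained per elapsed-time cutoff; at
prediction time each patient is scored by the model matching their elapsed
visit time. Gradient-boosted trees are the default algorithm; random
forest and lasso-penalised logistic regression are provided as
comparators. Tree models consume missing values natively; the others
impute at the training median. Hyperparameters are chosen by k-fold
cross-validation minimising log loss over a small declared grid, since
accurate probabilities (not classification accuracy) are what the
downstream count aggregation needs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.impute import SimpleImputer
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from xgboost import XGBClassifier

from .framing import FEATURE_COLUMNS, FEATURE_GROUPS, Snapshot, build_left_aligned

__all__ = [
    "AdmissionClassifier",
    "ModelBundle",
    "TuningConfig",
    "train_bundle",
    "predict_snapshot",
    "evaluate_models",
    "calibration_bins",
]

PROB_CLIP = 1e-15

DEFAULT_PARAMS = {
    "xgboost": {"max_depth": 3, "learning_rate": 0.1, "n_estimators": 250,
                "subsample": 0.9, "min_child_weight": 5},
    "random_forest": {"n_estimators": 300, "min_samples_leaf": 5},
    "lasso_logistic": {"C": 0.1},
}

DEFAULT_GRIDS = {
    "xgboost": [
        {"max_depth": 3, "learning_rate": 0.1, "n_estimators": 250,
         "subsample": 0.9, "min_child_weight": 5},
        {"max_depth": 4, "learning_rate": 0.05, "n_estimators": 250, "subsample": 0.9},
    ],
    "random_forest": [
        {"n_estimators": 300, "min_samples_leaf": 5},
        {"n_estimators": 300, "min_samples_leaf": 20},
    ],
    # a lasso grid is a regularisation path: C = 1/penalty, strongest last
    "lasso_logistic": [{"C": c} for c in (10.0, 3.0, 1.0, 0.3, 0.1, 0.03, 0.01, 0.003)],
}


@dataclass
class TuningConfig:
    """Cross-validation tuning settings; ``grid=None`` uses the declared default."""

    grid: list | None = None
    cv: int = 10
    lasso_selection: str = "min"  # min | 2se | 3se | 4se


def _clip(p: np.ndarray) -> np.ndarray:
    return np.clip(p, PROB_CLIP, 1.0 - PROB_CLIP)


class AdmissionClassifier(BaseEstimator, ClassifierMixin):
    """Probabilistic admitted-vs-discharged classifier for one cutoff.

    Parameters
    ----------
    algorithm : {"xgboost", "random_forest", "lasso_logistic"}
    params : explicit hyperparameters; when given, no CV search runs.
    grid : candidate hyperparameter dicts for CV selection (ignored when
        ``params`` is set). For the lasso the grid is a C path and
        ``lasso_selection`` picks the minimum-CV-error value ("min") or the
        sparsest model within k standard errors of it ("2se"/"3se"/"4se").
    cv : folds for the stratified CV log-loss search.
    class_weight : optional "balanced" switch; off by default.
    """

    def __init__(self, algorithm: str = "xgboost", params: dict | None = None,
                 grid: list | None = None, cv: int = 10,
                 lasso_selection: str = "min", class_weight=None,
                 random_state: int = 0):
        self.algorithm = algorithm
        self.params = params
        self.grid = grid
        self.cv = cv
        self.lasso_selection = lasso_selection
        self.class_weight = class_weight
        self.random_state = random_state

    # -- construction of the underlying estimator ----------------------
    def _make(self, params: dict):
        if self.algorithm == "xgboost":
            return XGBClassifier(
                objective="binary:logistic", eval_metric="logloss",
                tree_method="hist", n_jobs=1, random_state=self.random_state,
                **params,
            )
        if self.algorithm == "random_forest":
            model = RandomForestClassifier(
                n_jobs=1, random_state=self.random_state,
                class_weight=self.class_weight, **params,
            )
        elif self.algorithm == "lasso_logistic":
            model = LogisticRegression(
                l1_ratio=1.0, solver="liblinear", max_iter=2000,
                class_weight=self.class_weight, random_state=self.random_state,
                **params,
            )
        else:
            raise ValueError(f"unknown algorithm: {self.algorithm}")
        # non-tree models cannot consume NaN: impute at the training median
        steps = [("impute", SimpleImputer(strategy="median"))]
        if self.algorithm == "lasso_logistic":
            steps.append(("scale", StandardScaler()))
        steps.append(("model", model))
        return Pipeline(steps)

    @staticmethod
    def _proba(est, X) -> np.ndarray:
        return est.predict_proba(X)[:, 1]

    def _cv_losses(self, X, y, grid) -> pd.DataFrame:
        skf = StratifiedKFold(n_splits=self.cv, shuffle=True, random_state=self.random_state)
        rows = []
        for i, params in enumerate(grid):
            losses = []
            for tr, va in skf.split(X, y):
                est = self._make(params)
                est.fit(X.iloc[tr], y[tr])
                p = _clip(self._proba(est, X.iloc[va]))
                losses.append(log_loss(y[va], p, labels=[0, 1]))
            losses = np.asarray(losses)
            rows.append(
                {"candidate": i, "params": params,
                 "mean_log_loss": losses.mean(),
                 "se_log_loss": losses.std(ddof=1) / np.sqrt(len(losses))}
            )
        return pd.DataFrame(rows)

    def _select(self, cv_results: pd.DataFrame) -> dict:
        best = cv_results.loc[cv_results["mean_log_loss"].idxmin()]
        if self.algorithm != "lasso_logistic" or self.lasso_selection == "min":
            return dict(best["params"])
        k = {"2se": 2.0, "3se": 3.0, "4se": 4.0}.get(self.lasso_selection)
        if k is None:
            raise ValueError(f"unknown lasso_selection: {self.lasso_selection}")
        ceiling = best["mean_log_loss"] + k * best["se_log_loss"]
        ok = cv_results[cv_results["mean_log_loss"] <= ceiling]
        # sparsest admissible model = smallest C (heaviest penalty)
        sparsest = min(ok["params"], key=lambda p: p["C"])
        return dict(sparsest)

    # -- sklearn API ----------------------------------------------------
    def fit(self, X, y):
        X = pd.DataFrame(X)
        y = np.asarray(y).astype(int)
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError("training data contains a single class")
        self.classes_ = np.array([0, 1])
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.n_features_in_ = X.shape[1]
        if self.params is not None:
            chosen, self.cv_results_ = dict(self.params), None
        else:
            grid = self.grid if self.grid is not None else DEFAULT_GRIDS[self.algorithm]
            if len(grid) == 1:
                chosen, self.cv_results_ = dict(grid[0]), None
            else:
                self.cv_results_ = self._cv_losses(X, y, grid)
                chosen = self._select(self.cv_results_)
        if self.algorithm == "xgboost" and self.class_weight == "balanced":
            chosen = {**chosen, "scale_pos_weight": float((y == 0).sum() / max((y == 1).sum(), 1))}
        self.best_params_ = chosen
        self.model_ = self._make(chosen)
        self.model_.fit(X, y)
        return self

    def _check_X(self, X) -> pd.DataFrame:
        X = pd.DataFrame(X)
        expected = list(self.feature_names_in_)
        if list(X.columns) != expected:
            missing = sorted(set(expected) - set(X.columns))
            extra = sorted(set(X.columns) - set(expected))
            if missing or extra:
                raise ValueError(f"feature schema mismatch: missing={missing} unexpected={extra}")
            X = X[expected]
        return X

    def predict_proba(self, X) -> np.ndarray:
        X = self._check_X(X)
        p1 = np.clip(self._proba(self.model_, X), 0.0, 1.0)
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    # -- introspection ---------------------------------------------------
    def nonzero_coefficients(self) -> int:
        if self.algorithm != "lasso_logistic":
            raise ValueError("coefficient counts only apply to the lasso model")
        coef = self.model_.named_steps["model"].coef_.ravel()
        return int(np.count_nonzero(coef))

    def feature_importances(self) -> pd.Series:
        if self.algorithm == "xgboost":
            imp = self.model_.feature_importances_
        elif self.algorithm == "random_forest":
            imp = self.model_.named_steps["model"].feature_importances_
        else:
            imp = np.abs(self.model_.named_steps["model"].coef_.ravel())
        return pd.Series(imp, index=self.feature_names_in_)


@dataclass
class ModelBundle:
    """One fitted classifier per configured cutoff, plus training metadata."""

    models: dict  # cutoff -> AdmissionClassifier
    algorithm: str
    feature_columns: list = field(default_factory=lambda: list(FEATURE_COLUMNS))
    training_info: dict = field(default_factory=dict)  # cutoff -> {n, admitted_frac}

    @property
    def cutoffs(self) -> list:
        return sorted(self.models)

    def schema_hash(self) -> str:
        return hashlib.sha256(",".join(self.feature_columns).encode()).hexdigest()[:16]

    def importance_table(self) -> pd.DataFrame:
        """Per-model feature importances with the feature-group labels."""
        groups = {c: g for g, cols in FEATURE_GROUPS.items() for c in cols}
        table = pd.DataFrame(
            {f"T{c}": self.models[c].feature_importances() for c in self.cutoffs}
        )
        table.insert(0, "group", [groups.get(f, "other") for f in table.index])
        return table.rename_axis("feature")

    def save(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        manifest = {
            "version": 1,
            "algorithm": self.algorithm,
            "cutoffs": self.cutoffs,
            "feature_schema_hash": self.schema_hash(),
            "feature_columns": self.feature_columns,
            "training_info": {str(k): v for k, v in self.training_info.items()},
            "hyperparameters": {str(c): self.models[c].best_params_ for c in self.cutoffs},
        }
        (path / "manifest.json").write_text(json.dumps(manifest, indent=2))
        for c, model in self.models.items():
            joblib.dump(model, path / f"model_T{c}.joblib")

    @classmethod
    def load(cls, path) -> "ModelBundle":
        path = Path(path)
        manifest = json.loads((path / "manifest.json").read_text())
        models = {c: joblib.load(path / f"model_T{c}.joblib") for c in manifest["cutoffs"]}
        return cls(
            models=models,
            algorithm=manifest["algorithm"],
            feature_columns=manifest["feature_columns"],
            training_info={int(k): v for k, v in manifest["training_info"].items()},
        )


def train_bundle(rows_by_cutoff: dict, algorithm: str = "xgboost",
                 tuning: TuningConfig | None = None, class_weight=None,
                 random_state: int = 0) -> ModelBundle:
    """Fit one classifier per cutoff from left-aligned training tables.

    ``rows_by_cutoff`` maps cutoff -> frame as produced by
    :func:`edcast.framing.build_left_aligned`. With ``tuning=None`` the
    declared default hyperparameters are used directly; passing a
    :class:`TuningConfig` runs the CV grid search.
    """
    models, info = {}, {}
    for cutoff, rows in rows_by_cutoff.items():
        y = rows["admitted"].to_numpy()
        X = rows[FEATURE_COLUMNS]
        if len(rows) < 50 or len(np.unique(y)) < 2:
            raise ValueError(
                f"cutoff {cutoff}: need >= 50 rows with both classes "
                f"(got n={len(rows)}, admitted={int(y.sum())})"
            )
        if tuning is None:
            clf = AdmissionClassifier(
                algorithm=algorithm, params=DEFAULT_PARAMS[algorithm],
                class_weight=class_weight, random_state=random_state,
            )
        else:
            clf = AdmissionClassifier(
                algorithm=algorithm, grid=tuning.grid, cv=tuning.cv,
                lasso_selection=tuning.lasso_selection,
                class_weight=class_weight, random_state=random_state,
            )
        models[cutoff] = clf.fit(X, y)
        info[cutoff] = {"n": int(len(rows)), "admitted_frac": float(y.mean())}
    return ModelBundle(models=models, algorithm=algorithm, training_info=info)


def predict_snapshot(bundle: ModelBundle, snapshot: Snapshot) -> pd.DataFrame:
    """Score every patient in a snapshot with the model for their cutoff.

    Returns a frame with visit_id, cutoff_used and p_admit.
    """
    rows = snapshot.rows
    if rows.empty:
        return pd.DataFrame(columns=["visit_id", "cutoff_used", "p_admit"])
    needed = set(rows["cutoff_minutes"].unique())
    missing = sorted(needed - set(bundle.models))
    if missing:
        raise ValueError(f"bundle has no model for cutoffs {missing}")
    out = []
    for cutoff, grp in rows.groupby("cutoff_minutes", sort=True):
        p = bundle.models[cutoff].predict_proba(grp[bundle.feature_columns])[:, 1]
        out.append(pd.DataFrame(
            {"visit_id": grp["visit_id"].to_numpy(), "cutoff_used": cutoff, "p_admit": p}
        ))
    result = pd.concat(out, ignore_index=True)
    order = {v: i for i, v in enumerate(rows["visit_id"])}
    return result.sort_values("visit_id", key=lambda s: s.map(order), kind="stable").reset_index(drop=True)


def prediction_metrics(y_true, p) -> tuple:
    """(log loss, AUROC) with probabilities clipped to [1e-15, 1-1e-15].

    AUROC is NaN for single-class targets.
    """
    y = np.asarray(y_true).astype(int)
    p = np.asarray(p, dtype=float)
    ll = float(log_loss(y, _clip(p), labels=[0, 1]))
    auroc = float(roc_auc_score(y, p)) if np.unique(y).size == 2 else float("nan")
    return ll, auroc


def calibration_bins(y_true: np.ndarray, p: np.ndarray, n_bins: int = 10) -> pd.DataFrame:
    """Equal-count calibration bins: (predicted mean, observed rate, n)."""
    order = np.argsort(p, kind="stable")
    splits = np.array_split(order, n_bins)
    rows = []
    for i, idx in enumerate(splits):
        if idx.size == 0:
            continue
        rows.append(
            {"bin": i, "predicted_mean": float(p[idx].mean()),
             "observed_rate": float(np.asarray(y_true)[idx].mean()), "n": int(idx.size)}
        )
    return pd.DataFrame(rows)


def evaluate_models(bundle: ModelBundle, test_visits, config=None) -> tuple:
    """Per-cutoff log loss, AUROC and calibration bins on held-out visits.

    Every visit whose duration exceeds a model's cutoff contributes to that
    model's evaluation, so later models are judged on the (smaller, more
    admission-heavy) populations they actually see. AUROC is NaN when the
    test rows at a cutoff are single-class.
    """
    metrics, calibration = [], {}
    for cutoff in bundle.cutoffs:
        rows = build_left_aligned(test_visits, cutoff, config)
        y = rows["admitted"].to_numpy()
        p = bundle.models[cutoff].predict_proba(rows[bundle.feature_columns])[:, 1]
        ll, auroc = prediction_metrics(y, p)
        metrics.append(
            {"cutoff": cutoff, "n": len(rows), "admitted_frac": float(y.mean()),
             "log_loss": ll, "auroc": auroc}
        )
        calibration[cutoff] = calibration_bins(y, p)
    return pd.DataFrame(metrics), calibration
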