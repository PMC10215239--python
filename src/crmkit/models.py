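"""The six classical regression families used for CRM estimation.

Linear regression, three single regression trees of decreasing depth
("fine", "medium", "coarse" — minimum leaf sizes 4/12/36), bootstrap-
aggregated trees and least-squares gradient-boosted trees (both 30
learners with eight-observation leaves).  All are exposed through one
sklearn-compatible estimator, :class:`CRMRegressor`, plus thin
module-level helpers mirroring a spec/config-driven workflow.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.ensemble import BaggingRegressor, GradientBoostingRegressor
from sklearn.linear_model import LinearRegression
from sklearn.tree import DecisionTreeRegressor
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "MODEL_KINDS",
    "ModelSpec",
    "CRMRegressor",
    "TrainedModel",
    "fit_model",
    "predict_model",
    "train_matrix",
    "save_model",
    "load_model",
    "smooth_predictions",
]

#: Minimum leaf sizes of the named single-tree presets.
TREE_LEAF_SIZES = {"tree_fine": 4, "tree_medium": 12, "tree_coarse": 36}
MODEL_KINDS = (
    "linear", "tree_fine", "tree_medium", "tree_coarse",
    "bagged_trees", "boosted_trees",
)


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one model to train."""

    kind: str
    features: tuple[str, ...]
    n_learners: int = 30
    leaf_size: int = 8
    learning_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {self.kind!r}")
        if not self.features:
            raise ValueError("feature subset must be non-empty")


class CRMRegressor(RegressorMixin, BaseEstimator):
    """Unified estimator over the six model families.

    Parameters
    ----------
    kind : one of ``MODEL_KINDS``.
    n_learners, leaf_size, learning_rate : ensemble hyperparameters
        (defaults 30 learners, 8-observation leaves, rate 0.1); ignored
        by the non-ensemble kinds.
    bootstrap : draw bootstrap resamples for bagging.  With
        ``bootstrap=False`` and ``n_learners=1`` bagging reduces exactly
        to the single-tree fit.
    clamp : clip predictions into [0, 1] (off by default; raw
        regression output may over/undershoot the label range).
    """

    def __init__(self, kind: str = "bagged_trees", n_learners: int = 30,
                 leaf_size: int = 8, learning_rate: float = 0.1,
                 bootstrap: bool = True, clamp: bool = False,
                 random_state: int = 0):
        self.kind = kind
        self.n_learners = n_learners
        self.leaf_size = leaf_size
        self.learning_rate = learning_rate
        self.bootstrap = bootstrap
        self.clamp = clamp
        self.random_state = random_state

    def _make(self):
        if self.kind == "linear":
            return LinearRegression()
        if self.kind in TREE_LEAF_SIZES:
            return DecisionTreeRegressor(
                min_samples_leaf=TREE_LEAF_SIZES[self.kind],
                random_state=self.random_state,
            )
        if self.kind == "bagged_trees":
            return BaggingRegressor(
                estimator=DecisionTreeRegressor(
                    min_samples_leaf=self.leaf_size,
                    random_state=self.random_state,
                ),
                n_estimators=self.n_learners,
                bootstrap=self.bootstrap,
                random_state=self.random_state,
            )
        if self.kind == "boosted_trees":
            return GradientBoostingRegressor(
                n_estimators=self.n_learners,
                learning_rate=self.learning_rate,
                min_samples_leaf=self.leaf_size,
                random_state=self.random_state,
            )
        raise ValueError(f"unknown model kind {self.kind!r}")

    def fit(self, X, y):
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
            Xa = X.to_numpy(dtype=float)
        else:
            Xa = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if Xa.ndim != 2 or len(Xa) != len(y):
            raise ValueError("X must be 2-D with one target per row")
        if not (np.isfinite(Xa).all() and np.isfinite(y).all()):
            raise ValueError("inputs must be finite")
        self.n_features_in_ = Xa.shape[1]
        self.model_ = self._make().fit(Xa, y)
        resid = self.model_.predict(Xa) - y
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        self.training_summary_ = {
            "n_rows": int(len(y)),
            "p_rmse": float(np.sqrt(np.mean(resid**2))),
            "p_r2": 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else float("nan"),
        }
        return self

    def predict(self, X):
        check_is_fitted(self, "model_")
        if isinstance(X, pd.DataFrame) and hasattr(self, "feature_names_in_"):
            missing = [c for c in self.feature_names_in_ if c not in X.columns]
            if missing:
                raise KeyError(f"missing feature columns: {missing}")
            X = X[list(self.feature_names_in_)]
        Xa = np.asarray(X, dtype=float)
        pred = self.model_.predict(Xa)
        if self.clamp:
            pred = np.clip(pred, 0.0, 1.0)
        return pred


@dataclass
class TrainedModel:
    """A fitted model plus its provenance (spec, training subjects)."""

    spec: ModelSpec
    regressor: CRMRegressor
    train_subjects: frozenset[str]
    summary: dict = field(default_factory=dict)

    def predict(self, rows: pd.DataFrame) -> np.ndarray:
        return predict_model(self, rows)


def fit_model(spec: ModelSpec, table: pd.DataFrame) -> TrainedModel:
    """Train one model on a labeled feature table (CRM target)."""
    if len(table) < 10:
        raise ValueError("need at least 10 training rows")
    missing = [f for f in spec.features if f not in table.columns]
    if missing:
        raise KeyError(f"unknown feature name(s): {missing}")
    reg = CRMRegressor(
        kind=spec.kind, n_learners=spec.n_learners, leaf_size=spec.leaf_size,
        learning_rate=spec.learning_rate, random_state=spec.seed,
    )
    reg.fit(table[list(spec.features)], table["crm"].to_numpy())
    subjects = frozenset(table["subject_id"]) if "subject_id" in table else frozenset()
    return TrainedModel(
        spec=spec, regressor=reg, train_subjects=subjects,
        summary=dict(reg.training_summary_),
    )


def predict_model(model: TrainedModel, rows: pd.DataFrame) -> np.ndarray:
    missing = [f for f in model.spec.features if f not in rows.columns]
    if missing:
        raise KeyError(f"unknown feature name(s): {missing}")
    return model.regressor.predict(rows[list(model.spec.features)])


def train_matrix(
    table: pd.DataFrame,
    groups: "list",
    spec: ModelSpec,
) -> dict:
    """Fit one model per training group with an otherwise identical spec.

    A group is either ``"all"`` or a decompensation-step integer; the
    per-step models are trained only on subjects of that group.
    """
    out = {}
    for g in groups:
        sub = table if g == "all" else table[table["hdd_step"] == g]
        if len(sub) == 0:
            raise ValueError(f"training group {g!r} is empty")
        out[g] = fit_model(spec, sub)
    return out


def smooth_predictions(pred: np.ndarray, window: int = 10) -> np.ndarray:
    """Optional prediction-time rolling-median smoother (beats)."""
    s = pd.Series(np.asarray(pred, dtype=float))
    return s.rolling(window, min_periods=1, center=True).median().to_numpy()


# ---------------------------------------------------------------------------
# JSON persistence: linear coefficients, or nested arrays per tree, so fitted
# state is portable and diffable without pickles.

def _tree_to_json(tree) -> dict:
    t = tree.tree_
    return {
        "children_left": t.children_left.tolist(),
        "children_right": t.children_right.tolist(),
        "feature": t.feature.tolist(),
        "threshold": t.threshold.tolist(),
        "value": t.value[:, 0, 0].tolist(),
    }


def _tree_predict(node_arrays: dict, X: np.ndarray) -> np.ndarray:
    cl = node_arrays["children_left"]
    cr = node_arrays["children_right"]
    feat = node_arrays["feature"]
    thr = node_arrays["threshold"]
    val = node_arrays["value"]
    out = np.empty(len(X))
    for r, row in enumerate(X):
        i = 0
        while cl[i] != -1:
            i = cl[i] if row[feat[i]] <= thr[i] else cr[i]
        out[r] = val[i]
    return out


def save_model(model: TrainedModel, path: "str | Path") -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    spec = {
        "kind": model.spec.kind, "features": list(model.spec.features),
        "n_learners": model.spec.n_learners, "leaf_size": model.spec.leaf_size,
        "learning_rate": model.spec.learning_rate, "seed": model.spec.seed,
    }
    inner = model.regressor.model_
    if model.spec.kind == "linear":
        state = {"intercept": float(inner.intercept_),
                 "coef": inner.coef_.tolist()}
    elif model.spec.kind in TREE_LEAF_SIZES:
        state = {"tree": _tree_to_json(inner)}
    elif model.spec.kind == "bagged_trees":
        state = {"trees": [_tree_to_json(t) for t in inner.estimators_],
                 "features_per_tree": [f.tolist() for f in inner.estimators_features_]}
    else:  # boosted_trees
        init = float(inner.init_.predict(np.zeros((1, len(spec["features"]))))[0])
        state = {"init": init, "learning_rate": model.spec.learning_rate,
                 "trees": [_tree_to_json(t[0]) for t in inner.estimators_]}
    path.write_text(json.dumps({
        "spec": spec,
        "train_subjects": sorted(model.train_subjects),
        "summary": model.summary,
        "state": state,
    }))
    return path


class JSONModel:
    """Predictor reconstructed from a :func:`save_model` file."""

    def __init__(self, payload: dict):
        self.spec = ModelSpec(
            kind=payload["spec"]["kind"],
            features=tuple(payload["spec"]["features"]),
            n_learners=payload["spec"]["n_learners"],
            leaf_size=payload["spec"]["leaf_size"],
            learning_rate=payload["spec"]["learning_rate"],
            seed=payload["spec"]["seed"],
        )
        self.train_subjects = frozenset(payload["train_subjects"])
        self.summary = payload["summary"]
        self._state = payload["state"]

    def predict(self, rows) -> np.ndarray:
        if isinstance(rows, pd.DataFrame):
            missing = [f for f in self.spec.features if f not in rows.columns]
            if missing:
                raise KeyError(f"unknown feature name(s): {missing}")
            X = rows[list(self.spec.features)].to_numpy(dtype=float)
        else:
            X = np.asarray(rows, dtype=float)
        s = self._state
        if self.spec.kind == "linear":
            return s["intercept"] + X @ np.asarray(s["coef"])
        if self.spec.kind in TREE_LEAF_SIZES:
            return _tree_predict(s["tree"], X)
        if self.spec.kind == "bagged_trees":
            preds = [
                _tree_predict(t, X[:, cols])
                for t, cols in zip(s["trees"], s["features_per_tree"])
            ]
            return np.mean(preds, axis=0)
        acc = np.full(len(X), s["init"])
        for t in s["trees"]:
            acc = acc + s["learning_rate"] * _tree_predict(t, X)
        return acc


def load_model(path: "str | Path") -> JSONModel:
    return JSONModel(json.loads(Path(path).read_text()))
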