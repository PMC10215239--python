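"""Dual regression metrics and the subgroup cross-evaluation matrix.

Two metric families are reported for predicted vs. calculated CRM:

* *perfect* regression — residuals about the identity line y = x,
  giving P-RMSE and P-R² (P-R² can be negative; a model must predict
  on the 1:1 line to score well);
* *conventional* regression — residuals about the least-squares line
  y = m x + b, giving RMSE, R², and the fitted slope/intercept.

By construction RMSE <= P-RMSE and P-R² <= R²: the fitted line can
never do worse than the identity line it generalises.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MetricSet",
    "perfect_metrics",
    "linear_metrics",
    "compute_metrics",
    "evaluate_matrix",
]


@dataclass(frozen=True)
class MetricSet:
    p_rmse: float
    p_r2: float
    rmse: float
    r2: float
    slope: float
    intercept: float
    n: int

    def as_dict(self) -> dict:
        return asdict(self)


def _check(y_true, y_pred, min_n=1):
    y = np.asarray(y_true, dtype=float)
    yhat = np.asarray(y_pred, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1 or len(y) < min_n:
        raise ValueError(f"need equal-length 1-D vectors of >= {min_n} points")
    return y, yhat


def perfect_metrics(y_true, y_pred) -> tuple[float, float]:
    """(P-RMSE, P-R²) about the identity line y = x.

    P-RMSE = sqrt(mean((yhat - y)^2)); P-R² = 1 - SS_res/SS_tot with
    residuals taken about y = x.  For a constant ``y_true`` the
    explained-variance denominator vanishes: P-R² is returned as NaN
    with a warning while P-RMSE is still well-defined.
    """
    y, yhat = _check(y_true, y_pred)
    ss_res = float(np.sum((yhat - y) ** 2))
    p_rmse = float(np.sqrt(ss_res / len(y)))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        warnings.warn("constant y_true: P-R2 is undefined (NaN)", stacklevel=2)
        return p_rmse, float("nan")
    return p_rmse, 1.0 - ss_res / ss_tot


def linear_metrics(y_true, y_pred) -> tuple[float, float, float, float]:
    """(RMSE, R², slope, intercept) of the least-squares fit of
    predictions on calculated CRM.

    R² is the squared Pearson correlation; RMSE is the root-mean-square
    residual about the fitted line.
    """
    y, yhat = _check(y_true, y_pred, min_n=3)
    if np.ptp(y) == 0:
        raise ValueError("constant y_true: conventional regression undefined")
    fit = stats.linregress(y, yhat)
    resid = yhat - (fit.slope * y + fit.intercept)
    rmse = float(np.sqrt(np.mean(resid**2)))
    return rmse, float(fit.rvalue**2), float(fit.slope), float(fit.intercept)


def compute_metrics(y_true, y_pred) -> MetricSet:
    """Both metric families in one record."""
    p_rmse, p_r2 = perfect_metrics(y_true, y_pred)
    rmse, r2, m, b = linear_metrics(y_true, y_pred)
    return MetricSet(p_rmse=p_rmse, p_r2=p_r2, rmse=rmse, r2=r2,
                     slope=m, intercept=b, n=len(np.asarray(y_true)))


def evaluate_matrix(
    models: dict,
    test_tables: "dict[object, pd.DataFrame]",
    check_leakage: bool = True,
) -> "dict[tuple, MetricSet]":
    """Cross-evaluate trained models against per-group blind test tables.

    ``models`` maps a training group (``"all"`` or a step integer) to a
    fitted model exposing ``predict(rows)`` and ``train_subjects``;
    ``test_tables`` maps a test group to its labeled feature table.
    Beats are pooled within each test group.  Returns a cell per
    (training group, test group) pair.  Subject-level overlap between a
    model's training set and any test table is treated as leakage and
    rejected.
    """
    cells: dict[tuple, MetricSet] = {}
    for tg, tbl in test_tables.items():
        if len(tbl) == 0:
            raise ValueError(f"test group {tg!r} is empty")
    for mg, model in models.items():
        for tg, tbl in test_tables.items():
            if check_leakage:
                overlap = model.train_subjects & set(tbl["subject_id"])
                if overlap:
                    raise ValueError(
                        f"subject leakage between train group {mg!r} and "
                        f"test group {tg!r}: {sorted(overlap)[:5]}"
                    )
            pred = model.predict(tbl)
            cells[(mg, tg)] = compute_metrics(tbl["crm"].to_numpy(), pred)
    return cells


def matrix_frame(cells: "dict[tuple, MetricSet]", metric: str) -> pd.DataFrame:
    """Pivot one metric of a subgroup matrix into rows = training group,
    columns = test group (the heat-map layout)."""
    rows = sorted({k[0] for k in cells}, key=str)
    cols = sorted({k[1] for k in cells}, key=str)
    return pd.DataFrame(
        [[getattr(cells[(r, c)], metric) for c in cols] for r in rows],
        index=rows, columns=cols,
    )
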