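"""Minimal-redundancy-maximal-relevance (MRMR) feature ranking.

Greedy forward selection: the first pick maximises relevance (mutual
information with the target); each later pick maximises
``relevance - mean MI with already-selected features`` (difference
scheme, default) or the corresponding quotient.  Mutual information is
the plug-in estimate on a joint histogram with equal-frequency binning
of each variable, which makes the ranking invariant to strictly
monotone transforms of any single feature.  Ties break deterministically
by column (registry) order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = ["mutual_information", "rank_mrmr", "RankingResult", "MRMRSelector"]


def _equal_frequency_bins(x: np.ndarray, bins: int) -> np.ndarray:
    """Digitize ``x`` into at most ``bins`` equal-frequency bins."""
    edges = np.quantile(x, np.linspace(0.0, 1.0, bins + 1)[1:-1])
    return np.searchsorted(edges, x, side="right")


def mutual_information(x, y, bins: int = 8) -> float:
    """Plug-in mutual information (nats) between two real vectors.

    Both variables are discretised into ``bins`` equal-frequency bins;
    a constant vector collapses to a single bin and yields MI = 0.
    Symmetric in its arguments and nonnegative.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("x and y must be equal-length 1-D vectors, n >= 2")
    if bins < 1:
        raise ValueError("bins must be >= 1")
    bx = _equal_frequency_bins(x, bins)
    by = _equal_frequency_bins(y, bins)
    n = len(x)
    joint = np.zeros((bx.max() + 1, by.max() + 1))
    np.add.at(joint, (bx, by), 1.0)
    pxy = joint / n
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    mask = pxy > 0
    mi = float(np.sum(pxy[mask] * np.log(pxy[mask] / (px @ py)[mask])))
    return max(mi, 0.0)


@dataclass
class RankingResult:
    """MRMR ranking: ``names[i]`` was the *i*-th pick with greedy score
    ``scores[i]``, relevance ``relevance[i]`` and mean redundancy
    against the previously selected features ``redundancy[i]``."""

    names: list[str]
    scores: list[float]
    relevance: list[float]
    redundancy: list[float]

    def top(self, k: int) -> list[str]:
        return self.names[:k]

    def rank_of(self, name: str) -> int:
        """1-based rank of a feature."""
        return self.names.index(name) + 1

    def to_json(self, path: "str | Path") -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        records = [
            {"name": n, "score": s, "relevance": r, "redundancy": d}
            for n, s, r, d in zip(
                self.names, self.scores, self.relevance, self.redundancy
            )
        ]
        path.write_text(json.dumps(records, indent=1))
        return path


def default_bins(n: int) -> int:
    """Equal-frequency bin count: ceil(sqrt(n)), capped at 64."""
    return min(int(np.ceil(np.sqrt(n))), 64)


def rank_mrmr(
    X: "pd.DataFrame | np.ndarray",
    y,
    k: "int | None" = None,
    scheme: str = "difference",
    bins: "int | None" = None,
    feature_names: "list[str] | None" = None,
) -> RankingResult:
    """Rank features by greedy MRMR forward selection.

    Parameters
    ----------
    X : DataFrame or 2-D array of features (column order = tie-break order).
    y : target vector (continuous CRM labels; binned like the features).
    k : how many features to rank (default: all).
    scheme : ``difference`` (relevance - mean redundancy, default) or
        ``quotient`` (relevance / mean redundancy).
    bins : histogram bins; default ceil(sqrt(n)) capped at 64.
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xa = X.to_numpy(dtype=float)
    else:
        Xa = np.asarray(X, dtype=float)
        names = feature_names or [f"f{i}" for i in range(Xa.shape[1])]
    y = np.asarray(y, dtype=float)
    n, p = Xa.shape
    if k is None:
        k = p
    if k <= 0:
        raise ValueError("k must be positive")
    if k > p:
        raise ValueError(f"k={k} exceeds the {p} available features")
    if scheme not in ("difference", "quotient"):
        raise ValueError("scheme must be 'difference' or 'quotient'")
    if bins is None:
        bins = default_bins(n)

    relevance = np.array([mutual_information(Xa[:, j], y, bins) for j in range(p)])
    pair_mi = np.full((p, p), np.nan)  # lazily filled, symmetric

    selected: list[int] = []
    scores: list[float] = []
    reds: list[float] = []
    remaining = list(range(p))

    first = int(np.argmax(relevance))  # argmax is stable -> registry order
    selected.append(first)
    scores.append(float(relevance[first]))
    reds.append(0.0)
    remaining.remove(first)

    while len(selected) < k:
        last = selected[-1]
        for j in remaining:
            if np.isnan(pair_mi[last, j]):
                m = mutual_information(Xa[:, last], Xa[:, j], bins)
                pair_mi[last, j] = pair_mi[j, last] = m
        red = np.array([np.nanmean(pair_mi[selected, j]) for j in remaining])
        rel = relevance[remaining]
        if scheme == "difference":
            crit = rel - red
        else:
            crit = rel / np.maximum(red, 1e-12)
        pick_pos = int(np.argmax(crit))
        j = remaining[pick_pos]
        selected.append(j)
        scores.append(float(crit[pick_pos]))
        reds.append(float(red[pick_pos]))
        remaining.remove(j)

    return RankingResult(
        names=[names[j] for j in selected],
        scores=scores,
        relevance=[float(relevance[j]) for j in selected],
        redundancy=reds,
    )


class MRMRSelector(SelectorMixin, BaseEstimator):
    """scikit-learn transformer selecting the top-``k`` MRMR features.

    Examples
    --------
    >>> sel = MRMRSelector(k=10).fit(X, y)
    >>> X10 = sel.transform(X)
    >>> sel.ranking_.names[:3]
    """

    def __init__(self, k: int = 10, scheme: str = "difference",
                 bins: "int | None" = None):
        self.k = k
        self.scheme = scheme
        self.bins = bins

    def fit(self, X, y):
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
            names = list(X.columns)
            Xa = X.to_numpy(dtype=float)
        else:
            Xa = np.asarray(X, dtype=float)
            names = [f"f{i}" for i in range(Xa.shape[1])]
        self.n_features_in_ = Xa.shape[1]
        self.ranking_ = rank_mrmr(
            Xa, y, k=min(self.k, Xa.shape[1]), scheme=self.scheme,
            bins=self.bins, feature_names=names,
        )
        top = set(self.ranking_.names[: self.k])
        self.support_ = np.array([n in top for n in names])
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_

    def __sklearn_tags__(self):
        tags = super().__sklearn_tags__()
        tags.target_tags.required = True
        return tags
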