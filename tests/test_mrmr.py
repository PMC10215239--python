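"""MRMR ranking: mutual information estimator and greedy selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from crmkit import mrmr
from crmkit.mrmr import MRMRSelector, mutual_information, rank_mrmr


# --- independent oracles ---------------------------------------------------

def oracle_bin(x, bins):
    """Equal-frequency binning by explicit quantile comparison."""
    qs = [np.quantile(x, q) for q in np.linspace(0, 1, bins + 1)[1:-1]]
    out = np.zeros(len(x), dtype=int)
    for i, v in enumerate(x):
        b = 0
        for edge in qs:
            if v > edge:
                b += 1
        out[i] = b
    return out


def oracle_mi(x, y, bins):
    """Plug-in MI by explicit double loop over the joint histogram."""
    bx, by = oracle_bin(x, bins), oracle_bin(y, bins)
    n = len(x)
    mi = 0.0
    for i in range(bins):
        for j in range(bins):
            nij = np.sum((bx == i) & (by == j))
            if nij == 0:
                continue
            pij = nij / n
            pi = np.sum(bx == i) / n
            pj = np.sum(by == j) / n
            mi += pij * np.log(pij / (pi * pj))
    return mi


def oracle_greedy(X, y, bins, scheme="difference"):
    """Exhaustive greedy MRMR: recompute the criterion for every
    candidate at every step using the oracle MI."""
    p = X.shape[1]
    rel = [oracle_mi(X[:, j], y, bins) for j in range(p)]
    selected = [int(np.argmax(rel))]
    while len(selected) < p:
        best, best_c = None, -np.inf
        for j in range(p):
            if j in selected:
                continue
            red = np.mean([oracle_mi(X[:, j], X[:, s], bins) for s in selected])
            c = rel[j] - red if scheme == "difference" else rel[j] / max(red, 1e-12)
            if c > best_c:
                best, best_c = j, c
        selected.append(best)
    return selected


# --- mutual information ----------------------------------------------------

class TestMutualInformation:
    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(42)
        x = rng.normal(size=200)
        y = 0.6 * x + rng.normal(size=200)
        assert mutual_information(x, y, bins=4) == pytest.approx(
            oracle_mi(x, y, 4), abs=1e-12
        )

    def test_identity_equals_marginal_entropy(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=400)
        bx = oracle_bin(x, 8)
        counts = np.bincount(bx) / len(x)
        entropy = -np.sum(counts[counts > 0] * np.log(counts[counts > 0]))
        assert mutual_information(x, x, bins=8) == pytest.approx(entropy, abs=1e-12)

    def test_independent_vectors_near_zero(self):
        rng = np.random.default_rng(7)
        x, y = rng.normal(size=5000), rng.normal(size=5000)
        assert mutual_information(x, y, bins=8) < 0.05

    def test_constant_vector_gives_zero(self):
        assert mutual_information(np.ones(50), np.arange(50.0), bins=4) == 0.0

    @given(seed=st.integers(0, 100))
    def test_symmetric_and_nonnegative(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=60), rng.normal(size=60)
        a = mutual_information(x, y, bins=5)
        assert a == pytest.approx(mutual_information(y, x, bins=5), abs=1e-12)
        assert a >= 0


# --- greedy ranking --------------------------------------------------------

def make_table(n=240, seed=5):
    rng = np.random.default_rng(seed)
    y = rng.uniform(0, 1, n)
    X = np.column_stack([
        y + 0.1 * rng.normal(size=n),          # strong signal
        y + 0.12 * rng.normal(size=n),         # redundant with f0
        -y + 0.3 * rng.normal(size=n),         # weaker, anti-correlated
        rng.normal(size=n),                    # noise
        y**2 + 0.2 * rng.normal(size=n),       # nonlinear signal
        rng.normal(size=n),                    # noise
    ])
    return X, y


class TestRankMRMR:
    @pytest.mark.parametrize("scheme", ["difference", "quotient"])
    def test_matches_exhaustive_greedy_oracle(self, scheme):
        X, y = make_table()
        bins = 6
        r = rank_mrmr(X, y, scheme=scheme, bins=bins)
        expected = oracle_greedy(X, y, bins, scheme)
        got = [int(n[1:]) for n in r.names]
        assert got == expected

    def test_first_pick_maximizes_relevance(self):
        X, y = make_table()
        r = rank_mrmr(X, y, k=1, bins=6)
        rels = [mutual_information(X[:, j], y, 6) for j in range(X.shape[1])]
        assert r.names == [f"f{int(np.argmax(rels))}"]
        assert r.redundancy == [0.0]

    def test_duplicate_feature_penalized(self):
        X, y = make_table()
        Xd = np.column_stack([X[:, 0], X[:, 0], X[:, 2], X[:, 4]])
        r = rank_mrmr(Xd, y, bins=6)
        assert r.names[0] == "f0"
        assert r.names[1] != "f1"  # exact duplicate is not picked next

    def test_monotone_transform_invariance(self):
        X, y = make_table()
        r0 = rank_mrmr(pd.DataFrame(X, columns=list("abcdef")), y, bins=6)
        Xt = X.copy()
        Xt[:, 0] = np.exp(Xt[:, 0])          # strictly increasing
        Xt[:, 4] = np.log1p(Xt[:, 4] - Xt[:, 4].min())
        r1 = rank_mrmr(pd.DataFrame(Xt, columns=list("abcdef")), y, bins=6)
        assert r0.names == r1.names
        assert np.allclose(r0.scores, r1.scores)

    def test_names_are_permutation_and_k_validated(self):
        X, y = make_table()
        r = rank_mrmr(X, y)
        assert sorted(r.names) == [f"f{i}" for i in range(6)]
        with pytest.raises(ValueError):
            rank_mrmr(X, y, k=0)
        with pytest.raises(ValueError):
            rank_mrmr(X, y, k=7)

    def test_ranking_json_roundtrip(self, tmp_path):
        X, y = make_table()
        r = rank_mrmr(X, y, bins=6)
        path = r.to_json(tmp_path / "r.json")
        import json

        rec = json.loads(path.read_text())
        assert [d["name"] for d in rec] == r.names
        assert rec[0]["redundancy"] == 0.0


class TestSelector:
    def test_sklearn_selector_contract(self):
        X, y = make_table()
        df = pd.DataFrame(X, columns=[f"c{i}" for i in range(6)])
        sel = MRMRSelector(k=3, bins=6).fit(df, y)
        assert sel.get_support().sum() == 3
        assert sel.transform(df).shape == (len(df), 3)
        assert set(sel.get_feature_names_out()) == set(sel.ranking_.top(3))

    def test_pipeline_composition(self):
        from sklearn.pipeline import Pipeline
        from crmkit.models import CRMRegressor

        X, y = make_table()
        pipe = Pipeline([
            ("select", MRMRSelector(k=2, bins=6)),
            ("model", CRMRegressor(kind="linear")),
        ])
        pred = pipe.fit(X, y).predict(X)
        assert pred.shape == y.shape
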