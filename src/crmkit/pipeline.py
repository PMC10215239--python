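"""End-to-end experiment orchestration.

Simulate a balanced cohort, split it 8:4 at the subject level, extract
per-beat features, rank them by MRMR, train the model families on
top-k subsets, and evaluate with both metric families.  A run is fully
determined by its :class:`RunConfig` (stamped into every artifact as a
config hash plus seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluate, features, models, mrmr, synth

__all__ = ["RunConfig", "split_cohort", "build_cohort_tables", "run_experiment"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything needed to reproduce one experiment."""

    seed: int = 0
    # cohort
    n_per_group: int = 12
    groups: tuple = (4, 5, 6, 7, 8)
    train_per_group: int = 8
    test_per_group: int = 4
    noise_sd: float = 1.0
    wander_amp: float = 2.0
    # protocol
    n_steps: int = 9
    min_pressure: float = -100.0
    step_duration: float = 300.0
    fs: float = 500.0
    # filtering
    cutoff: float = 20.0
    n_taps: int = 101
    # selection / models
    mrmr_scheme: str = "difference"
    mrmr_bins: "int | None" = None
    top_k: tuple = (15, 10, 5, 1)
    model_kinds: tuple = models.MODEL_KINDS
    selected_kind: str = "bagged_trees"
    selected_k: int = 10
    clamp: bool = False
    # output
    out_dir: "str | None" = None

    def validate(self, for_split: bool = False) -> "RunConfig":
        if for_split and self.n_per_group < self.train_per_group + self.test_per_group:
            raise ValueError("n_per_group must cover the train+test split")
        if not self.groups:
            raise ValueError("groups must be non-empty")
        if any(k <= 0 or k > len(features.FEATURE_NAMES) for k in self.top_k):
            raise ValueError("top_k values must lie in [1, 54]")
        unknown = set(self.model_kinds) - set(models.MODEL_KINDS)
        if unknown:
            raise ValueError(f"unknown model kinds: {sorted(unknown)}")
        if self.selected_kind not in self.model_kinds:
            raise ValueError("selected_kind must be among model_kinds")
        if max(self.groups) > self.n_steps:
            raise ValueError("groups exceed the protocol length")
        return self

    def to_dict(self) -> dict:
        # out_dir is excluded: where artifacts land does not alter the
        # scientific identity (or hash) of a run
        d = asdict(self)
        d.pop("out_dir")
        d["groups"] = list(self.groups)
        d["top_k"] = list(self.top_k)
        d["model_kinds"] = list(self.model_kinds)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: "str | Path") -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("groups", "top_k", "model_kinds"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw).validate()


def split_cohort(
    subjects: list, train_per_group: int, test_per_group: int, seed: int = 0
) -> tuple[list, list]:
    """Disjoint subject-level train/test split, balanced per HDD group."""
    rng = np.random.default_rng(seed)
    by_group: dict[int, list] = {}
    for s in subjects:
        by_group.setdefault(s.hdd_step, []).append(s)
    train, test = [], []
    for g in sorted(by_group):
        members = by_group[g]
        need = train_per_group + test_per_group
        if len(members) < need:
            raise ValueError(
                f"group {g} has {len(members)} subjects, needs {need}"
            )
        order = rng.permutation(len(members))
        train += [members[i] for i in order[:train_per_group]]
        test += [members[i] for i in order[train_per_group:need]]
    return train, test


def build_cohort_tables(config: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate, split, and featurise: returns (train, test) tables."""
    config.validate(for_split=True)
    protocol = synth.make_protocol(
        config.n_steps, config.min_pressure, config.step_duration
    )
    cohort = synth.sample_cohort(
        config.n_per_group, config.groups, seed=config.seed,
        noise_sd=config.noise_sd, wander_amp=config.wander_amp,
    )
    train_subj, test_subj = split_cohort(
        cohort, config.train_per_group, config.test_per_group,
        seed=config.seed + 1,
    )

    def featurise(subjects):
        sessions = [
            synth.simulate_session(s, protocol, fs=config.fs) for s in subjects
        ]
        return features.build_table(
            sessions, cutoff=config.cutoff, n_taps=config.n_taps
        )

    return featurise(train_subj), featurise(test_subj)


def _metric_pair(model: models.TrainedModel, table: pd.DataFrame) -> dict:
    p_rmse, p_r2 = evaluate.perfect_metrics(
        table["crm"].to_numpy(), model.predict(table)
    )
    return {"p_rmse": p_rmse, "p_r2": p_r2}


def run_experiment(config: RunConfig) -> dict:
    """Run the full study pipeline and return the report bundle.

    The bundle contains the model-by-top-k sweep grid, the per-group
    metrics of the selected all-step model, the per-group top-10
    rankings with rank shifts against the all-step ranking, and the
    subgroup cross-evaluation matrices.  When ``config.out_dir`` is
    set, artifacts are also written there as JSON/CSV.
    """
    config.validate()
    train, test = build_cohort_tables(config)
    X_train = train[features.FEATURE_NAMES]
    y_train = train["crm"].to_numpy()

    ranking = mrmr.rank_mrmr(
        X_train, y_train, scheme=config.mrmr_scheme, bins=config.mrmr_bins
    )

    # --- model x top-k sweep (Table 2 analog) -----------------------------
    sweep = []
    for k in config.top_k:
        feats = tuple(ranking.top(k))
        for kind in config.model_kinds:
            spec = models.ModelSpec(kind=kind, features=feats, seed=config.seed)
            tm = models.fit_model(spec, train)
            sweep.append({
                "kind": kind, "k": k,
                "train": {"p_rmse": tm.summary["p_rmse"],
                          "p_r2": tm.summary["p_r2"]},
                "test": _metric_pair(tm, test),
            })

    # --- selected model, per-group metrics (Table 3 analog) ---------------
    sel_feats = tuple(ranking.top(config.selected_k))
    sel_spec = models.ModelSpec(
        kind=config.selected_kind, features=sel_feats, seed=config.seed
    )
    sel_model = models.fit_model(sel_spec, train)
    per_group = {}
    for g in config.groups:
        sub = test[test["hdd_step"] == g]
        ms = evaluate.compute_metrics(sub["crm"].to_numpy(), sel_model.predict(sub))
        per_group[str(g)] = ms.as_dict()

    # --- per-group rankings with rank shifts (Table 4 analog) -------------
    rankings = {"all": ranking}
    for g in config.groups:
        sub = train[train["hdd_step"] == g]
        rankings[str(g)] = mrmr.rank_mrmr(
            sub[features.FEATURE_NAMES], sub["crm"].to_numpy(),
            scheme=config.mrmr_scheme, bins=config.mrmr_bins,
        )
    top10 = {}
    all_rank = {n: i + 1 for i, n in enumerate(ranking.names)}
    for key, r in rankings.items():
        top10[key] = [
            {"rank": i + 1, "name": n, "shift": all_rank[n] - (i + 1)}
            for i, n in enumerate(r.top(10))
        ]

    # --- subgroup cross-evaluation (Fig. 4 analog) ------------------------
    group_models = {
        "all": sel_model,
        **{
            g: models.fit_model(
                models.ModelSpec(
                    kind=config.selected_kind,
                    features=tuple(rankings[str(g)].top(config.selected_k)),
                    seed=config.seed,
                ),
                train[train["hdd_step"] == g],
            )
            for g in config.groups
        },
    }
    test_tables = {g: test[test["hdd_step"] == g] for g in config.groups}
    cells = evaluate.evaluate_matrix(group_models, test_tables)
    matrices = {
        metric: {
            str(row): {str(col): val for col, val in cols.items()}
            for row, cols in
            evaluate.matrix_frame(cells, metric).to_dict(orient="index").items()
        }
        for metric in ("p_r2", "p_rmse")
    }

    bundle = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_train_rows": int(len(train)),
        "n_test_rows": int(len(test)),
        "exclusions": {
            "train": train.attrs.get("exclusions"),
            "test": test.attrs.get("exclusions"),
        },
        "ranking_all": ranking.names,
        "sweep": sweep,
        "per_group_metrics": per_group,
        "top10_rankings": top10,
        "subgroup_matrices": matrices,
    }

    if config.out_dir:
        out = Path(config.out_dir)
        (out / "reports").mkdir(parents=True, exist_ok=True)
        (out / "reports" / "run.json").write_text(
            json.dumps(bundle, indent=1, sort_keys=True)
        )
        (out / "rankings").mkdir(exist_ok=True)
        for key, r in rankings.items():
            r.to_json(out / "rankings" / f"ranking_{key}.json")
        (out / "models").mkdir(exist_ok=True)
        for g, tm in group_models.items():
            models.save_model(tm, out / "models" / f"model_{g}.json")
        pd.DataFrame(sweep).to_json(out / "reports" / "sweep.json", orient="records")
        features.export_registry(out / "reports" / "feature_registry.json")
    return bundle
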