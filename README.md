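# crmkit

Explainable estimation of the **compensatory reserve measurement (CRM)**
from arterial pulse waveforms.

CRM is a 0–1 triage index of how much physiological compensation a
patient has left before hemodynamic decompensation from blood loss: 1 at
baseline, 0 at the threshold of decompensated shock. In lower-body
negative pressure (LBNP) experiments — the standard safe model of
progressive central hypovolemia — the reference label at chamber
pressure `LBNP` is

```
CRM = 1 − LBNP / LBNP_HDD
```

where `LBNP_HDD` is the pressure at which that subject decompensates.
Instead of an opaque deep network, `crmkit` estimates CRM from named
morphological features of each arterial pulse, so the waveform elements
driving a prediction stay inspectable:

1. **Simulate** an LBNP cohort: a 9-step staircase protocol (0 →
   −100 mmHg, 5 min/step), subject-specific decompensation steps 4–8,
   and per-beat pulse morphology whose pulse pressure, heart period and
   half-rise→inflection timing shrink monotonically as reserve is
   exhausted (the human datasets this pipeline targets are
   access-restricted, so a fully characterised synthetic cohort stands
   in; see `docs/methods.md`).
2. **Preprocess**: zero-phase windowed-sinc FIR lowpass, foot-to-foot
   beat segmentation from first-derivative peaks, and location of the
   four pulse landmarks — foot (A), half-rise (B), systolic peak (C)
   and first post-systolic inflection (D). Beats without a post-peak
   inflection are excluded; with several, only the first is tracked.
3. **Featurise**: a registry-driven catalogue of 54 per-beat features
   (7 individual, 6 time, 5 average-pressure, 5 area, 10 normalized,
   18 inflection-re-referenced "NODIA", 3 slope), including HRIP, the
   half-rise→inflection delay.
4. **Select** features by minimal-redundancy–maximal-relevance (MRMR)
   greedy ranking on equal-frequency-binned mutual information.
5. **Model** with six classical regression families — linear, fine /
   medium / coarse trees, bagged trees and boosted trees (ensembles:
   30 learners, 8-observation leaves) — over top-{15, 10, 5, 1}
   feature subsets, including per-decompensation-group models.
6. **Evaluate** with *perfect* regression metrics (P-RMSE, P-R²:
   residuals about the identity line y = x) alongside conventional
   linear-fit RMSE/R², and cross-evaluate per-group models against
   every test subgroup.

The selection and regression stages are scikit-learn estimators
(`MRMRSelector`, `CRMRegressor`) and compose with sklearn pipelines and
model selection.

## Worked example

```python
from crmkit import ModelSpec, RunConfig, fit_model, perfect_metrics, rank_mrmr
from crmkit.features import FEATURE_NAMES
from crmkit.pipeline import build_cohort_tables

cfg = RunConfig(seed=1, n_per_group=6, train_per_group=4, test_per_group=2,
                step_duration=30.0)
train, test = build_cohort_tables(cfg)
print(f"{len(train)} training beats from "
      f"{train['subject_id'].nunique()} subjects")

ranking = rank_mrmr(train[FEATURE_NAMES], train["crm"].to_numpy())
print("top 5 MRMR features:", ", ".join(ranking.top(5)))

model = fit_model(ModelSpec("bagged_trees", tuple(ranking.top(10)), seed=1),
                  train)
p_rmse, p_r2 = perfect_metrics(test["crm"].to_numpy(), model.predict(test))
print(f"blind-test P-RMSE = {p_rmse:.3f}, P-R2 = {p_r2:.3f}")
```

prints

```
4778 training beats from 20 subjects
top 5 MRMR features: PPI, t_sys_dec, PP, dec_area, sys_pressure
blind-test P-RMSE = 0.169, P-R2 = 0.756
```

Every row of the feature table is one retained beat with its subject
id, protocol step, CRM label, and the 54 features. The ranking puts the
beat-interval and pulse-pressure family first on this small cohort; the
bagged-trees model trained on the top 10 features predicts CRM for
beats from subjects it never saw with a root-mean-square error of 0.169
about the identity line, explaining 76% of the label variance without
any slope/intercept adjustment (that is what the "perfect" metrics
measure).

The same pipeline is scriptable from the shell:

```sh
crmkit run-all --seed 1 --out runs/demo          # full experiment bundle
crmkit simulate --out runs/demo --seed 1         # or stage by stage
crmkit extract  --waveforms runs/demo/waveforms --out runs/demo/features.csv
crmkit rank     --features runs/demo/features.csv --out runs/demo/ranking.json
```

`run-all` writes a report bundle (model × top-k sweep, per-subgroup
metrics, per-group top-10 rankings with rank shifts, and the
train-group × test-group heat-map matrices), each artifact stamped with
the config hash and seed.

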