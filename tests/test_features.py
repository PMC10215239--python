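"""The 54-feature catalogue: registry, formulas, table assembly."""

import numpy as np
import pytest
from scipy import stats

from crmkit import features, preprocess, synth
from crmkit.features import CATEGORY_COUNTS, FEATURE_NAMES, REGISTRY
from crmkit.preprocess import BeatLandmarks, BeatSegment
from conftest import FS, analytic_shape


def manual_landmarks(iB, iC, iD, n):
    return BeatLandmarks(iA=0, iB=iB, iC=iC, iD=iD, iA_next=n, valid=True)


class TestRegistry:
    def test_partition_counts(self):
        counts = {}
        for f in REGISTRY:
            counts[f.category] = counts.get(f.category, 0) + 1
        assert counts == CATEGORY_COUNTS
        assert sum(counts.values()) == 54

    def test_names_unique_and_exported(self, tmp_path):
        assert len(set(FEATURE_NAMES)) == 54
        path = features.export_registry(tmp_path / "reg.json")
        import json

        reg = json.loads(path.read_text())
        assert [r["name"] for r in reg] == FEATURE_NAMES


class TestExtract:
    def test_every_valid_beat_yields_54_features(self, quiet_subject):
        x = synth.synth_beat(quiet_subject, 0.8, FS)
        lm = preprocess.locate_landmarks(BeatSegment(0, len(x), x), FS)
        out = features.extract_features(BeatSegment(0, len(x), x), lm, FS)
        assert set(out) == set(FEATURE_NAMES)
        assert all(np.isfinite(v) for v in out.values())

    def test_rectangular_phase_area_and_average(self):
        # diastolic phase held at a constant pressure c: area = c*T, avg = c
        fs, c = 100.0, 64.0
        rise = np.linspace(50, 120, 20)
        fall = np.linspace(120, c, 30)
        flat = np.full(51, c)
        p = np.concatenate([rise, fall, flat])
        lm = manual_landmarks(iB=10, iC=19, iD=49, n=len(p))
        out = features.extract_features(BeatSegment(0, len(p), p), lm, fs)
        t_dia = (len(p) - 1 - 49) / fs
        assert out["t_dia"] == pytest.approx(t_dia)
        assert out["dia_area"] == pytest.approx(c * t_dia)
        assert out["avg_dia"] == pytest.approx(c)

    def test_beat_at_inflection_pressure_zeroes_nodia(self):
        p = np.full(80, 93.0)
        lm = manual_landmarks(iB=10, iC=30, iD=50, n=80)
        with np.errstate(invalid="ignore"):
            out = features.extract_features(BeatSegment(0, 80, p), lm, 100.0)
        for name in FEATURE_NAMES:
            if "nodia" in name:
                assert out[name] == 0.0

    def test_invalid_beat_rejected(self):
        lm = BeatLandmarks(0, 0, 0, 0, 10, valid=False)
        with pytest.raises(ValueError):
            features.extract_features(
                BeatSegment(0, 10, np.zeros(10)), lm, FS
            )

    def test_areas_match_oversampled_riemann_oracle(self, quiet_subject):
        """Trapezoids on the sampled beat vs midpoint Riemann sums of the
        continuous model at 10x oversampling, within 1%."""
        crm = 0.7
        params = synth.beat_shape_params(quiet_subject, crm)
        s = analytic_shape(params)
        x = synth.synth_beat(quiet_subject, crm, FS)
        grid = np.arange(len(x)) / FS
        sg = s(grid)
        amp = params["pp"] / (sg.max() - sg.min())

        def pressure(t):
            return params["dia"] + amp * (s(t) - sg.min())

        seg = BeatSegment(0, len(x), x)
        lm = preprocess.locate_landmarks(seg, FS)
        out = features.extract_features(seg, lm, FS)
        idx = {"A": 0, "C": lm.iC, "D": lm.iD, "A'": len(x) - 1}
        for ph, (a, b) in features.PHASES.items():
            if ph == "pp":
                continue
            t0, t1 = idx[a] / FS, idx[b] / FS
            tm = np.linspace(t0, t1, 10 * (idx[b] - idx[a]), endpoint=False)
            dt = tm[1] - tm[0]
            riemann = np.sum(pressure(tm + dt / 2)) * dt
            assert out[f"{ph}_area"] == pytest.approx(riemann, rel=0.01)

    def test_scale_equivariance(self, quiet_subject):
        x = synth.synth_beat(quiet_subject, 0.6, FS)
        k = 2.5
        seg, seg_k = BeatSegment(0, len(x), x), BeatSegment(0, len(x), k * x)
        lm = preprocess.locate_landmarks(seg, FS)
        lm_k = preprocess.locate_landmarks(seg_k, FS)
        assert (lm.iB, lm.iC, lm.iD) == (lm_k.iB, lm_k.iC, lm_k.iD)
        a = features.extract_features(seg, lm, FS)
        b = features.extract_features(seg_k, lm_k, FS)
        invariant = {"PPI", "HR", "SI", "HRIP"} | {
            n for n in FEATURE_NAMES if n.startswith("t_")
        }
        for name in FEATURE_NAMES:
            if name in invariant:
                assert b[name] == pytest.approx(a[name], rel=1e-9)
            else:
                assert b[name] == pytest.approx(k * a[name], rel=1e-9)


class TestBuildTable:
    def test_noise_free_features_track_label(self, quiet_session):
        df = features.build_table([quiet_session])
        for name in ("PP", "PPI", "HRIP"):
            rho = stats.spearmanr(df[name], df["crm"]).statistic
            assert rho > 0.9, name

    def test_row_per_valid_beat_and_column_order(self, noisy_session):
        df = features.build_table([noisy_session])
        excl = df.attrs["exclusions"]
        assert len(df) == excl["n_beats"] - excl["no_inflection"] - excl["malformed"]
        assert list(df.columns) == features.META_COLUMNS + FEATURE_NAMES
        assert set(df["crm"]).issubset(set(noisy_session.step_crm.values()))
        assert not df.isna().any().any()

    def test_exclusions_counted(self, noisy_session, monkeypatch):
        real = features.locate_landmarks
        counter = {"i": 0}

        def flaky(beat, fs):
            counter["i"] += 1
            if counter["i"] % 5 == 0:
                return BeatLandmarks(
                    0, 0, 0, 0, len(beat), valid=False,
                    exclusion_reason=preprocess.ExclusionReason.no_inflection,
                )
            return real(beat, fs)

        monkeypatch.setattr(features, "locate_landmarks", flaky)
        df = features.build_table([noisy_session])
        excl = df.attrs["exclusions"]
        assert excl["no_inflection"] == excl["n_beats"] // 5
        assert len(df) == excl["n_beats"] - excl["no_inflection"]

    def test_all_invalid_raises(self, noisy_session, monkeypatch):
        monkeypatch.setattr(
            features, "locate_landmarks",
            lambda beat, fs: BeatLandmarks(
                0, 0, 0, 0, len(beat), valid=False,
                exclusion_reason=preprocess.ExclusionReason.malformed,
            ),
        )
        with pytest.raises(ValueError, match="excluded"):
            features.build_table([noisy_session])
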