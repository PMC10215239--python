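"""The per-beat morphological feature catalogue.

Fifty-four features are computed from each valid beat, organised over
six waveform phases delimited by the landmarks A (foot), B
(half-rise), C (systolic peak), D (post-systolic inflection) and A'
(next foot):

======== ==================== =========================
phase    span                 meaning
======== ==================== =========================
sys_rise A -> C               systolic upstroke
sys_dec  C -> D               peak to inflection
sys      A -> D               full systolic phase
dec      C -> A'              descending limb
dia      D -> A'              diastolic runoff
pp       A -> A'              whole beat
======== ==================== =========================

The catalogue partitions into 7 individual, 6 time-duration, 5
average-pressure, 5 area, 10 normalized-area, 18 NODIA and 3 slope
features.  NODIA features are recomputed after re-referencing the
pressure to the inflection-point value (P - P(D)).  The registry below
is the single source of truth for names, categories, units and column
order.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import (
    BeatLandmarks,
    BeatSegment,
    detect_beats,
    locate_landmarks,
    lowpass_fir,
)
from .synth import Session

__all__ = [
    "FeatureDef",
    "REGISTRY",
    "FEATURE_NAMES",
    "CATEGORY_COUNTS",
    "extract_features",
    "build_table",
    "export_registry",
]

log = logging.getLogger(__name__)

#: Phase name -> (start landmark, end landmark).
PHASES = {
    "sys_rise": ("A", "C"),
    "sys_dec": ("C", "D"),
    "sys": ("A", "D"),
    "dec": ("C", "A'"),
    "dia": ("D", "A'"),
    "pp": ("A", "A'"),
}
_AREA_PHASES = ("sys_rise", "sys_dec", "sys", "dec", "dia")  # 5-phase families
_NODIA_PHASES = tuple(PHASES)  # all 6, incl. whole beat


@dataclass(frozen=True)
class FeatureDef:
    name: str
    category: str
    unit: str
    formula: str


def _build_registry() -> list[FeatureDef]:
    reg: list[FeatureDef] = []

    def add(name, category, unit, formula):
        reg.append(FeatureDef(name, category, unit, formula))

    # 7 individual
    add("sys_pressure", "individual", "mmHg", "P(C)")
    add("dia_pressure", "individual", "mmHg", "P(A)")
    add("infl_pressure", "individual", "mmHg", "P(D)")
    add("PP", "individual", "mmHg", "P(C) - P(A)")
    add("PPI", "individual", "s", "interval between consecutive systolic peaks")
    add("HR", "individual", "beats/min", "60 / PPI")
    add("SI", "individual", "-", "(P(D) - P(A)) / PP")
    # 6 time
    for ph in _AREA_PHASES:
        a, b = PHASES[ph]
        add(f"t_{ph}", "time", "s", f"t({b}) - t({a})")
    add("HRIP", "time", "s", "t(D) - t(B)")
    # 5 average pressure
    for ph in _AREA_PHASES:
        add(f"avg_{ph}", "average", "mmHg", f"mean P over {ph}")
    # 5 area
    for ph in _AREA_PHASES:
        add(f"{ph}_area", "area", "mmHg*s", f"trapezoidal integral of P over {ph}")
    # 10 normalized: per-phase and per-beat sample counts
    for ph in _AREA_PHASES:
        add(f"{ph}_area_norm", "normalized", "mmHg", f"{ph}_area / n_samples({ph})")
    for ph in _AREA_PHASES:
        add(
            f"{ph}_area_norm_beat", "normalized", "mmHg",
            f"{ph}_area / n_samples(beat)",
        )
    # 18 NODIA: P re-referenced to the inflection pressure
    for ph in _NODIA_PHASES:
        add(f"{ph}_area_nodia", "nodia", "mmHg*s",
            f"trapezoidal integral of (P - P(D)) over {ph}")
    for ph in _NODIA_PHASES:
        add(f"avg_{ph}_nodia", "nodia", "mmHg", f"mean (P - P(D)) over {ph}")
    for ph in _NODIA_PHASES:
        add(f"{ph}_area_norm_nodia", "nodia", "mmHg",
            f"{ph}_area_nodia / n_samples({ph})")
    # 3 slope
    add("slope_sys", "slope", "mmHg/s", "(P(C) - P(A)) / t_sys_rise")
    add("slope_desc_sys", "slope", "mmHg/s", "(P(D) - P(C)) / t_sys_dec")
    add("slope_dia", "slope", "mmHg/s", "(P(A') - P(D)) / t_dia")
    return reg


REGISTRY: list[FeatureDef] = _build_registry()
FEATURE_NAMES: list[str] = [f.name for f in REGISTRY]
CATEGORY_COUNTS = {
    "individual": 7, "time": 6, "average": 5, "area": 5,
    "normalized": 10, "nodia": 18, "slope": 3,
}
assert len(FEATURE_NAMES) == 54 == len(set(FEATURE_NAMES))

#: Metadata columns preceding the 54 feature columns in a feature table.
META_COLUMNS = ["subject_id", "hdd_step", "step", "crm"]


def extract_features(
    beat: BeatSegment,
    lm: BeatLandmarks,
    fs: float,
    ppi: "float | None" = None,
) -> dict[str, float]:
    """Compute the 54-feature vector for one valid beat.

    ``ppi`` is the interval to the next beat's systolic peak; when the
    caller does not know it (isolated beat), the foot-to-foot beat
    length is used instead.
    """
    if not lm.valid:
        raise ValueError(f"cannot extract features from an invalid beat "
                         f"({lm.exclusion_reason.value})")
    p = beat.samples
    n = len(p)
    idx = {"A": lm.iA, "B": lm.iB, "C": lm.iC, "D": lm.iD, "A'": n - 1}
    for ph, (a, b) in PHASES.items():
        if idx[b] <= idx[a]:
            raise ValueError(f"zero-duration phase {ph}")

    def seg(ph):
        a, b = PHASES[ph]
        return p[idx[a] : idx[b] + 1]

    def dur(ph):
        a, b = PHASES[ph]
        return (idx[b] - idx[a]) / fs

    out: dict[str, float] = {}
    pp = p[lm.iC] - p[lm.iA]
    out["sys_pressure"] = p[lm.iC]
    out["dia_pressure"] = p[lm.iA]
    out["infl_pressure"] = p[lm.iD]
    out["PP"] = pp
    out["PPI"] = n / fs if ppi is None else float(ppi)
    out["HR"] = 60.0 / out["PPI"]
    out["SI"] = (p[lm.iD] - p[lm.iA]) / pp
    for ph in _AREA_PHASES:
        out[f"t_{ph}"] = dur(ph)
    out["HRIP"] = (lm.iD - lm.iB) / fs
    for ph in _AREA_PHASES:
        out[f"avg_{ph}"] = float(np.mean(seg(ph)))
    areas = {ph: float(np.trapezoid(seg(ph), dx=1.0 / fs)) for ph in _AREA_PHASES}
    for ph in _AREA_PHASES:
        out[f"{ph}_area"] = areas[ph]
    for ph in _AREA_PHASES:
        out[f"{ph}_area_norm"] = areas[ph] / len(seg(ph))
    for ph in _AREA_PHASES:
        out[f"{ph}_area_norm_beat"] = areas[ph] / n
    q = p - p[lm.iD]

    def qseg(ph):
        a, b = PHASES[ph]
        return q[idx[a] : idx[b] + 1]

    for ph in _NODIA_PHASES:
        out[f"{ph}_area_nodia"] = float(np.trapezoid(qseg(ph), dx=1.0 / fs))
    for ph in _NODIA_PHASES:
        out[f"avg_{ph}_nodia"] = float(np.mean(qseg(ph)))
    for ph in _NODIA_PHASES:
        out[f"{ph}_area_norm_nodia"] = out[f"{ph}_area_nodia"] / len(qseg(ph))
    out["slope_sys"] = pp / dur("sys_rise")
    out["slope_desc_sys"] = (p[lm.iD] - p[lm.iC]) / dur("sys_dec")
    out["slope_dia"] = (p[n - 1] - p[lm.iD]) / dur("dia")
    assert len(out) == 54
    return out


def _assign_step(session: Session, sample: int) -> "tuple[int, float] | None":
    for step, start, end in session.step_bounds:
        if start <= sample < end:
            return step, session.step_crm[step]
    # a beat overrunning the final boundary belongs to the last step
    step, _, end = session.step_bounds[-1]
    if sample >= end - 1:
        return step, session.step_crm[step]
    return None


def build_table(
    sessions: "list[Session]",
    cutoff: float = 20.0,
    n_taps: int = 101,
) -> pd.DataFrame:
    """Filter, segment and featurise sessions into one labeled table.

    One row per valid beat, ordered by subject (input order) then
    time.  Beats failing the landmark rules are dropped; exclusion
    counts are logged and attached as ``df.attrs['exclusions']``.
    """
    rows: list[dict] = []
    excl = {"no_inflection": 0, "malformed": 0, "n_beats": 0}
    for session in sessions:
        xf = lowpass_fir(session.samples, session.fs, cutoff=cutoff, n_taps=n_taps)
        beats = detect_beats(xf, session.fs)
        lms = [locate_landmarks(b, session.fs) for b in beats]
        abs_peak = [b.start + lm.iC if lm.valid else None
                    for b, lm in zip(beats, lms)]
        for i, (b, lm) in enumerate(zip(beats, lms)):
            excl["n_beats"] += 1
            if not lm.valid:
                excl[lm.exclusion_reason.value] += 1
                continue
            assigned = _assign_step(session, b.start)
            if assigned is None:  # pragma: no cover - defensive
                excl["malformed"] += 1
                continue
            step, crm = assigned
            ppi = None
            if i + 1 < len(beats) and abs_peak[i + 1] is not None:
                ppi = (abs_peak[i + 1] - abs_peak[i]) / session.fs
            row = {
                "subject_id": session.subject.subject_id,
                "hdd_step": session.subject.hdd_step,
                "step": step,
                "crm": crm,
            }
            row.update(extract_features(b, lm, session.fs, ppi=ppi))
            rows.append(row)
    if not rows:
        raise ValueError("all beats were excluded; no feature rows produced")
    df = pd.DataFrame(rows, columns=META_COLUMNS + FEATURE_NAMES)
    df.attrs["exclusions"] = excl
    log.info(
        "feature table: %d rows from %d beats (%d no-inflection, %d malformed)",
        len(df), excl["n_beats"], excl["no_inflection"], excl["malformed"],
    )
    return df


def export_registry(path: "str | Path") -> Path:
    """Write the feature registry (name, category, unit, formula) as JSON."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(
        [f.__dict__ for f in REGISTRY], indent=1))
    return path
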