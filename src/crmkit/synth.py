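"""Synthetic lower-body negative pressure (LBNP) cohort simulator.

LBNP experiments redistribute central blood volume by applying stepwise
negative chamber pressure to a supine subject's lower body, safely
emulating progressive hemorrhage.  The compensatory reserve measurement
(CRM) labels each pressure step on a 0-1 scale,

    CRM = 1 - LBNP / LBNP_HDD,

where ``LBNP`` is the current chamber pressure and ``LBNP_HDD`` the
pressure at which that subject reaches hemodynamic decompensation.  CRM
is 1 at baseline and 0 at the decompensation step.

Because the human LBNP datasets this pipeline was designed around are
access-restricted, this module generates arterial-pressure-like
waveforms whose per-beat morphology carries the same signal the real
data does: as CRM falls, pulse pressure shrinks, heart rate rises, and
the delay between the half-rise and the post-systolic inflection point
(HRIP) contracts.  Each beat is a pair of positive unimodal (Gaussian)
components — a systolic wave plus a delayed reflected wave — on a
diastolic baseline, which guarantees exactly one early post-peak
curvature sign change in the noise-free limit.  Measurement noise and
low-frequency baseline wander are added on top.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

__all__ = [
    "ProtocolStep",
    "SubjectParams",
    "Session",
    "DEFAULT_LADDER",
    "make_protocol",
    "crm_label",
    "beat_shape_params",
    "synth_beat",
    "simulate_session",
    "sample_cohort",
    "write_session",
    "read_session",
    "write_manifest",
    "read_manifest",
]

#: Canonical 9-step pressure staircase (mmHg), baseline 0 down to -100.
DEFAULT_LADDER = (0.0, -15.0, -30.0, -45.0, -60.0, -70.0, -80.0, -90.0, -100.0)

#: Effect sizes at CRM = 0, relative to the subject's baseline:
#: pulse pressure falls to 50%, heart rate rises by 40%, and the
#: half-rise-to-inflection timing falls to 55%.
PP_DROP = 0.50
HR_RISE = 0.40
HRIP_DROP = 0.45


@dataclass(frozen=True)
class ProtocolStep:
    """One level of the LBNP staircase.

    Attributes
    ----------
    index : int
        1-based step number; step 1 is the 0 mmHg baseline.
    pressure : float
        Chamber pressure in mmHg (non-positive).
    duration : float
        Step duration in seconds.
    """

    index: int
    pressure: float
    duration: float


@dataclass(frozen=True)
class SubjectParams:
    """Subject-level physiological and simulation parameters.

    ``hdd_step`` is the 1-based protocol step at which the subject
    reaches hemodynamic decompensation; the cohort draws it from
    {4..8}.  ``hrip_base`` is the baseline half-rise-to-inflection
    delay in seconds, the timescale that sets the beat's systolic and
    reflected-wave geometry.
    """

    subject_id: str
    hdd_step: int
    baseline_sys: float = 120.0
    baseline_dia: float = 78.0
    baseline_hr: float = 65.0
    hrip_base: float = 0.25
    noise_sd: float = 1.0
    wander_amp: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.baseline_sys > self.baseline_dia > 0):
            raise ValueError("require baseline_sys > baseline_dia > 0")
        if not (40.0 <= self.baseline_hr <= 120.0):
            raise ValueError("baseline_hr must lie in [40, 120] bpm")
        if self.hrip_base <= 0:
            raise ValueError("hrip_base must be positive")


@dataclass
class Session:
    """One simulated LBNP session: waveform plus ground-truth labels.

    ``step_bounds`` maps each completed protocol step to its half-open
    sample range.  Per-beat arrays are aligned: ``beat_starts[i]`` is
    the sample index of beat *i*'s onset (generated foot),
    ``beat_steps[i]`` its protocol step and ``beat_crm[i]`` its CRM
    label.  Within a step the label is constant (stepwise CRM).
    """

    subject: SubjectParams
    fs: float
    samples: np.ndarray
    step_bounds: list[tuple[int, int, int]]  # (step index, start, end)
    step_crm: dict[int, float]
    beat_starts: np.ndarray
    beat_steps: np.ndarray
    beat_crm: np.ndarray


def make_protocol(
    n_steps: int = 9,
    min_pressure: float = -100.0,
    step_duration: float = 300.0,
    pressures: "list[float] | None" = None,
) -> list[ProtocolStep]:
    """Build the LBNP pressure staircase.

    Defaults reproduce the canonical protocol: nine steps from 0 down
    to -100 mmHg, five minutes each.  A custom ``pressures`` ladder may
    be supplied; it must start at 0, end at ``min_pressure`` and be
    strictly decreasing.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if min_pressure > 0:
        raise ValueError("min_pressure must be <= 0 mmHg")
    if step_duration <= 0:
        raise ValueError("step_duration must be positive")
    if pressures is None:
        if n_steps == 1:
            pressures = [0.0]
        elif n_steps == len(DEFAULT_LADDER) and min_pressure == DEFAULT_LADDER[-1]:
            pressures = list(DEFAULT_LADDER)
        else:
            pressures = list(np.linspace(0.0, min_pressure, n_steps))
    else:
        pressures = [float(p) for p in pressures]
        if len(pressures) != n_steps:
            raise ValueError("pressures length must equal n_steps")
    if pressures[0] != 0.0:
        raise ValueError("step 1 must be at 0 mmHg baseline")
    if n_steps > 1:
        if pressures[-1] != float(min_pressure):
            raise ValueError("last step must equal min_pressure")
        diffs = np.diff(pressures)
        if not np.all(diffs < 0):
            raise ValueError("ladder pressures must be strictly decreasing")
    return [
        ProtocolStep(index=i + 1, pressure=float(p), duration=float(step_duration))
        for i, p in enumerate(pressures)
    ]


def crm_label(
    step: ProtocolStep, subject: SubjectParams, protocol: list[ProtocolStep]
) -> float:
    """CRM of ``subject`` at ``step``: ``1 - LBNP / LBNP_HDD``.

    Defined only up to the subject's decompensation step; equals 1 at
    baseline (0 mmHg) and 0 at ``hdd_step``.
    """
    if not (1 <= subject.hdd_step <= len(protocol)):
        raise ValueError(
            f"hdd_step {subject.hdd_step} outside protocol of {len(protocol)} steps"
        )
    if step.index > subject.hdd_step:
        raise ValueError("step beyond the subject's decompensation step")
    p_hdd = protocol[subject.hdd_step - 1].pressure
    if p_hdd == 0:
        raise ValueError("decompensation step cannot be the 0 mmHg baseline")
    crm = 1.0 - step.pressure / p_hdd
    if not (0.0 <= crm <= 1.0 + 1e-12):
        raise AssertionError("CRM outside [0, 1]")
    return float(min(crm, 1.0))


def beat_shape_params(subject: SubjectParams, crm: float) -> dict[str, float]:
    """Closed-form parameters of the two-component beat model at ``crm``.

    The noise-free pulse is ``dia + amp * (g1(t) + a2 * g2(t))`` over one
    period ``T``, with Gaussian components
    ``g_i(t) = exp(-(t - mu_i)^2 / (2 s_i^2))``; ``amp`` is chosen so the
    peak-minus-foot pressure equals the target pulse pressure.  All
    timing parameters scale with the CRM-modulated half-rise-to-
    inflection timescale ``h``, so the beat's landmark geometry
    contracts monotonically as the reserve is exhausted.
    """
    if not (0.0 <= crm <= 1.0):
        raise ValueError("crm must lie in [0, 1]")
    severity = 1.0 - crm
    hr = subject.baseline_hr * (1.0 + HR_RISE * severity)
    pp = (subject.baseline_sys - subject.baseline_dia) * (1.0 - PP_DROP * severity)
    h = subject.hrip_base * (1.0 - HRIP_DROP * severity)
    s1 = 0.30 * h
    mu1 = 3.2 * s1
    return {
        "T": 60.0 / hr,
        "dia": subject.baseline_dia,
        "pp": pp,
        "mu1": mu1,
        "s1": s1,
        "mu2": mu1 + 1.30 * h,
        "s2": 0.45 * h,
        "a2": 0.40,
        "h": h,
    }


def _shape(t: np.ndarray, p: dict[str, float]) -> np.ndarray:
    g1 = np.exp(-((t - p["mu1"]) ** 2) / (2.0 * p["s1"] ** 2))
    g2 = np.exp(-((t - p["mu2"]) ** 2) / (2.0 * p["s2"] ** 2))
    return g1 + p["a2"] * g2


def synth_beat(
    subject: SubjectParams,
    crm: float,
    fs: float,
    rng: "np.random.Generator | None" = None,
) -> np.ndarray:
    """Generate one cardiac cycle's pressure samples at ``crm``.

    The block spans one beat period; samples are in mmHg.  The pulse is
    scaled so that, noise-free, its on-grid peak-minus-foot amplitude
    equals the CRM-modulated pulse pressure exactly.  Gaussian
    measurement noise of sd ``subject.noise_sd`` is added when an
    ``rng`` is supplied and the sd is positive.
    """
    p = beat_shape_params(subject, crm)
    n = max(int(round(p["T"] * fs)), 8)
    t = np.arange(n) / fs
    s = _shape(t, p)
    span = s.max() - s.min()
    x = p["dia"] + p["pp"] * (s - s.min()) / span
    if rng is not None and subject.noise_sd > 0:
        x = x + rng.normal(0.0, subject.noise_sd, n)
    return x


def simulate_session(
    subject: SubjectParams,
    protocol: list[ProtocolStep],
    fs: float = 500.0,
    wander_freq: float = 0.2,
) -> Session:
    """Simulate a full LBNP session for one subject.

    Steps 1..``hdd_step`` are run in order; the session is truncated at
    decompensation, when the chamber would be vented.  Beats are
    concatenated until each step's duration is covered (the final beat
    of a step may overrun the boundary by less than one period).  A
    ``wander_freq`` sinusoid of amplitude ``subject.wander_amp``
    emulates slow baseline wander.  Fully reproducible from
    ``subject.seed``.
    """
    if subject.hdd_step > len(protocol):
        raise ValueError("subject decompensates beyond the protocol")
    rng = np.random.default_rng(subject.seed)
    phase = rng.uniform(0.0, 2.0 * math.pi)

    chunks: list[np.ndarray] = []
    step_bounds: list[tuple[int, int, int]] = []
    step_crm: dict[int, float] = {}
    beat_starts: list[int] = []
    beat_steps: list[int] = []
    beat_crm: list[float] = []

    cursor = 0
    for step in protocol[: subject.hdd_step]:
        crm = crm_label(step, subject, protocol)
        step_crm[step.index] = crm
        start = cursor
        target = start + int(round(step.duration * fs))
        while cursor < target:
            block = synth_beat(subject, crm, fs, rng)
            beat_starts.append(cursor)
            beat_steps.append(step.index)
            beat_crm.append(crm)
            chunks.append(block)
            cursor += len(block)
        step_bounds.append((step.index, start, cursor))

    x = np.concatenate(chunks)
    if subject.wander_amp > 0:
        tt = np.arange(len(x)) / fs
        x = x + subject.wander_amp * np.sin(2.0 * math.pi * wander_freq * tt + phase)
    return Session(
        subject=subject,
        fs=float(fs),
        samples=x,
        step_bounds=step_bounds,
        step_crm=step_crm,
        beat_starts=np.asarray(beat_starts, dtype=np.int64),
        beat_steps=np.asarray(beat_steps, dtype=np.int64),
        beat_crm=np.asarray(beat_crm, dtype=float),
    )


def sample_cohort(
    n_per_group: int,
    groups: "tuple[int, ...] | list[int]" = (4, 5, 6, 7, 8),
    seed: int = 0,
    noise_sd: float = 1.0,
    wander_amp: float = 2.0,
) -> list[SubjectParams]:
    """Draw a balanced cohort: ``n_per_group`` subjects per HDD group.

    Groups are the decompensation steps represented in the cohort
    (defaults to {4..8}; the sparse extremes of the real distribution
    are not simulated).  Subject baselines are drawn from truncated
    normal distributions typical of healthy adults; each subject gets
    an independent seed derived from the cohort seed.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    groups = sorted(set(int(g) for g in groups))
    if not groups:
        raise ValueError("groups must be non-empty")
    rng = np.random.default_rng(seed)
    cohort: list[SubjectParams] = []
    for g in groups:
        for i in range(n_per_group):
            pp0 = float(np.clip(rng.normal(48.0, 7.0), 32.0, 65.0))
            sys = float(np.clip(rng.normal(125.0, 10.0), 100.0, 160.0))
            cohort.append(
                SubjectParams(
                    subject_id=f"S{g}-{i:02d}",
                    hdd_step=g,
                    baseline_sys=sys,
                    baseline_dia=sys - pp0,
                    baseline_hr=float(np.clip(rng.normal(64.0, 8.0), 45.0, 100.0)),
                    hrip_base=float(np.clip(rng.normal(0.25, 0.03), 0.17, 0.33)),
                    noise_sd=noise_sd,
                    wander_amp=wander_amp,
                    seed=int(rng.integers(0, 2**31)),
                )
            )
    return cohort


# ---------------------------------------------------------------------------
# On-disk dialect: CSV waveform + JSON sidecar, one pair per session.

def write_session(session: Session, out_dir: "str | Path") -> tuple[Path, Path]:
    """Persist a session as ``<id>.csv`` (time_s,pressure_mmhg) plus a
    JSON sidecar with the labels and step boundaries."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sid = session.subject.subject_id
    csv_path = out_dir / f"{sid}.csv"
    t = np.arange(len(session.samples)) / session.fs
    arr = np.column_stack([t, session.samples])
    np.savetxt(
        csv_path, arr, delimiter=",", header="time_s,pressure_mmhg",
        comments="", fmt="%.6f",
    )
    meta = {
        "subject": asdict(session.subject),
        "fs": session.fs,
        "step_bounds": [list(b) for b in session.step_bounds],
        "step_crm": {str(k): v for k, v in session.step_crm.items()},
        "beat_starts": session.beat_starts.tolist(),
        "beat_steps": session.beat_steps.tolist(),
        "beat_crm": session.beat_crm.tolist(),
    }
    json_path = out_dir / f"{sid}.json"
    json_path.write_text(json.dumps(meta))
    return csv_path, json_path


def read_session(csv_path: "str | Path") -> Session:
    """Load a session written by :func:`write_session`."""
    csv_path = Path(csv_path)
    data = np.loadtxt(csv_path, delimiter=",", skiprows=1)
    meta = json.loads(csv_path.with_suffix(".json").read_text())
    return Session(
        subject=SubjectParams(**meta["subject"]),
        fs=float(meta["fs"]),
        samples=data[:, 1],
        step_bounds=[tuple(b) for b in meta["step_bounds"]],
        step_crm={int(k): float(v) for k, v in meta["step_crm"].items()},
        beat_starts=np.asarray(meta["beat_starts"], dtype=np.int64),
        beat_steps=np.asarray(meta["beat_steps"], dtype=np.int64),
        beat_crm=np.asarray(meta["beat_crm"], dtype=float),
    )


def write_manifest(cohort: list[SubjectParams], path: "str | Path") -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps([asdict(s) for s in cohort], indent=1))
    return path


def read_manifest(path: "str | Path") -> list[SubjectParams]:
    return [SubjectParams(**d) for d in json.loads(Path(path).read_text())]
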