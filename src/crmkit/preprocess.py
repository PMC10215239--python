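"""Waveform conditioning, beat segmentation and pulse landmarks.

The landmark vocabulary follows the pulse-wave-analysis convention:
the pulse foot ("A") at the onset of the systolic upstroke, the
half-rise ("B") at the amplitude midpoint of the rising limb, the
systolic peak ("C"), and the first post-systolic inflection point
("D") — the first curvature sign change after the peak, associated
with the reflected/dicrotic wave.  Beats without any post-peak
inflection are flagged invalid and excluded downstream; when several
inflections exist, only the first is tracked.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import signal

__all__ = [
    "BeatSegment",
    "BeatLandmarks",
    "ExclusionReason",
    "lowpass_fir",
    "detect_beats",
    "locate_landmarks",
]

#: Refractory period between successive systolic upstrokes (s).
REFRACTORY_S = 0.3
#: Lookback window when searching for the pulse foot before an upstroke (s).
FOOT_LOOKBACK_S = 0.25
#: Moving-average width (samples) applied before the second derivative.
D2_SMOOTH = 5


class ExclusionReason(str, Enum):
    none = "none"
    no_inflection = "no_inflection"
    malformed = "malformed"


@dataclass(frozen=True)
class BeatSegment:
    """Half-open, 0-based sample range of one foot-to-foot beat."""

    start: int
    end: int
    samples: np.ndarray

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("beat segment must have end > start")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class BeatLandmarks:
    """Landmark indices relative to the beat start; ``iA_next`` is the
    next foot (== len(beat) for foot-to-foot segments)."""

    iA: int
    iB: int
    iC: int
    iD: int
    iA_next: int
    valid: bool
    exclusion_reason: ExclusionReason = ExclusionReason.none


def lowpass_fir(
    x: np.ndarray, fs: float, cutoff: float = 20.0, n_taps: int = 101
) -> np.ndarray:
    """Zero-phase windowed-sinc (Hamming) lowpass filter.

    The symmetric tap vector is applied centred (edge-padded
    convolution), so linear-phase delay is compensated and the output
    has the input's length.  DC gain is unity to within 1e-3.
    """
    x = np.asarray(x, dtype=float)
    if not (0 < cutoff < fs / 2):
        raise ValueError("cutoff must lie in (0, fs/2)")
    if n_taps % 2 != 1 or n_taps < 3:
        raise ValueError("n_taps must be odd and >= 3")
    taps = signal.firwin(n_taps, cutoff, fs=fs, window="hamming")
    half = n_taps // 2
    padded = np.pad(x, half, mode="edge")
    return np.convolve(padded, taps, mode="valid")


def detect_beats(x: np.ndarray, fs: float) -> list[BeatSegment]:
    """Segment a filtered waveform into foot-to-foot beats.

    Systolic upstrokes are the peaks of the first derivative (with a
    0.3 s refractory period); each pulse foot is the local minimum in
    the lookback window preceding its upstroke.  An incomplete
    trailing beat (no following foot) is discarded.  Flat input yields
    no beats.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < int(2 * fs):
        raise ValueError("need at least 2 s of data")
    if np.ptp(x) == 0:
        return []
    d = np.gradient(x) * fs
    dmax = d.max()
    if dmax <= 0:
        return []
    peaks, _ = signal.find_peaks(
        d, height=0.33 * dmax, distance=max(int(REFRACTORY_S * fs), 1)
    )
    if len(peaks) < 2:
        return []
    lookback = max(int(FOOT_LOOKBACK_S * fs), 2)
    feet = []
    for p in peaks:
        lo = max(p - lookback, 0)
        feet.append(lo + int(np.argmin(x[lo : p + 1])))
    feet = np.unique(feet)
    return [
        BeatSegment(start=int(a), end=int(b), samples=x[a:b])
        for a, b in zip(feet[:-1], feet[1:])
    ]


def _second_derivative(p: np.ndarray) -> np.ndarray:
    # light moving-average smoothing guards the sign-change test against
    # discretisation ripple; the window is symmetric, so no phase shift
    kernel = np.ones(D2_SMOOTH) / D2_SMOOTH
    ps = np.convolve(p, kernel, mode="same")
    return np.gradient(np.gradient(ps))


def locate_landmarks(beat: BeatSegment, fs: float) -> BeatLandmarks:
    """Locate landmarks A, B, C, D within one beat.

    A is the beat-start foot and C the global maximum.  B is the first
    rising-limb sample at or above the A-C amplitude midpoint.  D is
    the first sample after C where the (smoothed, central-difference)
    second derivative crosses zero from negative to positive; beats
    with no such crossing before the next foot are invalid with reason
    ``no_inflection``, and only the first crossing is kept when several
    exist.
    """
    p = beat.samples
    n = len(p)

    def bad(reason: ExclusionReason) -> BeatLandmarks:
        return BeatLandmarks(0, 0, 0, 0, n, valid=False, exclusion_reason=reason)

    if n < 5:
        return bad(ExclusionReason.malformed)
    iA = 0
    iC = int(np.argmax(p))
    if iC <= iA or iC >= n - 2:
        return bad(ExclusionReason.malformed)
    midpoint = 0.5 * (p[iA] + p[iC])
    rising = np.nonzero(p[1 : iC + 1] >= midpoint)[0]
    if len(rising) == 0:
        return bad(ExclusionReason.malformed)
    iB = int(rising[0]) + 1
    if iB >= iC:
        return bad(ExclusionReason.malformed)
    d2 = _second_derivative(p)
    # exclude the last two samples, where central differences are one-sided
    iD = None
    for i in range(iC + 1, n - 2):
        if d2[i - 1] < 0 and d2[i] >= 0:
            iD = i
            break
    if iD is None:
        return bad(ExclusionReason.no_inflection)
    return BeatLandmarks(iA=iA, iB=iB, iC=iC, iD=iD, iA_next=n, valid=True)
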