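"""Breathing-cycle detection and per-cycle measures.

Inspiration onsets are found on the working-rate trace by (i) mean
centring, (ii) a bidirectional first-order Butterworth band-pass
(0.01-0.6 Hz), (iii) a centred 1 s running median, and (iv) taking each
negative zero-crossing of the processed signal as the start of an
inspiration, with a 1 s refractory period to suppress noise-induced
double crossings.  For each detected cycle, the respiration period (RP)
is its duration, the respiration amplitude (RA) the range of the trace
within the cycle, and the respiratory flow rate (RFR) their quotient
RA/RP.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .io_physio import RespirationTrace

__all__ = [
    "CycleSeries",
    "DetectionEval",
    "detect_inspiration_onsets",
    "compute_cycle_measures",
    "evaluate_detection",
]


@dataclass(frozen=True)
class CycleSeries:
    """Inspiration onsets with per-cycle RP (s), RA (trace units), RFR (units/s).

    Cycle i spans the half-open interval [onsets[i], onsets[i+1]), so the
    measure arrays are one shorter than the onset array.
    """

    onsets: np.ndarray
    rp: np.ndarray
    ra: np.ndarray
    rfr: np.ndarray

    def __post_init__(self) -> None:
        n = self.onsets.size
        if not (self.rp.size == self.ra.size == self.rfr.size == n - 1):
            raise ValueError("per-cycle arrays must have len(onsets) - 1 entries")

    @property
    def n_cycles(self) -> int:
        return self.rp.size

    def measure(self, kind: str) -> np.ndarray:
        kind = kind.lower()
        if kind not in ("rp", "ra", "rfr"):
            raise ValueError(f"unknown measure {kind!r}")
        return getattr(self, kind)


@dataclass(frozen=True)
class DetectionEval:
    """Detection quality against reference onsets."""

    tp: int
    fp: int
    fn: int
    delays: np.ndarray  # signed, detected - reference, one per TP pair

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def ppv(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else float("nan")


def _running_median(x: np.ndarray, win: int) -> np.ndarray:
    # centred window; shrinks at the edges instead of padding
    return (
        pd.Series(x).rolling(win, center=True, min_periods=1).median().to_numpy()
    )


def detect_inspiration_onsets(
    trace: RespirationTrace,
    band: tuple[float, float] = (0.01, 0.6),
    median_win: float = 1.0,
    refractory: float = 1.0,
) -> np.ndarray:
    """Detect inspiration-onset times on a working-rate (10 Hz) trace.

    Returns strictly increasing times; consecutive onsets are at least
    ``refractory`` seconds apart.  A negative zero-crossing at sample k
    (processed value[k-1] > 0 >= value[k]) maps to time t0 + k/fs.  An
    empty result is valid (no cycles found).
    """
    lo, hi = band
    if not (0 < lo < hi < trace.fs / 2):
        raise ValueError(f"band {band} must lie inside (0, {trace.fs / 2}) Hz")
    win = int(round(median_win * trace.fs))
    if win % 2 == 0:
        win += 1  # odd, centred window avoids phase shift
    if trace.n < 2 * win:
        raise ValueError("trace too short for the median window")

    x = trace.values - np.mean(trace.values)
    b, a = signal.butter(1, [lo, hi], btype="bandpass", fs=trace.fs)
    # pad a few high-pass time constants so edge transients do not move
    # zero-crossings near the recording boundaries
    padlen = int(min(trace.n - 1, 3 * trace.fs / lo))
    x = signal.filtfilt(b, a, x, padtype="even", padlen=padlen)
    x = _running_median(x, win)

    crossing = np.flatnonzero((x[:-1] > 0) & (x[1:] <= 0)) + 1
    onsets: list[float] = []
    last = -np.inf
    for k in crossing:
        t = trace.t0 + k / trace.fs
        if t - last >= refractory:
            onsets.append(t)
            last = t
    return np.asarray(onsets)


def compute_cycle_measures(
    trace: RespirationTrace, onsets: np.ndarray
) -> CycleSeries:
    """Per-cycle RP, RA and RFR from a trace and its inspiration onsets.

    Cycle i covers [onsets[i], onsets[i+1]): RP is its duration, RA the
    max - min of the trace values in that half-open window, RFR = RA/RP.
    """
    onsets = np.asarray(onsets, dtype=float)
    if onsets.size < 2:
        raise ValueError("need at least 2 onsets to form a cycle")
    t_end = trace.t0 + trace.n / trace.fs
    if onsets[0] < trace.t0 - 0.5 / trace.fs or onsets[-1] > t_end + 0.5 / trace.fs:
        raise ValueError("onset outside the trace span")
    idx = np.round((onsets - trace.t0) * trace.fs).astype(int)
    idx = np.clip(idx, 0, trace.n)
    rp = np.diff(onsets)
    ra = np.empty(rp.size)
    for i in range(rp.size):
        seg = trace.values[idx[i] : max(idx[i + 1], idx[i] + 1)]
        ra[i] = float(np.max(seg) - np.min(seg))
    return CycleSeries(onsets=onsets, rp=rp, ra=ra, rfr=ra / rp)


def evaluate_detection(
    reference: np.ndarray, detected: np.ndarray, tol: float = 1.0
) -> DetectionEval:
    """Score detected onsets against reference onsets.

    Greedy one-to-one pairing in reference order: each reference onset is
    paired with the nearest still-unmatched detected onset; pairs with
    |delay| < tol count as true positives.  Unpaired reference onsets are
    false negatives, unpaired detected onsets false positives.  Delays
    are recorded as detected - reference.
    """
    reference = np.asarray(reference, dtype=float)
    detected = np.asarray(detected, dtype=float)
    used = np.zeros(detected.size, dtype=bool)
    delays: list[float] = []
    tp = 0
    for r in reference:
        free = np.flatnonzero(~used)
        if free.size == 0:
            break
        j = free[np.argmin(np.abs(detected[free] - r))]
        delay = detected[j] - r
        if abs(delay) < tol:
            used[j] = True
            delays.append(delay)
            tp += 1
    fn = reference.size - tp
    fp = int(np.sum(~used))
    return DetectionEval(tp=tp, fp=fp, fn=fn, delays=np.asarray(delays))
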