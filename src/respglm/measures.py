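"""Continuous respiratory measures and legacy discrete event scores.

Each per-cycle measure (RP, RA, RFR) is assigned to the inspiration
onset *following* its cycle, linearly interpolated onto a uniform 10 Hz
grid, and band-pass filtered by applying the same causal first-order
Butterworth band-pass twice in cascade.  Peri-event epochs ([-5, 40] s
by default) and grand averages feed response-function estimation.

Legacy scores reproduce the classical discrete measures: the peri-minus
-pre cycle period difference (D-RP), the peri-over-pre period change
(RPQ, reported as percent change by default), and the respiration line
length difference (D-RLL) between the 15 s after and before each event.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .cycles import CycleSeries
from .io_physio import EventTable, RespirationTrace

__all__ = [
    "InterpolatedMeasure",
    "LegacyScores",
    "interpolate_measure",
    "filter_measure",
    "extract_peri_event",
    "grand_average",
    "legacy_scores",
    "respiration_line_length",
]

logger = logging.getLogger(__name__)

MEASURE_KINDS = ("rp", "ra", "rfr")


@dataclass(frozen=True)
class InterpolatedMeasure:
    """One respiratory measure as a uniform working-rate series."""

    kind: str
    values: np.ndarray
    fs: float
    t0: float
    filter_band: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.kind.lower() not in MEASURE_KINDS:
            raise ValueError(f"kind must be one of {MEASURE_KINDS}")
        object.__setattr__(self, "kind", self.kind.lower())
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite values in interpolated series")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.values.size) / self.fs


@dataclass(frozen=True)
class LegacyScores:
    """Per-event discrete scores d_rp (s), rpq, d_rll (trace units)."""

    onsets: np.ndarray
    conditions: tuple[str, ...]
    d_rp: np.ndarray
    rpq: np.ndarray
    d_rll: np.ndarray


def interpolate_measure(
    cycles: CycleSeries,
    kind: str,
    fs: float = 10.0,
    span: tuple[float, float] | None = None,
) -> InterpolatedMeasure:
    """Linearly interpolate a per-cycle measure onto a uniform grid.

    Anchor points sit at ``onsets[1:]`` — the inspiration following each
    cycle — and carry that cycle's measure.  Between anchors the series
    is linear; outside the anchor span it holds the nearest anchor value.

    Parameters
    ----------
    span : (float, float), optional
        Time span of the output grid; defaults to the anchor span.
    """
    if cycles.n_cycles < 2:
        raise ValueError("need at least 2 cycles to interpolate")
    anchors = cycles.onsets[1:]
    values = cycles.measure(kind)
    if span is None:
        span = (float(anchors[0]), float(anchors[-1]))
    t0, t1 = span
    if t1 <= t0:
        raise ValueError("span end must exceed span start")
    n = int(np.floor((t1 - t0) * fs)) + 1
    grid = t0 + np.arange(n) / fs
    out = np.interp(grid, anchors, values)  # np.interp holds the edge values
    return InterpolatedMeasure(kind=kind, values=out, fs=fs, t0=t0)


def _causal_bandpass_twice(
    x: np.ndarray, band: tuple[float, float], fs: float
) -> np.ndarray:
    lo, hi = band
    if not (0 < lo < hi < fs / 2):
        raise ValueError(f"band {band} must lie inside (0, {fs / 2}) Hz")
    b, a = signal.butter(1, [lo, hi], btype="bandpass", fs=fs)
    # step-matched initial conditions suppress the onset transient
    zi = signal.lfilter_zi(b, a)
    for _ in range(2):
        x, _ = signal.lfilter(b, a, x, zi=zi * x[0])
    return x


def filter_measure(
    im: InterpolatedMeasure, band: tuple[float, float] = (0.01, 1.0)
) -> InterpolatedMeasure:
    """Apply the causal first-order Butterworth band-pass twice in cascade.

    Both passes run in the forward direction (the filter is unidirectional,
    hence causal); output length equals input length.  Supported grids in
    validation studies span high-pass {0.001, 0.005, 0.01, 0.05} Hz and
    low-pass {0.5, 1, 2, 5} Hz; any band inside (0, fs/2) is accepted.
    """
    out = _causal_bandpass_twice(im.values.copy(), band, im.fs)
    return InterpolatedMeasure(
        kind=im.kind, values=out, fs=im.fs, t0=im.t0, filter_band=tuple(band)
    )


def extract_peri_event(
    im: InterpolatedMeasure,
    events: EventTable,
    window: tuple[float, float] = (-5.0, 40.0),
) -> np.ndarray:
    """Extract one row per event over ``window`` seconds around its onset.

    Column j corresponds to window_start + j/fs relative to the onset,
    which is snapped to the nearest sample.  Events whose window exceeds
    the series are dropped with a logged warning.

    Returns
    -------
    ndarray of shape (n_events_kept, n_window_samples)
    """
    lo, hi = window
    if hi <= lo:
        raise ValueError("window end must exceed window start")
    n_win = int(round((hi - lo) * im.fs)) + 1
    lo_off = int(round(lo * im.fs))
    rows = []
    for onset in events.onsets:
        k = int(round((onset - im.t0) * im.fs))
        start = k + lo_off
        stop = start + n_win
        if start < 0 or stop > im.values.size:
            logger.warning(
                "dropping event at %.2f s: window [%g, %g] s exceeds the series",
                onset, lo, hi,
            )
            continue
        rows.append(im.values[start:stop])
    if not rows:
        raise ValueError("no event window fits inside the series")
    return np.vstack(rows)


def grand_average(epoch_matrices: list[np.ndarray]) -> np.ndarray:
    """Pointwise mean over all rows of all epoch matrices (trials weighted equally)."""
    if not epoch_matrices:
        raise ValueError("no epochs to average")
    widths = {m.shape[1] for m in epoch_matrices}
    if len(widths) != 1:
        raise ValueError(f"epoch matrices disagree on window length: {sorted(widths)}")
    return np.mean(np.vstack(epoch_matrices), axis=0)


def respiration_line_length(
    trace: RespirationTrace, start: float, stop: float
) -> float:
    """Path length of the trace projected on the data axis over [start, stop).

    Computed as the sum of absolute first differences of the working-rate
    samples in the window.  Invariant to constant offsets; scales linearly
    with trace gain.
    """
    i0 = int(round((start - trace.t0) * trace.fs))
    i1 = int(round((stop - trace.t0) * trace.fs))
    if i0 < 0 or i1 > trace.n:
        raise ValueError("RLL window outside the trace")
    seg = trace.values[i0:i1]
    return float(np.sum(np.abs(np.diff(seg))))


def legacy_scores(
    cycles: CycleSeries,
    trace: RespirationTrace,
    events: EventTable,
    rll_win: float = 15.0,
    rpq_mode: str = "percent",
) -> LegacyScores:
    """Classical discrete event scores D-RP, RPQ and D-RLL.

    For each event the peri-event cycle is the cycle into which the event
    falls (half-open cycle windows; an event exactly on an onset belongs
    to the cycle starting there) and the pre-event cycle is the one
    before it.  D-RP = peri RP - pre RP.  RPQ is the peri/pre period
    change, as percent (``100*(peri/pre - 1)``, default) or as the raw
    ratio.  RLL is computed on the working-rate trace over ``rll_win``
    seconds after (and before) the event; D-RLL = post - pre.
    """
    if rpq_mode not in ("percent", "ratio"):
        raise ValueError("rpq_mode must be 'percent' or 'ratio'")
    d_rp, rpq, d_rll = [], [], []
    for onset in events.onsets:
        i = int(np.searchsorted(cycles.onsets, onset, side="right")) - 1
        if i < 1 or i >= cycles.n_cycles:
            raise ValueError(
                f"event at {onset:.2f} s has no peri-event cycle with a preceding cycle"
            )
        peri, pre = cycles.rp[i], cycles.rp[i - 1]
        d_rp.append(peri - pre)
        ratio = peri / pre
        rpq.append(100.0 * (ratio - 1.0) if rpq_mode == "percent" else ratio)
        post_rll = respiration_line_length(trace, onset, onset + rll_win)
        pre_rll = respiration_line_length(trace, onset - rll_win, onset)
        d_rll.append(post_rll - pre_rll)
    return LegacyScores(
        onsets=events.onsets.copy(),
        conditions=events.conditions,
        d_rp=np.asarray(d_rp),
        rpq=np.asarray(rpq),
        d_rll=np.asarray(d_rll),
    )
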