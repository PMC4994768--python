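"""Anti-alias filtering and downsampling of raw belt recordings.

The raw transducer output (typically 1000 Hz) is low-passed with a
bidirectional first-order Butterworth filter (5 Hz cut-off by default)
and decimated to a 10 Hz working rate.  All subsequent analysis operates
on the working-rate trace.  Optional per-recording z-scoring removes the
between-subject belt gain in within-subject designs.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .io_physio import RespirationTrace

__all__ = ["antialias_downsample", "zscore_trace"]


def antialias_downsample(
    trace: RespirationTrace,
    lp_cutoff: float = 5.0,
    target_fs: float = 10.0,
) -> RespirationTrace:
    """Low-pass filter and decimate a trace to the working rate.

    The filter is a first-order Butterworth applied forward then backward
    (zero phase; the effective magnitude response is the squared
    single-pass response).  Decimation keeps every k-th sample, where
    k = fs / target_fs must be an integer.

    Raises
    ------
    ValueError
        If the cut-off is at or above Nyquist, or the decimation ratio is
        not an integer.
    """
    if lp_cutoff >= trace.fs / 2:
        raise ValueError(
            f"cut-off {lp_cutoff} Hz must be below Nyquist {trace.fs / 2} Hz"
        )
    if target_fs > trace.fs:
        raise ValueError("target rate above source rate")
    ratio = trace.fs / target_fs
    k = round(ratio)
    if abs(ratio - k) > 1e-6 * ratio:
        raise ValueError(
            f"decimation ratio {ratio} is not an integer; resample externally first"
        )
    b, a = signal.butter(1, lp_cutoff, btype="low", fs=trace.fs)
    # 'even' padding reflects the signal at the edges, avoiding step transients
    filtered = signal.filtfilt(b, a, trace.values, padtype="even")
    return RespirationTrace(filtered[::k], fs=trace.fs / k, t0=trace.t0)


def zscore_trace(trace: RespirationTrace) -> RespirationTrace:
    """Standardise a trace to sample mean 0 and standard deviation 1.

    Uses the ddof=1 sample standard deviation.  Raises on constant input.
    """
    sd = float(np.std(trace.values, ddof=1))
    if sd == 0:
        raise ValueError("cannot z-score a constant trace")
    return RespirationTrace(
        (trace.values - np.mean(trace.values)) / sd, fs=trace.fs, t0=trace.t0
    )
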