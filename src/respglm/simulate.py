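"""Synthetic respiration recordings with known ground truth.

The generator renders quasi-periodic breathing cycle by cycle: cycle i,
starting at time s_i, has period P_i = base_period * (1 + u_RP(s_i)) and
amplitude A_i = base_amp * (1 + u_RA(s_i)), where u_m(t) is the sum over
events of that event's fractional input amplitude times the measure's
Gaussian response function evaluated at t - t_event.  This is the
forward counterpart of the convolution model the analysis inverts:
breathing is a cyclic effector, so the modulation enters per cycle,
fixed at cycle onset, which keeps the ground truth unambiguous.

Each cycle is one period of a raised-cosine waveform with a sharpened
falling flank (default 30% of the cycle) emulating the sharp pressure
drop of a bellows transducer at inspiration.  The flank's negative
zero-crossing lies exactly at the cycle onset, matching the operational
definition of an inspiration onset used by both the detector and a
human rater.  White measurement noise and a slow sinusoidal baseline
drift are superposed.  Default conditions: 3.4 s mean period, unit
amplitude, noise SD 5% of the signal amplitude, 1000 Hz sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cycles import CycleSeries
from .io_physio import EventTable, RespirationTrace
from .response_functions import CANONICAL_PARAMS, gaussian_rf

__all__ = [
    "SimulationSpec",
    "simulate_recording",
    "make_benchmark",
    "benchmark_detection",
    "run_recovery_study",
    "RP_INPUT_LEVELS",
    "RA_INPUT_LEVELS",
]


@dataclass(frozen=True)
class SimulationSpec:
    """Ground-truth description of one synthetic recording.

    Input amplitudes are fractional modulations of the baseline (an RP
    amplitude of -0.1 shortens the period by up to 10% at the response
    peak), so recovery tests are free of the arbitrary belt gain.
    """

    duration: float = 600.0
    base_period: float = 3.4
    base_amp: float = 1.0
    event_onsets: tuple[float, ...] = ()
    event_conditions: tuple[str, ...] = ()
    rp_amps: tuple[float, ...] = ()
    ra_amps: tuple[float, ...] = ()
    rf_params: dict = field(
        default_factory=lambda: {
            "rp": CANONICAL_PARAMS["rp"],
            "ra": CANONICAL_PARAMS["ra"],
        }
    )
    noise_sd: float = 0.05
    drift: tuple[float, float] = (0.3, 0.005)  # (amplitude, frequency Hz)
    fs: float = 1000.0
    fall_frac: float = 0.3
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.base_period <= 1.0:
            raise ValueError("base period must exceed the 1 s detection refractory")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be non-negative")
        if not (0 < self.fall_frac < 1):
            raise ValueError("fall fraction must be in (0, 1)")
        n_ev = len(self.event_onsets)
        if self.event_conditions and len(self.event_conditions) != n_ev:
            raise ValueError("one condition per event required")
        if not self.event_conditions:
            object.__setattr__(self, "event_conditions", ("event",) * n_ev)
        for amps, name in ((self.rp_amps, "rp_amps"), (self.ra_amps, "ra_amps")):
            if amps and len(amps) != n_ev:
                raise ValueError(f"{name} must have one entry per event")
        if n_ev:
            rf_end = max(
                mu + 5 * sigma for mu, sigma in self.rf_params.values()
            )
            if self.duration <= max(self.event_onsets) + rf_end:
                raise ValueError("recording ends before the last response decays")


def _modulation(t: float, onsets, amps, mu: float, sigma: float) -> float:
    if not amps:
        return 0.0
    total = 0.0
    for t_ev, a in zip(onsets, amps):
        if t >= t_ev - 5 * sigma:
            total += a * gaussian_rf(np.asarray(t - t_ev), mu, sigma)
    return float(total)


def _render_cycle(tau: np.ndarray, period: float, amp: float, fall: float) -> np.ndarray:
    """One cycle of the asymmetric raised cosine on local time tau in [0, P).

    Falls from 0 to -A/2 over the first half-flank, rises to +A/2 over
    the bulk of the cycle, and falls back to 0 at the cycle end, so the
    negative zero-crossing sits exactly at the cycle boundary.
    """
    half = fall * period / 2.0
    y = np.empty_like(tau)
    m1 = tau < half
    m3 = tau >= period - half
    m2 = ~(m1 | m3)
    y[m1] = -(amp / 2.0) * np.sin(np.pi * tau[m1] / (fall * period))
    y[m2] = -(amp / 2.0) * np.cos(
        np.pi * (tau[m2] - half) / (period - fall * period)
    )
    y[m3] = (amp / 2.0) * np.cos(
        np.pi * (tau[m3] - (period - half)) / (fall * period)
    )
    return y


def simulate_recording(
    spec: SimulationSpec,
) -> tuple[RespirationTrace, CycleSeries, EventTable]:
    """Render a synthetic recording; returns (trace, truth cycles, events).

    Truth onsets are the exact cycle-start times (no sampling-grid
    rounding); the trace is bit-reproducible under a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.fs))
    values = np.zeros(n)
    t = np.arange(n) / spec.fs

    mu_rp, sig_rp = spec.rf_params["rp"]
    mu_ra, sig_ra = spec.rf_params["ra"]

    # breathing is a continuous process that the recording crops mid-cycle:
    # start half a cycle before t = 0 and render past the end, so no truth
    # onset coincides with a recording boundary
    starts: list[float] = []
    periods: list[float] = []
    amps: list[float] = []
    s = -0.5 * spec.base_period
    while s < spec.duration:
        period = spec.base_period * (
            1.0 + _modulation(s, spec.event_onsets, spec.rp_amps, mu_rp, sig_rp)
        )
        amp = spec.base_amp * (
            1.0 + _modulation(s, spec.event_onsets, spec.ra_amps, mu_ra, sig_ra)
        )
        if period <= 1.0:
            raise ValueError("modulated period fell below the 1 s refractory")
        i0 = max(int(np.ceil(s * spec.fs)), 0)
        i1 = min(int(np.ceil((s + period) * spec.fs)), n)
        if i1 > i0:
            values[i0:i1] = _render_cycle(t[i0:i1] - s, period, amp, spec.fall_frac)
        starts.append(s)
        periods.append(period)
        amps.append(amp)
        s += period

    # ground-truth cycles are those fully inside the recording
    full = [
        i
        for i, (st, p) in enumerate(zip(starts, periods))
        if st >= 0.0 and st + p <= spec.duration
    ]
    if not full:
        raise ValueError("duration too short for a single breathing cycle")

    drift_amp, drift_freq = spec.drift
    if drift_amp:
        values += drift_amp * np.sin(2.0 * np.pi * drift_freq * t)
    if spec.noise_sd:
        values += rng.normal(0.0, spec.noise_sd, n)

    onset_arr = np.asarray(
        [starts[i] for i in full] + [starts[full[-1]] + periods[full[-1]]]
    )
    rp = np.asarray([periods[i] for i in full])
    ra = np.asarray([amps[i] for i in full])
    truth = CycleSeries(onsets=onset_arr, rp=rp, ra=ra, rfr=ra / rp)
    events = EventTable(np.asarray(spec.event_onsets), spec.event_conditions)
    trace = RespirationTrace(values, fs=spec.fs, t0=0.0)
    return trace, truth, events


def make_benchmark(
    seed: int | None = None,
    n_recordings: int = 7,
    duration: float = 600.0,
) -> list[tuple[RespirationTrace, np.ndarray]]:
    """Detection benchmark: event-free recordings with varied conditions.

    Recordings span base periods of 2.5-5 s, noise SDs of 2-8% of the
    signal amplitude and drift amplitudes up to 50% of it, mirroring a
    small multi-subject validation sample.  Returns (trace, true onset
    times) pairs; deterministic under a fixed seed.
    """
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(n_recordings) % (2**31)
    periods = np.linspace(2.5, 5.0, n_recordings)
    noise_levels = np.linspace(0.02, 0.08, n_recordings)
    drift_amps = np.linspace(0.1, 0.5, n_recordings)
    drift_freqs = np.linspace(0.003, 0.009, n_recordings)
    out = []
    for i in range(n_recordings):
        spec = SimulationSpec(
            duration=duration,
            base_period=float(periods[i]),
            noise_sd=float(noise_levels[i]),
            drift=(float(drift_amps[i]), float(drift_freqs[i])),
            seed=int(child_seeds[i]),
        )
        trace, truth, _ = simulate_recording(spec)
        out.append((trace, truth.onsets))
    return out


# ---------------------------------------------------------------------------
# end-to-end validation studies on synthetic data

# fractional input-amplitude levels for the recovery study: breathing
# decelerations of 3-15% of the baseline period and amplitude increases of
# 5-25%, the order of magnitude of event-related respiratory responses
RP_INPUT_LEVELS: tuple[float, ...] = (-0.03, -0.06, -0.09, -0.12, -0.15)
RA_INPUT_LEVELS: tuple[float, ...] = (0.05, 0.10, 0.15, 0.20, 0.25)


def benchmark_detection(
    seed: int | None = None, tol: float = 1.0
) -> "DetectionEval":
    """Run the detector over the synthetic benchmark and pool the scores.

    Each benchmark recording is anti-alias filtered and downsampled to
    10 Hz, inspiration onsets are detected with default settings, and
    detections are paired with the ground-truth onsets at the given
    tolerance.  Returns pooled counts and delays over all recordings.
    """
    from .cycles import DetectionEval, detect_inspiration_onsets, evaluate_detection
    from .preprocess import antialias_downsample

    tp = fp = fn = 0
    delays: list[np.ndarray] = []
    for trace, truth in make_benchmark(seed):
        working = antialias_downsample(trace)
        detected = detect_inspiration_onsets(working)
        ev = evaluate_detection(truth, detected, tol=tol)
        tp, fp, fn = tp + ev.tp, fp + ev.fp, fn + ev.fn
        delays.append(ev.delays)
    return DetectionEval(tp=tp, fp=fp, fn=fn, delays=np.concatenate(delays))


def run_recovery_study(
    seed: int | None = None,
    n_recordings: int = 20,
    n_events: int = 10,
    measure_band: tuple[float, float] = (0.01, 1.0),
    n_nonevents: int = 3,
) -> dict:
    """Inject known input amplitudes and re-estimate them with the GLM.

    Each recording carries ``n_events`` events (~45 s apart), two per
    input-amplitude level: period decelerations from RP_INPUT_LEVELS and
    amplitude increases from RA_INPUT_LEVELS, assigned jointly per level.
    The flow-rate ground truth is the implied fractional change,
    approximately the RA level minus the RP level.  Control time points
    between events enter the model as a "nonevent" condition.

    Returns a dict with, per measure, the injected and estimated
    amplitudes (one pair per recording x level), their Pearson
    correlation and sign-recovery fraction, plus the pooled non-event
    estimates.
    """
    from .cycles import compute_cycle_measures, detect_inspiration_onsets
    from .glm import fit_measure_glm, nonevent_onsets
    from .io_physio import EventTable
    from .measures import filter_measure, interpolate_measure
    from .preprocess import antialias_downsample
    from .response_functions import canonical_rf

    ss = np.random.SeedSequence(seed)
    rec_seeds = ss.generate_state(n_recordings) % (2**31)
    n_levels = len(RP_INPUT_LEVELS)
    injected: dict[str, list[float]] = {"rp": [], "ra": [], "rfr": []}
    estimated: dict[str, list[float]] = {"rp": [], "ra": [], "rfr": []}
    nonevent_betas: list[float] = []

    for r in range(n_recordings):
        rng = np.random.default_rng(rec_seeds[r])
        onsets = 40.0 + np.arange(n_events) * 45.0 + rng.uniform(-5, 5, n_events)
        reps = int(np.ceil(n_events / n_levels))
        levels = rng.permutation(np.tile(np.arange(n_levels), reps)[:n_events])
        spec = SimulationSpec(
            duration=float(onsets[-1] + 60.0),
            event_onsets=tuple(onsets),
            event_conditions=tuple(f"L{k + 1}" for k in levels),
            rp_amps=tuple(RP_INPUT_LEVELS[k] for k in levels),
            ra_amps=tuple(RA_INPUT_LEVELS[k] for k in levels),
            seed=int(rec_seeds[r]),
        )
        trace, _truth, events = simulate_recording(spec)
        working = antialias_downsample(trace)
        det = detect_inspiration_onsets(working)
        cyc = compute_cycle_measures(working, det)
        controls = nonevent_onsets(events, n=n_nonevents, margin=15.0, seed=rng)
        all_events = EventTable(
            np.concatenate([events.onsets, controls.onsets]),
            events.conditions + controls.conditions,
        )
        span = (working.t0, working.t0 + working.duration)
        for kind in ("rp", "ra", "rfr"):
            im = interpolate_measure(cyc, kind, fs=working.fs, span=span)
            im = filter_measure(im, measure_band)
            result = fit_measure_glm(im, all_events, canonical_rf(kind, fs=working.fs))
            for k in range(n_levels):
                if kind == "rp":
                    injected[kind].append(RP_INPUT_LEVELS[k])
                elif kind == "ra":
                    injected[kind].append(RA_INPUT_LEVELS[k])
                else:
                    injected[kind].append(RA_INPUT_LEVELS[k] - RP_INPUT_LEVELS[k])
                estimated[kind].append(result.beta_for(f"L{k + 1}"))
            nonevent_betas.append(result.beta_for("nonevent"))

    out: dict = {"nonevent_betas": np.asarray(nonevent_betas)}
    for kind in ("rp", "ra", "rfr"):
        x = np.asarray(injected[kind])
        y = np.asarray(estimated[kind])
        out[kind] = {
            "injected": x,
            "estimated": y,
            "pearson_r": float(np.corrcoef(x, y)[0, 1]),
            "sign_recovery": float(np.mean(np.sign(y) == np.sign(x))),
        }
    return out
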