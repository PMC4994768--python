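# Methods

## Model

`respglm` treats event-related respiratory responses as the output of a
linear time-invariant (LTI) system.  A cognitive event at time `t_e` is
assumed to deliver a brief (delta) neural input of unknown amplitude
into the respiratory system; the measured consequence, after conversion
of the belt signal to a continuous respiratory measure `y(t)`, is the
convolution of that input with a canonical response function (RF)
`h(t)`:

    y(t) = sum_e  beta_e * h(t - t_e) + error

Three measures are analysed per recording: respiration period (RP, the
cycle duration in seconds), respiration amplitude (RA, the range of the
belt-transducer output within a cycle, proportional to tidal volume up
to a subject-specific belt gain), and respiratory flow rate
(RFR = RA / RP, proportional to tidal volumetric flow).  Each RF is a
unit-peak Gaussian `exp(-(t - mu)^2 / (2 sigma^2))` with measure-specific
latency and dispersion:

| measure | mu (s) | sigma (s) |
|---------|--------|-----------|
| RP      | 4.20   | 1.65      |
| RA      | 8.07   | 3.74      |
| RFR     | 6.00   | 3.23      |

All shipped RFs are positive-peaked; a breathing deceleration appears as
a negative estimated amplitude, not a negative basis function.  An
optional second basis column per RF is the analytic time derivative,
which absorbs small latency shifts.  The amplitude `beta` carries the
arbitrary units of a single belt, so only within-subject comparisons of
`beta` are meaningful.

LTI assumptions are approximations for respiration: the system saturates
under rapid event sequences, so the model is intended for long
inter-trial-interval designs (tens of seconds between events).

## Pipeline

1. **Preprocessing** — the raw trace (typically 1000 Hz) is low-passed
   with a first-order Butterworth filter at 5 Hz applied forward and
   backward (zero phase, squared magnitude response) and decimated to a
   10 Hz working rate.  Decimation requires an integer ratio; the
   backward pass reflects the signal at the edges to avoid transients.
   Optional z-scoring of the working-rate trace (sample mean 0, SD 1)
   removes the between-subject belt gain in within-subject designs; it
   is applied before cycle detection, where it provably leaves detected
   onsets unchanged (detection is affine-invariant) and rescales RA and
   RFR uniformly.
2. **Inspiration-onset detection** — the working trace is mean-centred,
   band-passed with a bidirectional first-order Butterworth filter
   (0.01–0.6 Hz) and median-filtered over a centred 1 s window (11
   samples at 10 Hz, shrinking at the edges).  Each negative
   zero-crossing (previous sample > 0 ≥ current sample) marks an
   inspiration onset; a keep-first 1 s refractory period suppresses
   noise-induced double crossings.  The band-pass is padded with a few
   high-pass time constants so edge transients do not move crossings
   near the recording boundaries.
3. **Per-cycle measures** — cycle i spans the half-open window
   [onset_i, onset_{i+1}); RP is its duration, RA the max − min of the
   working-rate trace inside the window, RFR their quotient (exact).
4. **Continuous series** — each cycle's measure is assigned to the
   inspiration *following* that cycle, linearly interpolated at 10 Hz,
   held constant outside the anchor span (the later high-pass removes
   the resulting DC segments), then filtered twice in cascade with the
   same *causal* first-order Butterworth band-pass (default
   0.01–1 Hz; 0.001–1 Hz is the empirically most sensitive setting).
   Initial filter conditions are step-matched to the first sample to
   suppress the onset transient.
5. **GLM** — per condition, a unit impulse train at the event onsets
   (nearest-sample rounding, ties to even) is convolved with each basis
   column; an all-ones intercept is appended (the causal filter's onset
   transient can leave small offsets).  Amplitudes are estimated with
   the Moore–Penrose pseudoinverse, `beta = pinv(X) Y`: the
   least-squares solution for full-rank designs and the minimum-norm
   solution (with a warning) otherwise.  Group-level summaries
   (one-sample t-tests over per-recording contrasts) are ordinary
   statistics provided for convenience; the method's contract ends at
   per-recording amplitude estimates and contrasts.

A control analysis estimates amplitudes at random "non-event" time
points drawn between real events (at least a configurable margin from
both neighbours); under the model these are zero-mean.

## Legacy discrete scores

For comparison with classical analyses: D-RP (peri-event minus
pre-event cycle period), RPQ (peri/pre period change) and D-RLL
(respiration line length over 15 s after minus 15 s before the event,
where RLL is the sum of absolute sample differences of the working-rate
trace).  RPQ is reported as percent change, `100 * (peri/pre − 1)`,
because published group values of order 4–10 are inconsistent with a
raw ratio near 1; the raw ratio is available via
`measures_rpq_mode="ratio"`.  RLL is computed on the 10 Hz working
trace — path length depends on the sampling rate, so the rate must be
pinned; events exactly on an inspiration onset belong to the cycle
starting there (half-open convention).

## Synthetic data

The generator renders quasi-periodic breathing cycle by cycle: cycle i
starting at `s_i` has period `P_i = base_period * (1 + u_RP(s_i))` and
amplitude `A_i = base_amp * (1 + u_RA(s_i))`, with `u_m(t)` the sum of
event-locked Gaussian responses scaled by fractional input amplitudes.
Modulation enters per cycle (fixed at cycle onset) because breathing is
a cyclic effector; this matches how the analysis measures it and keeps
the ground truth unambiguous.  Each cycle is an asymmetric raised
cosine whose steep falling flank (30% of the cycle) emulates the sharp
pressure drop of a bellows transducer at inspiration; the flank's
negative zero-crossing is placed exactly at the cycle onset so that the
ground-truth onset coincides with the operational definition of an
inspiration onset.  White noise (default SD 5% of the unit signal
amplitude) and a slow sinusoidal baseline drift are superposed, and the
recording crops the breathing process mid-cycle at both ends, as a real
recording does.  Defaults: 3.4 s mean period, 1000 Hz sampling.

What the generator does **not** emulate: breath-to-breath period
variability in the absence of events, sighs and apnoeas, movement
artefacts, sensor saturation, and any nonlinearity or saturation of the
physiological response.  Passing recovery tests therefore show that the
pipeline inverts its own forward model under realistic noise, drift and
waveform asymmetry — not that the LTI assumptions hold in human data.

### Validation studies

* **Detection benchmark** — 7 event-free recordings of 10 min with base
  periods 2.5–5 s, noise SDs 2–8% and drift amplitudes 10–50% of the
  signal.  Detection is scored by greedy nearest-in-time one-to-one
  pairing against ground truth with a 1 s tolerance; pooled sensitivity
  and positive predictive value reach the 99% range with median
  absolute delay below 0.2 s.
* **Amplitude recovery** — 20 recordings × 10 events (~45 s apart), two
  events at each of five input levels (RP decelerations of 3–15%, RA
  increases of 5–25% of baseline; the implied RFR input is their
  difference), plus 3 non-event controls per recording.  Per measure,
  the Pearson correlation between injected and estimated amplitudes
  exceeds 0.8 and the sign is recovered throughout, while the pooled
  non-event estimate is statistically indistinguishable from zero.
  The problem sizes (10 min recordings, 20 simulated subjects) keep
  each study to a few seconds of compute while giving ~100
  injected/estimated pairs per measure.

One structural property of the pipeline is visible in these studies:
because a cycle's period is anchored at the *following* inspiration,
the apparent latency of an RP response in the interpolated series lags
the generating response peak by up to one breathing cycle.  The
canonical RFs, being fitted to data processed the same way, absorb this
lag; recovery correlations are unaffected.

## Numerical choices

* "Bidirectional" filters are one forward plus one backward pass of a
  first-order Butterworth design (zero phase); "filtered twice with a
  unidirectional filter" is two identical causal forward passes in
  cascade.
* Nelder–Mead Gaussian refits use parameter and function tolerances of
  1e-6 and at most 2000 iterations; sigma is returned as its absolute
  value (the model is even in sigma); an all-zero curve is flagged
  degenerate rather than fitted.
* Serial orthogonalisation (for exploratory multi-component bases,
  added in chronological order) is modified Gram–Schmidt with unit-peak
  renormalisation; a column that collapses below 1e-10 of its input
  peak raises a degenerate-basis error.  The derivative column is not
  orthogonalised against its canonical by default.
* Basis support is 30 s by default (≥ mu + 5 sigma for every shipped
  RF; truncation error < 1e-5 of peak).  The shipped RFs are
  peak-normalised; normalisation affects only the scale of `beta`, not
  test statistics.
* Delimited input auto-detects comma/tab/whitespace and skips `#`
  comments; a time column deviating more than 1% from a uniform grid is
  rejected.  BIDS-style physiological recordings (`*_physio.tsv.gz`
  plus JSON sidecar) are supported read-only.

## Known limitations

* No artefact rejection or despiking; recordings are assumed clean.
* Errors are assumed i.i.d.; no autoregressive error model or
  multi-level inference.
* RA and RFR from a single belt are only proportional to tidal volume
  and flow up to an unknown per-subject constant; no double-belt or
  spirometric calibration is attempted.
* The exact amplitude scale of `beta` depends on the peak-normalisation
  and filtering conventions; comparisons should stay within a fixed
  configuration.
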