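import numpy as np
import pytest
from scipy import signal

from respglm import (
    CycleSeries,
    EventTable,
    InterpolatedMeasure,
    RespirationTrace,
    compute_cycle_measures,
    extract_peri_event,
    filter_measure,
    grand_average,
    interpolate_measure,
    legacy_scores,
    respiration_line_length,
)


def make_cycles(onsets, rp=None, ra=None):
    onsets = np.asarray(onsets, dtype=float)
    rp = np.diff(onsets) if rp is None else np.asarray(rp, dtype=float)
    ra = np.ones_like(rp) if ra is None else np.asarray(ra, dtype=float)
    return CycleSeries(onsets=onsets, rp=rp, ra=ra, rfr=ra / rp)


def cascaded_gain(freq_hz, band, fs=10.0):
    """Analytic gain of the first-order band-pass applied twice in cascade."""
    b, a = signal.butter(1, list(band), btype="bandpass", fs=fs)
    _, h = signal.freqz(b, a, worN=[freq_hz], fs=fs)
    return float(np.abs(h[0]) ** 2)


class TestInterpolation:
    def test_constant_measure_gives_constant_series(self):
        cyc = make_cycles([0, 4, 8, 12, 16])
        im = interpolate_measure(cyc, "rp")
        np.testing.assert_allclose(im.values, 4.0)

    def test_midpoint_is_linear(self):
        cyc = make_cycles([0, 3, 8], rp=[3, 5])
        im = interpolate_measure(cyc, "rp", span=(3.0, 8.0))
        t = im.times
        k = np.argmin(np.abs(t - 5.5))
        assert t[k] == pytest.approx(5.5)
        assert im.values[k] == pytest.approx(4.0)

    def test_anchor_values_exact(self):
        cyc = make_cycles([0, 3, 8, 10], rp=[3.0, 5.0, 2.0])
        im = interpolate_measure(cyc, "rp", span=(0.0, 10.0))
        for anchor, val in [(3.0, 3.0), (8.0, 5.0), (10.0, 2.0)]:
            k = int(round((anchor - im.t0) * im.fs))
            assert im.values[k] == pytest.approx(val, abs=1e-12)

    def test_edges_hold_nearest_anchor(self):
        cyc = make_cycles([2, 5, 9], rp=[3, 4])
        im = interpolate_measure(cyc, "rp", span=(0.0, 12.0))
        assert im.values[0] == pytest.approx(3.0)  # before first anchor at t=5
        assert im.values[-1] == pytest.approx(4.0)  # after last anchor at t=9

    def test_rfr_equals_ra_over_rp_at_anchors(self):
        rng = np.random.default_rng(0)
        # anchors on the 10 Hz grid so anchor samples are grid samples
        onsets = np.cumsum(rng.integers(20, 50, 20)) / 10.0
        rp = np.diff(onsets)
        ra = rng.uniform(0.5, 2.0, rp.size)
        cyc = CycleSeries(onsets=onsets, rp=rp, ra=ra, rfr=ra / rp)
        ims = {k: interpolate_measure(cyc, k) for k in ("rp", "ra", "rfr")}
        for i, anchor in enumerate(onsets[1:-1]):
            k = int(round((anchor - ims["rp"].t0) * 10))
            got = ims["ra"].values[k] / ims["rp"].values[k]
            assert got == pytest.approx(ra[i] / rp[i], abs=1e-12)

    def test_too_few_cycles_rejected(self):
        with pytest.raises(ValueError):
            interpolate_measure(make_cycles([0, 4]), "rp")


class TestFilterMeasure:
    @staticmethod
    def _series(values, fs=10.0):
        return InterpolatedMeasure(kind="rp", values=values, fs=fs, t0=0.0)

    def test_dc_removed(self):
        im = self._series(np.full(6000, 5.0))
        out = filter_measure(im)
        assert abs(np.mean(out.values[3000:])) < 0.05

    @pytest.mark.parametrize("band", [(0.01, 1.0), (0.001, 1.0)])
    def test_gain_at_band_centre_matches_transfer_function(self, band):
        f0 = np.sqrt(band[0] * band[1])  # geometric band centre
        n = int(600 * 10 / (f0 * 6))  # many cycles
        t = np.arange(120000) / 10.0
        im = self._series(np.sin(2 * np.pi * f0 * t))
        out = filter_measure(im, band)
        seg = out.values[out.values.size // 2:]
        amp = np.sqrt(2.0) * np.std(seg)
        assert amp == pytest.approx(cascaded_gain(f0, band), rel=0.02)

    def test_linear_time_invariant_on_interior(self):
        pulse = np.zeros(2000)
        pulse[400] = 1.0
        out1 = filter_measure(self._series(pulse)).values
        shifted = np.roll(pulse, 70)
        out2 = filter_measure(self._series(shifted)).values
        np.testing.assert_allclose(out2[600:1500], out1[530:1430], atol=1e-9)

    def test_output_length_and_band_recorded(self):
        im = self._series(np.ones(500))
        out = filter_measure(im, (0.001, 1.0))
        assert out.values.size == 500
        assert out.filter_band == (0.001, 1.0)

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            filter_measure(self._series(np.ones(100)), (1.0, 0.01))


class TestPeriEvent:
    def test_window_geometry(self):
        im = InterpolatedMeasure(kind="rp", values=np.arange(2000.0), fs=10.0, t0=0.0)
        ev = EventTable(np.array([100.0]), ("c",))
        rows = extract_peri_event(im, ev)
        assert rows.shape == (1, 451)
        assert rows[0, 0] == 950.0  # sample at t = 95.0 s
        assert rows[0, 50] == 1000.0  # event onset at t = 100 s

    def test_out_of_range_event_dropped(self, caplog):
        im = InterpolatedMeasure(kind="rp", values=np.arange(2000.0), fs=10.0, t0=0.0)
        ev = EventTable(np.array([2.0, 100.0]), ("c", "c"))
        with caplog.at_level("WARNING"):
            rows = extract_peri_event(im, ev)
        assert rows.shape[0] == 1
        assert "dropping event" in caplog.text

    def test_identical_events_identical_rows(self):
        rng = np.random.default_rng(3)
        im = InterpolatedMeasure(kind="ra", values=rng.normal(size=3000), fs=10.0, t0=0.0)
        ev = EventTable(np.array([50.0, 50.0]), ("a", "b"))
        rows = extract_peri_event(im, ev)
        np.testing.assert_array_equal(rows[0], rows[1])


class TestGrandAverage:
    def test_pointwise_mean(self):
        out = grand_average([np.array([[1.0, 2, 3], [3, 2, 1]])])
        np.testing.assert_array_equal(out, [2, 2, 2])

    def test_single_epoch_is_itself(self):
        row = np.array([[1.0, 5.0, 2.0]])
        np.testing.assert_array_equal(grand_average([row]), row[0])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            grand_average([np.ones((2, 5)), np.ones((2, 4))])


class TestLegacyScores:
    def test_constant_breathing_zero_drp(self, sine_trace):
        onsets = np.arange(0.0, 300.0, 4.0)
        cyc = compute_cycle_measures(sine_trace, onsets)
        ev = EventTable(np.array([101.0, 201.0]), ("c", "c"))
        scores = legacy_scores(cyc, sine_trace, ev)
        np.testing.assert_allclose(scores.d_rp, 0.0, atol=1e-9)
        np.testing.assert_allclose(scores.rpq, 0.0, atol=1e-9)

    def test_flat_trace_zero_rll(self):
        trace = RespirationTrace(np.full(3000, 7.0), fs=10.0)
        assert respiration_line_length(trace, 10.0, 25.0) == 0.0

    def test_triangle_wave_rll_matches_slope(self):
        # |slope| = 0.8 per second, period 10 s, folds on the 10 Hz grid
        t = np.arange(6000) / 10.0
        tri = 0.8 * np.abs(t % 10.0 - 5.0)
        trace = RespirationTrace(tri, fs=10.0)
        rll = respiration_line_length(trace, 100.0, 115.0)
        assert rll == pytest.approx(0.8 * 15.0, rel=0.01)

    def test_rll_offset_invariant_and_gain_linear(self, sine_trace):
        base = respiration_line_length(sine_trace, 50.0, 65.0)
        shifted = RespirationTrace(sine_trace.values + 100.0, fs=10.0)
        assert respiration_line_length(shifted, 50.0, 65.0) == pytest.approx(base)
        scaled = RespirationTrace(sine_trace.values * 2.5, fs=10.0)
        assert respiration_line_length(scaled, 50.0, 65.0) == pytest.approx(2.5 * base)

    def test_rpq_modes(self, sine_trace):
        onsets = np.array([20.0, 24.0, 30.0, 34.0])  # periods 4, 6, 4
        cyc = compute_cycle_measures(sine_trace, onsets)
        ev = EventTable(np.array([25.0]), ("c",))  # peri cycle has RP 6, pre RP 4
        pct = legacy_scores(cyc, sine_trace, ev, rpq_mode="percent")
        ratio = legacy_scores(cyc, sine_trace, ev, rpq_mode="ratio")
        assert pct.rpq[0] == pytest.approx(50.0)
        assert ratio.rpq[0] == pytest.approx(1.5)
        assert pct.d_rp[0] == pytest.approx(2.0)

    def test_event_without_preceding_cycle_rejected(self, sine_trace):
        cyc = compute_cycle_measures(sine_trace, np.arange(0.0, 300.0, 4.0))
        with pytest.raises(ValueError, match="preceding"):
            legacy_scores(cyc, sine_trace, EventTable(np.array([2.0]), ("c",)))
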