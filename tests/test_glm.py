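import logging

import numpy as np
import pytest

from respglm import (
    EventTable,
    build_design,
    canonical_rf,
    condition_difference_weights,
    contrast,
    fit_glm,
    nonevent_onsets,
    overall_effect_weights,
)


@pytest.fixture
def rf():
    return canonical_rf("rp")


class TestBuildDesign:
    def test_single_event_at_origin(self, rf):
        ev = EventTable(np.array([0.0]), ("c",))
        X, cmap = build_design(ev, rf, n_samples=600, intercept=False)
        sampled = rf.sample()[:, 0]
        np.testing.assert_allclose(X[: sampled.size, 0], sampled)
        np.testing.assert_array_equal(X[sampled.size:, 0], 0.0)
        assert cmap == (("c", "canonical"),)

    def test_superposition_of_two_events(self, rf):
        ev = EventTable(np.array([0.0, 40.0]), ("c", "c"))
        X, _ = build_design(ev, rf, n_samples=800, intercept=False)
        single0, _ = build_design(EventTable(np.array([0.0]), ("c",)), rf, 800, intercept=False)
        single1, _ = build_design(EventTable(np.array([40.0]), ("c",)), rf, 800, intercept=False)
        np.testing.assert_allclose(X[:, 0], single0[:, 0] + single1[:, 0])

    def test_nearest_sample_rounding(self, rf):
        ev = EventTable(np.array([0.26]), ("c",))
        X, _ = build_design(ev, rf, n_samples=400, intercept=False)
        assert X[3, 0] > 0  # impulse lands on sample 3
        assert np.all(X[:3, 0] == 0)

    def test_intercept_column_last(self, rf):
        ev = EventTable(np.array([1.0]), ("c",))
        X, cmap = build_design(ev, rf, n_samples=400)
        np.testing.assert_array_equal(X[:, -1], 1.0)
        assert cmap[-1] == ("intercept", "intercept")

    def test_empty_events_rejected(self, rf):
        with pytest.raises(ValueError):
            build_design(EventTable(np.array([]), ()), rf, 400)

    def test_rate_mismatch_rejected(self):
        rf100 = canonical_rf("rp", fs=100.0)
        with pytest.raises(ValueError, match="Hz"):
            build_design(EventTable(np.array([1.0]), ("c",)), rf100, 400, fs=10.0)


class TestFitGLM:
    def test_noiseless_recovery(self, rng):
        X = rng.normal(size=(400, 5))
        beta_true = np.array([1.0, -2.0, 0.5, 3.0, -0.1])
        res = fit_glm(X, X @ beta_true)
        np.testing.assert_allclose(res.beta, beta_true, atol=1e-10)
        np.testing.assert_allclose(res.residuals, res.Y - res.X @ res.beta)

    def test_matches_normal_equations(self, rng):
        X = rng.normal(size=(400, 5))
        Y = X @ rng.normal(size=5) + rng.normal(size=400)
        res = fit_glm(X, Y)
        oracle = np.linalg.solve(X.T @ X, X.T @ Y)
        np.testing.assert_allclose(res.beta, oracle, rtol=1e-8)

    def test_rank_deficiency_minimum_norm_with_warning(self, rng, caplog):
        x = rng.normal(size=(100, 1))
        X = np.hstack([x, x])
        Y = x[:, 0] * 2.0
        with caplog.at_level(logging.WARNING):
            res = fit_glm(X, Y)
        assert "rank-deficient" in caplog.text
        # minimum-norm solution splits the weight equally
        np.testing.assert_allclose(res.beta, [1.0, 1.0], atol=1e-8)

    def test_shape_and_nan_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_glm(rng.normal(size=(10, 2)), np.zeros(11))
        X = rng.normal(size=(10, 2))
        Y = np.zeros(10)
        Y[0] = np.nan
        with pytest.raises(ValueError):
            fit_glm(X, Y)

    def test_time_invariance_whole_sample_shift(self, rf):
        fs, n = 10.0, 1200
        ev = EventTable(np.array([20.0, 60.0]), ("a", "b"))
        X, cmap = build_design(ev, rf, n_samples=n, fs=fs)
        beta_true = np.array([1.5, -0.7, 0.2])
        Y = X @ beta_true
        res = fit_glm(X, Y, cmap)
        shift = 7  # whole samples
        ev2 = EventTable(ev.onsets + shift / fs, ("a", "b"))
        X2, cmap2 = build_design(ev2, rf, n_samples=n, fs=fs)
        # before the first response the model output is the intercept alone
        Y2 = np.concatenate([np.full(shift, beta_true[2]), Y[:-shift]])
        res2 = fit_glm(X2, Y2, cmap2)
        np.testing.assert_allclose(res2.beta, res.beta, atol=1e-8)


class TestContrast:
    @pytest.fixture
    def fitted(self, rf, rng):
        ev = EventTable(np.array([10.0, 50.0, 90.0]), ("a", "b", "a"))
        X, cmap = build_design(ev, rf, n_samples=1300)
        Y = X @ np.array([2.0, -1.0, 0.5])
        return fit_glm(X, Y, cmap)

    def test_one_hot_returns_beta(self, fitted):
        assert contrast(fitted, [1, 0, 0]) == pytest.approx(fitted.beta[0])

    def test_condition_difference(self, fitted):
        w = condition_difference_weights(fitted, "a", "b")
        assert contrast(fitted, w) == pytest.approx(fitted.beta[0] - fitted.beta[1])

    def test_overall_effect_is_mean_of_canonicals(self, fitted):
        w = overall_effect_weights(fitted)
        assert contrast(fitted, w) == pytest.approx((fitted.beta[0] + fitted.beta[1]) / 2)

    def test_length_mismatch_rejected(self, fitted):
        with pytest.raises(ValueError):
            contrast(fitted, [1.0, 0.0])


class TestNoneventOnsets:
    def test_draw_respects_margin(self):
        ev = EventTable(np.array([40.0, 90.0]), ("c", "c"))
        out = nonevent_onsets(ev, n=1, margin=15.0, seed=0)
        assert 55.0 < out.onsets[0] < 75.0
        assert out.conditions == ("nonevent",)

    def test_infeasible_margin_rejected(self):
        ev = EventTable(np.array([40.0, 90.0]), ("c", "c"))
        with pytest.raises(ValueError):
            nonevent_onsets(ev, n=1, margin=30.0, seed=0)

    def test_reproducible_under_seed(self):
        ev = EventTable(np.array([40.0, 90.0, 150.0]), ("c",) * 3)
        a = nonevent_onsets(ev, n=5, margin=10.0, seed=42)
        b = nonevent_onsets(ev, n=5, margin=10.0, seed=42)
        np.testing.assert_array_equal(a.onsets, b.onsets)
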