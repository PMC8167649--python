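import warnings

import numpy as np
import pytest

from hrvt.io import RRSeries
from hrvt.preprocess import correct_artifacts, smoothness_priors_detrend
from hrvt.synth import RampSpec, generate_ramp, inject_artifacts


def constant_series(n=200, rr=800.0):
    return RRSeries(np.full(n, rr))


class TestArtifactCorrection:
    def test_ectopic_couplet_redistributed(self):
        rr = np.full(100, 800.0)
        rr[50], rr[51] = 400.0, 1200.0
        fixed, report = correct_artifacts(RRSeries(rr))
        assert report.n_corrected == 2
        assert report.fraction == pytest.approx(2 / 100)
        assert fixed.intervals[50] == pytest.approx(800.0)
        assert fixed.intervals[51] == pytest.approx(800.0)
        # total duration preserved
        assert fixed.duration_s == pytest.approx(RRSeries(rr).duration_s, abs=1e-9)

    def test_missed_beat_split(self):
        rr = np.full(100, 800.0)
        rr[40] = 1600.0
        fixed, report = correct_artifacts(RRSeries(rr))
        assert len(fixed) == 101
        assert fixed.intervals[40] == pytest.approx(800.0)
        assert fixed.intervals[41] == pytest.approx(800.0)
        # one detected artifact, one flagged beat
        assert report.n_corrected == 1
        assert fixed.duration_s == pytest.approx(RRSeries(rr).duration_s, abs=1e-9)

    def test_extra_beat_merged(self):
        rr = np.full(100, 800.0)
        rr[60], rr[61] = 200.0, 600.0
        fixed, report = correct_artifacts(RRSeries(rr))
        assert len(fixed) == 99
        assert fixed.intervals[60] == pytest.approx(800.0)
        assert report.n_corrected == 1

    def test_too_short_refused(self):
        with pytest.raises(ValueError, match="shorter"):
            correct_artifacts(constant_series(7))

    def test_unusable_fraction_refused(self):
        rng = np.random.default_rng(3)
        rr = rng.uniform(300, 1500, 60)  # wild jitter: most beats deviate
        with pytest.raises(ValueError, match="unusable"):
            correct_artifacts(RRSeries(rr), abs_floor=1.0, rel_threshold=0.05)

    def test_clean_series_untouched(self, rng):
        rr = 800 + 20 * rng.standard_normal(300)
        fixed, report = correct_artifacts(RRSeries(rr))
        assert report.n_corrected == 0
        assert np.array_equal(fixed.intervals, rr)

    def test_injected_recovery(self):
        """3% injected artifacts: fraction in [2%, 4%], >=90% recalled."""
        series, _ = generate_ramp(RampSpec(seed=5, duration_s=900))
        dirty, positions = inject_artifacts(series, rate=0.03, seed=99)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            fixed, report = correct_artifacts(dirty)
        assert 0.02 <= report.fraction <= 0.04
        hits = sum(
            np.min(np.abs(report.flagged_input_times - t)) < 1.5 for t in positions
        )
        assert hits / len(positions) >= 0.9

    def test_idempotent(self):
        series, _ = generate_ramp(RampSpec(seed=5, duration_s=600))
        dirty, _ = inject_artifacts(series, rate=0.03, seed=4)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            fixed, _ = correct_artifacts(dirty)
            fixed2, report2 = correct_artifacts(
                RRSeries(fixed.intervals)  # fresh flags
            )
        assert report2.fraction <= 0.001

    def test_warns_above_five_percent(self):
        series, _ = generate_ramp(RampSpec(seed=2, duration_s=600))
        dirty, _ = inject_artifacts(
            series, rate=0.08, mix={"missed": 1.0}, seed=8
        )
        with pytest.warns(UserWarning, match="exceeds"):
            correct_artifacts(dirty)


class TestSmoothnessPriors:
    def test_constant_maps_to_zero(self):
        out = smoothness_priors_detrend(np.full(100, 7.5))
        assert np.max(np.abs(out)) < 1e-9

    def test_line_removed_dense_oracle(self):
        """Residual of a pure line matches a dense brute-force solve and is tiny."""
        n = 200
        x = np.linspace(0.0, 50.0, n)
        lam = 500.0
        d2 = np.zeros((n - 2, n))
        for i in range(n - 2):
            d2[i, i : i + 3] = [1.0, -2.0, 1.0]
        trend = np.linalg.solve(np.eye(n) + lam**2 * d2.T @ d2, x)
        expected = x - trend
        out = smoothness_priors_detrend(x, lam)
        assert np.allclose(out, expected, atol=1e-8)
        assert np.max(np.abs(out)) < 0.01 * (x[-1] - x[0])

    def test_linearity(self, rng):
        x = rng.standard_normal(150)
        y = rng.standard_normal(150)
        lhs = smoothness_priors_detrend(2.5 * x + 0.7 * y)
        rhs = 2.5 * smoothness_priors_detrend(x) + 0.7 * smoothness_priors_detrend(y)
        assert np.allclose(lhs, rhs, atol=1e-9)

    def test_white_noise_variance_nearly_kept(self, rng):
        x = rng.standard_normal(200)
        out = smoothness_priors_detrend(x, 500.0)
        assert abs(out.var() / x.var() - 1) < 0.05

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            smoothness_priors_detrend([1.0, 2.0])
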