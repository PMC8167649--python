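import numpy as np
import pytest

from hrvt.ramp import A1Curve, A1Point
from hrvt.threshold import (
    DeclineSegment,
    estimate_hrvt,
    fit_segment,
    segment_from_range,
    select_decline_segment,
)


def make_curve(hr, a1):
    pts = [
        A1Point(
            t_end=120.0 + 5 * i,
            t_start=5.0 * i,
            mean_hr=float(h),
            alpha1=float(a),
            n_beats=150,
            artifact_frac=0.0,
        )
        for i, (h, a) in enumerate(zip(hr, a1))
    ]
    return A1Curve(points=pts)


def make_segment(slope, intercept, hr_lo=120.0, hr_hi=180.0):
    hr = np.linspace(hr_lo, hr_hi, 10)
    return DeclineSegment(
        indices=np.arange(10),
        slope=slope,
        intercept=intercept,
        r2=1.0,
        hr_range=(hr_lo, hr_hi),
        hr=hr,
        alpha1=intercept + slope * hr,
    )


class TestSelect:
    def test_exact_line(self):
        hr = np.linspace(120, 180, 13)
        a1 = np.linspace(1.2, 0.3, 13)
        seg = select_decline_segment(make_curve(hr, a1))
        assert seg.r2 == pytest.approx(1.0, abs=1e-12)
        assert seg.indices[-1] == 12  # extends to the end of the straight drop
        assert seg.indices[0] <= 3  # starts at the edge of the 1.0 level
        assert seg.slope == pytest.approx(-0.9 / 60, rel=1e-9)

    def test_flat_prefix_excluded(self):
        hr = np.concatenate([np.linspace(60, 119, 20), np.linspace(120, 180, 13)])
        a1 = np.concatenate([np.full(20, 1.1), np.linspace(1.2, 0.3, 13)])
        seg = select_decline_segment(make_curve(hr, a1))
        assert seg.indices[0] >= 20
        assert seg.r2 == pytest.approx(1.0, abs=1e-9)

    def test_never_declines(self):
        hr = np.linspace(100, 150, 20)
        a1 = np.full(20, 1.2)
        with pytest.raises(ValueError, match="no decline"):
            select_decline_segment(make_curve(hr, a1))

    def test_curve_too_small(self):
        with pytest.raises(ValueError, match="no decline"):
            select_decline_segment(make_curve([100, 110], [1.0, 0.9]))

    def test_synthetic_boundaries_near_programmed(self, default_ramp):
        """Selected segment brackets the programmed decline interval."""
        from hrvt import HRVThreshold

        series, truth = default_ramp
        res = HRVThreshold(series).fit()
        lo, hi = res.segment.hr_range
        # programmed decline: 140 -> ~183 bpm; 3-point grid slack each side
        assert abs(lo - truth.spec.hr_decline_start) < 10
        assert hi > truth.hr_crossing - 3


class TestManualOverride:
    def test_hr_range(self):
        hr = np.linspace(120, 180, 13)
        a1 = np.linspace(1.2, 0.3, 13)
        seg = segment_from_range(make_curve(hr, a1), hr_range=(140, 170))
        assert seg.hr_range[0] >= 140 and seg.hr_range[1] <= 170
        assert seg.slope == pytest.approx(-0.9 / 60, rel=1e-9)

    def test_requires_exactly_one_range(self):
        curve = make_curve([100, 110, 120], [1.0, 0.8, 0.6])
        with pytest.raises(ValueError):
            segment_from_range(curve)
        with pytest.raises(ValueError):
            segment_from_range(curve, hr_range=(1, 2), time_range=(1, 2))


class TestEstimate:
    def test_closed_form(self):
        seg = make_segment(slope=-0.01, intercept=2.2, hr_lo=140, hr_hi=175)
        assert estimate_hrvt(seg, 0.5).hr == pytest.approx(170.0, abs=1e-12)
        assert estimate_hrvt(seg, 0.75).hr == pytest.approx(145.0, abs=1e-12)

    def test_two_point_anchors(self):
        # line through (120, 1.0) and (170, 0.5)
        curve = make_curve([120.0, 170.0], [1.0, 0.5])
        seg = fit_segment(curve, [0, 1])
        assert estimate_hrvt(seg, 0.5, max_extrap_bpm=1).hr == pytest.approx(170.0)
        assert estimate_hrvt(seg, 0.75, max_extrap_bpm=1).hr == pytest.approx(145.0)

    def test_hrvt_below_hrvt2(self):
        seg = make_segment(slope=-0.008, intercept=1.9)
        assert estimate_hrvt(seg, 0.75, 99).hr < estimate_hrvt(seg, 0.5, 99).hr

    def test_extrapolation_flag_and_cap(self):
        seg = make_segment(slope=-0.01, intercept=2.2, hr_lo=120, hr_hi=165)
        est = estimate_hrvt(seg, 0.5)  # crossing 170, 5 bpm beyond range
        assert est.extrapolated
        with pytest.raises(ValueError, match="170"):
            estimate_hrvt(seg, 0.5, max_extrap_bpm=3)

    def test_refit_reproduces_parameters(self, default_ramp):
        from hrvt import HRVThreshold

        series, _ = default_ramp
        res = HRVThreshold(series).fit()
        refit = fit_segment(res.curve, res.segment.indices)
        assert refit.slope == res.segment.slope
        assert refit.intercept == res.segment.intercept

    def test_subsampling_robustness(self, default_ramp):
        """Estimates move < 2 bpm when the curve is thinned by factor 2."""
        from hrvt import HRVThreshold
        from hrvt.ramp import A1Curve

        series, _ = default_ramp
        res = HRVThreshold(series).fit()
        thin = A1Curve(points=res.curve.points[::2])
        seg = select_decline_segment(thin)
        est = estimate_hrvt(seg, 0.5)
        assert abs(est.hr - res.hrvt2) < 2.0
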