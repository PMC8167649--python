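"""Threshold detection on the alpha1-vs-HR curve.

During an incremental ramp the rolling alpha1 curve is typically
reverse-sigmoidal: stable above 1.0 at easy work rates, a rapid,
near-linear drop through 0.5 at high intensity, then a flat
anticorrelated tail.  The heart rate at which a straight line fitted
through the drop crosses a target alpha1 defines the HRV-derived
thresholds: alpha1 = 0.75 gives the aerobic-threshold surrogate (HRVT)
and alpha1 = 0.5 the anaerobic-threshold surrogate (HRVT2).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .ramp import A1Curve

__all__ = [
    "DeclineSegment",
    "ThresholdEstimate",
    "select_decline_segment",
    "fit_segment",
    "estimate_hrvt",
]


@dataclass
class DeclineSegment:
    """Contiguous run of curve points carrying the linear decline.

    ``slope``/``intercept`` parameterise the OLS fit of alpha1 on mean
    HR (alpha1 dependent); ``hr_range`` is the [min, max] heart-rate
    span of the fitted points.
    """

    indices: np.ndarray
    slope: float
    intercept: float
    r2: float
    hr_range: tuple
    hr: np.ndarray
    alpha1: np.ndarray

    def __post_init__(self) -> None:
        if self.slope >= 0:
            raise ValueError("decline segment must have negative slope")
        if not 0.0 <= self.r2 <= 1.0 + 1e-12:
            raise ValueError("r2 out of range")
        if len(self.indices) < 2 or np.any(np.diff(self.indices) != 1):
            raise ValueError("segment indices must be contiguous")

    def predict(self, hr) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(hr, dtype=float)


@dataclass
class ThresholdEstimate:
    """Heart rate at which the fitted decline crosses a target alpha1."""

    target_alpha1: float
    hr: float
    extrapolated: bool
    segment: DeclineSegment


def _running_median(a: np.ndarray, width: int) -> np.ndarray:
    half = width // 2
    return np.array(
        [np.median(a[max(0, i - half) : i + half + 1]) for i in range(len(a))]
    )


def _ols(hr: np.ndarray, a1: np.ndarray) -> tuple[float, float, float]:
    slope, intercept = np.polyfit(hr, a1, 1)
    resid = a1 - (intercept + slope * hr)
    ss_tot = float(np.sum((a1 - a1.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 0.0
    return float(slope), float(intercept), min(max(r2, 0.0), 1.0)


def fit_segment(curve: A1Curve, indices: Sequence[int]) -> DeclineSegment:
    """OLS line through an explicitly chosen contiguous index range."""
    idx = np.asarray(list(indices), dtype=int)
    hr = curve.mean_hr[idx]
    a1 = curve.alpha1[idx]
    slope, intercept, r2 = _ols(hr, a1)
    return DeclineSegment(
        indices=idx,
        slope=slope,
        intercept=intercept,
        r2=r2,
        hr_range=(float(hr.min()), float(hr.max())),
        hr=hr,
        alpha1=a1,
    )


def segment_from_range(
    curve: A1Curve,
    hr_range: Optional[tuple] = None,
    time_range: Optional[tuple] = None,
) -> DeclineSegment:
    """Manual segment selection by a heart-rate or time window.

    Mirrors the visual workflow in which an analyst marks the straight
    section of the plot by hand; all points whose mean HR (or window
    end time) falls inside the closed range are fitted.
    """
    if (hr_range is None) == (time_range is None):
        raise ValueError("give exactly one of hr_range or time_range")
    if hr_range is not None:
        lo, hi = sorted(hr_range)
        mask = (curve.mean_hr >= lo) & (curve.mean_hr <= hi)
    else:
        lo, hi = sorted(time_range)
        mask = (curve.t_end >= lo) & (curve.t_end <= hi)
    idx = np.flatnonzero(mask)
    if len(idx) < 2:
        raise ValueError("manual range selects fewer than 2 curve points")
    return fit_segment(curve, np.arange(idx[0], idx[-1] + 1))


def select_decline_segment(
    curve: A1Curve,
    hi: float = 1.0,
    lo: float = 0.5,
    min_points: int = 4,
) -> DeclineSegment:
    """Automatically locate the rapid near-linear decline.

    Anchors are found on a 7-point running-median smoothing of the
    curve (the fit always uses raw points): the start is the last
    point before the smoothed curve drops below ``hi`` for good (or
    the first point if it never exceeds ``hi``); the base end is the
    first point at or below ``lo``, extended forward while successive
    points stay inside the residual band of the running fit (2 base
    residual SDs, floored at 0.04 alpha1 units) — the "continues in a
    straight fashion" rule.  Among the candidate windows with negative
    slope and at least ``min_points`` points the one maximising r2 is
    returned, ties broken by the longer window, then the earlier start.

    Raises
    ------
    ValueError
        If no contiguous run with negative slope and the required
        length exists ("no decline found").
    """
    a1 = curve.alpha1
    hr = curve.mean_hr
    n = len(a1)
    if n < min_points:
        raise ValueError(
            f"no decline found: curve has {n} points (< {min_points})"
        )
    # anchors are located on a running-median-smoothed curve so that
    # single noisy windows cannot move them; the fit itself always uses
    # the raw points
    sm = _running_median(a1, 7)
    if np.all(sm >= hi):
        raise ValueError(f"no decline found: alpha1 never drops below {hi}")
    # last point before the (smoothed) curve drops below `hi` for good;
    # noise in the stable high-alpha1 plateau may dip below `hi`
    # transiently, so the final point at or above the level anchors the
    # decline start
    at_or_above = np.flatnonzero(sm >= hi)
    s0 = int(at_or_above[-1]) if len(at_or_above) else 0
    s0 = min(s0, n - min_points)
    at_lo = np.flatnonzero(sm[s0:] <= lo)
    e0 = s0 + int(at_lo[0]) if len(at_lo) else n - 1
    e0 = min(max(e0, s0 + 1), n - 1)

    # forward extension: keep adding points while the curve continues
    # inside the residual band of the base decline fit (floor 0.04 so a
    # near-perfect base fit still tolerates estimator jitter); a point
    # passes if its raw or its smoothed value stays in band
    base = np.arange(s0, e0 + 1)
    slope_b, icpt_b, _ = _ols(hr[base], a1[base])
    band = max(
        2.0 * float(np.std(a1[base] - (icpt_b + slope_b * hr[base]))), 0.04
    )
    e_ext = e0
    while e_ext + 1 < n:
        seg = np.arange(s0, e_ext + 1)
        slope, intercept, _ = _ols(hr[seg], a1[seg])
        nxt = e_ext + 1
        pred = intercept + slope * hr[nxt]
        if min(abs(a1[nxt] - pred), abs(sm[nxt] - pred)) <= band + 1e-9:
            e_ext = nxt
        else:
            break

    best = None  # ((r2, length, -start), segment)
    for s in range(s0, min(s0 + 3, n - min_points) + 1):
        for e in range(max(e_ext - 2, s + min_points - 1), e_ext + 1):
            idx = np.arange(s, e + 1)
            if len(idx) < min_points or e > n - 1:
                continue
            slope, intercept, r2 = _ols(hr[idx], a1[idx])
            if slope >= 0:
                continue
            key = (r2, len(idx), -s)
            if best is None or key > best[0]:
                best = (
                    key,
                    DeclineSegment(
                        indices=idx,
                        slope=slope,
                        intercept=intercept,
                        r2=r2,
                        hr_range=(float(hr[idx].min()), float(hr[idx].max())),
                        hr=hr[idx],
                        alpha1=a1[idx],
                    ),
                )
    if best is None:
        raise ValueError(
            "no decline found: no contiguous negative-slope run of "
            f">= {min_points} points"
        )
    return best[1]


def estimate_hrvt(
    segment: DeclineSegment,
    target: float = 0.5,
    max_extrap_bpm: float = 10.0,
) -> ThresholdEstimate:
    """Solve the fitted decline for the HR at a target alpha1.

    ``hr = (target - intercept) / slope``.  The estimate is marked
    extrapolated when it falls outside the heart-rate span of the
    fitted points; extrapolation beyond ``max_extrap_bpm`` raises.
    """
    if segment.slope >= 0:
        raise ValueError("cannot solve a non-declining segment for a threshold")
    hr = (target - segment.intercept) / segment.slope
    lo, hi = segment.hr_range
    extrapolated = not (lo <= hr <= hi)
    distance = max(0.0, lo - hr, hr - hi)
    if distance > max_extrap_bpm:
        raise ValueError(
            f"crossing of alpha1 = {target} at {hr:.1f} bpm lies "
            f"{distance:.1f} bpm outside the fitted range [{lo:.1f}, "
            f"{hi:.1f}] (cap {max_extrap_bpm:.0f} bpm)"
        )
    return ThresholdEstimate(
        target_alpha1=float(target),
        hr=float(hr),
        extrapolated=bool(extrapolated),
        segment=segment,
    )
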