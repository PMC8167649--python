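"""Model/Results front-end over the analysis pipeline.

Two statsmodels-style entry points:

* :class:`HRVThreshold` — built from an RR series; ``fit()`` runs
  artifact correction, the rolling short-term DFA exponent, decline
  selection and threshold solving, returning
  :class:`HRVThresholdResults` with the curve, the fitted segment, the
  threshold estimates and a ``summary()``.
* :class:`MethodAgreement` — built from paired reference/estimated
  threshold HRs; ``fit()`` returns :class:`AgreementResults` wrapping
  the full method-comparison report.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import io as _io
from .agreement import AgreementReport, agreement_stats
from .preprocess import ArtifactReport, correct_artifacts
from .ramp import A1Curve, rolling_alpha1
from .threshold import (
    DeclineSegment,
    estimate_hrvt,
    segment_from_range,
    select_decline_segment,
)

__all__ = [
    "HRVThreshold",
    "HRVThresholdResults",
    "MethodAgreement",
    "AgreementResults",
]


class HRVThreshold:
    """Heart-rate-variability threshold model for one exercise test.

    Parameters
    ----------
    series : RRSeries
        The incremental-test RR record (ms intervals).
    window_s, step_s : float
        Rolling-window length and step (default 120 s / 5 s).
    min_beats : int
        Minimum beats per window; shorter windows are skipped.
    detrend_mode : {'window', 'global', 'off'}
        Smoothness-priors detrending scope (lambda below).
    detrend_lambda : float
        Regularisation of the smoothness-priors detrend (default 500).
    correct : bool
        Apply artifact correction before analysis (default True).
    artifact_kwargs : dict, optional
        Forwarded to :func:`hrvt.preprocess.correct_artifacts`.

    Examples
    --------
    >>> from hrvt.synth import RampSpec, generate_ramp
    >>> series, truth = generate_ramp(RampSpec(seed=7))
    >>> res = HRVThreshold(series).fit()
    >>> abs(res.estimates[0.5].hr - truth.hr_crossing) < 3
    True
    """

    def __init__(
        self,
        series,
        window_s: float = 120.0,
        step_s: float = 5.0,
        min_beats: int = 100,
        detrend_mode: str = "window",
        detrend_lambda: float = 500.0,
        scale_min: int = 4,
        scale_max: int = 16,
        reverse_pass: bool = False,
        correct: bool = True,
        artifact_kwargs: Optional[dict] = None,
    ) -> None:
        self.series = series
        self.window_s = window_s
        self.step_s = step_s
        self.min_beats = min_beats
        self.detrend_mode = detrend_mode
        self.detrend_lambda = detrend_lambda
        self.scale_min = scale_min
        self.scale_max = scale_max
        self.reverse_pass = reverse_pass
        self.correct = correct
        self.artifact_kwargs = artifact_kwargs or {}

    @classmethod
    def from_file(cls, path, dialect: str = "plain_ms", **kwargs) -> "HRVThreshold":
        """Build the model straight from an RR file."""
        return cls(_io.read_rr(path, dialect=dialect), **kwargs)

    def fit(
        self,
        targets: Sequence[float] = (0.75, 0.5),
        hi: float = 1.0,
        lo: float = 0.5,
        min_points: int = 4,
        max_extrap_bpm: float = 10.0,
        segment_hr: Optional[tuple] = None,
        segment_time: Optional[tuple] = None,
    ) -> "HRVThresholdResults":
        """Run the full pipeline and solve for the target crossings.

        ``segment_hr``/``segment_time`` override automatic decline
        selection with a manual heart-rate or time range, reproducing
        the visual-inspection workflow.
        """
        if self.correct:
            corrected, report = correct_artifacts(self.series, **self.artifact_kwargs)
        else:
            corrected, report = self.series, None
        curve = rolling_alpha1(
            corrected,
            window_s=self.window_s,
            step_s=self.step_s,
            min_beats=self.min_beats,
            detrend_mode=self.detrend_mode,
            detrend_lambda=self.detrend_lambda,
            scale_min=self.scale_min,
            scale_max=self.scale_max,
            reverse_pass=self.reverse_pass,
        )
        if segment_hr is not None or segment_time is not None:
            segment = segment_from_range(curve, segment_hr, segment_time)
        else:
            segment = select_decline_segment(
                curve, hi=hi, lo=lo, min_points=min_points
            )
        estimates = {
            float(t): estimate_hrvt(segment, target=t, max_extrap_bpm=max_extrap_bpm)
            for t in targets
        }
        return HRVThresholdResults(
            model=self,
            corrected_series=corrected,
            artifact_report=report,
            curve=curve,
            segment=segment,
            estimates=estimates,
        )


@dataclass
class HRVThresholdResults:
    """Fitted thresholds plus everything needed to audit them."""

    model: HRVThreshold
    corrected_series: object
    artifact_report: Optional[ArtifactReport]
    curve: A1Curve
    segment: DeclineSegment
    estimates: dict

    @property
    def hrvt(self) -> Optional[float]:
        """HR at alpha1 = 0.75 (aerobic-threshold surrogate), if fitted."""
        est = self.estimates.get(0.75)
        return est.hr if est else None

    @property
    def hrvt2(self) -> Optional[float]:
        """HR at alpha1 = 0.5 (anaerobic-threshold surrogate), if fitted."""
        est = self.estimates.get(0.5)
        return est.hr if est else None

    def summary(self) -> str:
        seg = self.segment
        lines = [
            "HRV threshold analysis",
            "=" * 48,
            f"beats analysed            {len(self.corrected_series):>10d}",
            f"recording duration (s)    {self.corrected_series.duration_s:>10.1f}",
        ]
        if self.artifact_report is not None:
            lines.append(
                f"corrected artifacts       {self.artifact_report.n_corrected:>10d}"
                f" ({self.artifact_report.fraction:.2%})"
            )
        lines += [
            f"curve points              {len(self.curve):>10d}"
            f"  (skipped {len(self.curve.skipped)})",
            f"decline segment           {len(seg.indices):>10d} points, "
            f"HR {seg.hr_range[0]:.1f}-{seg.hr_range[1]:.1f} bpm",
            f"segment fit               slope {seg.slope:.5f} /bpm, "
            f"intercept {seg.intercept:.3f}, r2 {seg.r2:.3f}",
        ]
        for t in sorted(self.estimates, reverse=True):
            est = self.estimates[t]
            tag = " (extrapolated)" if est.extrapolated else ""
            name = {0.75: "HRVT ", 0.5: "HRVT2"}.get(t, f"a1={t:g}")
            lines.append(f"{name} @ alpha1 = {t:<5g}    {est.hr:>10.1f} bpm{tag}")
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        _io.write_results(self.curve, list(self.estimates.values()), path)

    def plot(self, ax=None):
        """alpha1-vs-HR curve with the fitted decline and crossings."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.curve.mean_hr, self.curve.alpha1, "o", ms=3, label="alpha1")
        hr_line = np.linspace(*self.segment.hr_range, 50)
        ax.plot(hr_line, self.segment.predict(hr_line), "-", label="decline fit")
        for t, est in self.estimates.items():
            ax.axhline(t, ls=":", lw=0.8)
            ax.axvline(est.hr, ls=":", lw=0.8)
            ax.annotate(f"{est.hr:.0f}", (est.hr, t))
        ax.set_xlabel("heart rate (bpm)")
        ax.set_ylabel("DFA alpha1")
        ax.legend()
        return ax


class MethodAgreement:
    """Agreement model between reference and estimated threshold HRs."""

    def __init__(self, pairs) -> None:
        if not isinstance(pairs, pd.DataFrame):
            pairs = pd.DataFrame(pairs, columns=["ref_hr", "est_hr"])
        self.pairs = pairs

    @classmethod
    def from_file(cls, path) -> "MethodAgreement":
        return cls(_io.read_pairs(path))

    def fit(self) -> "AgreementResults":
        return AgreementResults(self, agreement_stats(self.pairs))


@dataclass
class AgreementResults:
    model: MethodAgreement
    report: AgreementReport

    def summary(self) -> str:
        return self.report.summary()

    def to_csv(self, path) -> None:
        self.report.to_frame().to_csv(path, index=False)

    def plot_bland_altman(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ref = self.model.pairs["ref_hr"].to_numpy(float)
        est = self.model.pairs["est_hr"].to_numpy(float)
        mean = (ref + est) / 2
        diff = est - ref
        ax.plot(mean, diff, "o")
        r = self.report
        for y, ls in ((r.bias, "-"), (r.loa_low, "--"), (r.loa_high, "--")):
            ax.axhline(y, ls=ls, color="k", lw=0.8)
        ax.set_xlabel("mean of methods (bpm)")
        ax.set_ylabel("estimate - reference (bpm)")
        return ax

    def plot_scatter(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ref = self.model.pairs["ref_hr"].to_numpy(float)
        est = self.model.pairs["est_hr"].to_numpy(float)
        ax.plot(ref, est, "o")
        lims = [min(ref.min(), est.min()) - 5, max(ref.max(), est.max()) + 5]
        ax.plot(lims, lims, color="0.7", lw=0.8)
        r = self.report
        if np.isfinite(r.slope):
            x = np.linspace(*lims, 10)
            ax.plot(x, r.intercept + r.slope * x, "k-", lw=0.8)
        ax.set_xlabel("reference HR (bpm)")
        ax.set_ylabel("estimated HR (bpm)")
        return ax
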