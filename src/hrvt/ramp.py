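"""Rolling alpha1 over an incremental exercise test.

A 2-minute window is stepped every 5 s across the recording; inside
each window the beat intervals are (optionally) detrended and the
short-term DFA exponent computed, together with the window's mean heart
rate and corrected-artifact fraction.  The resulting alpha1-vs-HR curve
is the input to threshold detection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
import numpy as np
import pandas as pd

from .dfa import dfa_alpha1
from .io import FLAG_OK, RRSeries
from .preprocess import smoothness_priors_detrend

__all__ = ["A1Point", "A1Curve", "rolling_alpha1"]

logger = logging.getLogger(__name__)


@dataclass
class A1Point:
    """One rolling-window result.

    ``mean_hr`` is ``60000 / mean(RR)`` over the window (bpm), i.e. the
    rate implied by the mean interval, not the mean of instantaneous
    rates.
    """

    t_end: float
    t_start: float
    mean_hr: float
    alpha1: float
    n_beats: int
    artifact_frac: float


@dataclass
class A1Curve:
    """Ordered collection of rolling-window results."""

    points: list
    provenance: dict = field(default_factory=dict)
    skipped: list = field(default_factory=list)  # (t_end, reason)

    def __len__(self) -> int:
        return len(self.points)

    @property
    def mean_hr(self) -> np.ndarray:
        return np.array([p.mean_hr for p in self.points])

    @property
    def alpha1(self) -> np.ndarray:
        return np.array([p.alpha1 for p in self.points])

    @property
    def t_end(self) -> np.ndarray:
        return np.array([p.t_end for p in self.points])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_end_s": self.t_end,
                "mean_hr_bpm": self.mean_hr,
                "alpha1": self.alpha1,
                "n_beats": [p.n_beats for p in self.points],
                "artifact_frac": [p.artifact_frac for p in self.points],
            }
        )


def rolling_alpha1(
    series: RRSeries,
    window_s: float = 120.0,
    step_s: float = 5.0,
    min_beats: int = 100,
    detrend_mode: str = "window",
    detrend_lambda: float = 500.0,
    scale_min: int = 4,
    scale_max: int = 16,
    reverse_pass: bool = False,
) -> A1Curve:
    """Compute the alpha1-vs-HR curve of an exercise recording.

    For each window end time ``t_end`` on the grid ``window_s,
    window_s + step_s, ...`` up to the total duration, the beats whose
    onset lies in the half-open interval ``[t_end - window_s, t_end)``
    are selected; windows holding fewer than ``min_beats`` beats, or
    with zero fluctuation, are skipped (recorded in ``curve.skipped``).

    ``detrend_mode`` is one of ``window`` (smoothness-priors detrending
    of each window's beats just before DFA; default), ``global`` (one
    detrend of the whole series up front) or ``off``.
    """
    if detrend_mode not in ("window", "global", "off"):
        raise ValueError(f"unknown detrend_mode {detrend_mode!r}")
    duration = series.duration_s
    if duration < window_s:
        raise ValueError(
            f"recording of {duration:.1f} s is shorter than one "
            f"{window_s:.0f} s window"
        )
    times = series.times
    rr = series.intervals
    corrected = series.flags != FLAG_OK

    analysed = rr
    if detrend_mode == "global":
        analysed = smoothness_priors_detrend(rr, detrend_lambda)

    n_steps = int(np.floor((duration - window_s) / step_s + 1e-9))
    t_ends = window_s + step_s * np.arange(n_steps + 1)

    points: list[A1Point] = []
    skipped: list[tuple[float, str]] = []
    for t_end in t_ends:
        i0 = np.searchsorted(times, t_end - window_s, side="left")
        i1 = np.searchsorted(times, t_end, side="left")
        nb = i1 - i0
        if nb < min_beats:
            skipped.append((float(t_end), f"only {nb} beats (< {min_beats})"))
            logger.info("skipping window ending %.0f s: %d beats", t_end, nb)
            continue
        window = rr[i0:i1]
        x = analysed[i0:i1]
        if detrend_mode == "window":
            x = smoothness_priors_detrend(window, detrend_lambda)
        try:
            res = dfa_alpha1(
                x, scale_min=scale_min, scale_max=scale_max, reverse_pass=reverse_pass
            )
        except ValueError as exc:
            skipped.append((float(t_end), str(exc)))
            logger.info("skipping window ending %.0f s: %s", t_end, exc)
            continue
        points.append(
            A1Point(
                t_end=float(t_end),
                t_start=float(t_end - window_s),
                mean_hr=60000.0 / float(window.mean()),
                alpha1=res.alpha1,
                n_beats=int(nb),
                artifact_frac=float(corrected[i0:i1].mean()),
            )
        )
    return A1Curve(
        points=points,
        provenance={
            "window_s": window_s,
            "step_s": step_s,
            "min_beats": min_beats,
            "detrend_mode": detrend_mode,
            "detrend_lambda": detrend_lambda,
            "scale_min": scale_min,
            "scale_max": scale_max,
            "reverse_pass": reverse_pass,
        },
        skipped=skipped,
    )
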