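"""Reading and writing RR-interval series and tabular results.

The on-disk interchange formats are deliberately minimal plain text:

``plain_ms``
    one RR interval in milliseconds per line; blank lines and lines
    starting with ``#`` are ignored.
``time_interval_csv``
    CSV with header ``time_s,rr_ms`` where ``time_s`` is the cumulative
    onset time of each beat.

Units are fixed throughout the package: intervals in ms, cumulative time
in s, heart rate in bpm.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "RRSeries",
    "FLAG_OK",
    "FLAG_ECTOPIC",
    "FLAG_MISSED",
    "FLAG_EXTRA",
    "read_rr",
    "write_rr",
    "write_results",
    "read_pairs",
]

#: per-beat annotation values
FLAG_OK = "ok"
FLAG_ECTOPIC = "corrected_ectopic"
FLAG_MISSED = "corrected_missed"
FLAG_EXTRA = "corrected_extra"

_VALID_FLAGS = frozenset({FLAG_OK, FLAG_ECTOPIC, FLAG_MISSED, FLAG_EXTRA})


class RRParseError(ValueError):
    """A token in an RR file could not be interpreted."""


@dataclass
class RRSeries:
    """A beat-by-beat RR-interval record.

    Parameters
    ----------
    intervals : array-like
        Beat-to-beat durations in milliseconds; strictly positive.
    times : array-like, optional
        Cumulative onset time of each beat in seconds, ``times[0] = 0``
        and ``times[k] = times[k-1] + intervals[k-1] / 1000``.  Rebuilt
        from the intervals when omitted.
    flags : sequence of str, optional
        Per-beat annotation, one of ``ok``, ``corrected_ectopic``,
        ``corrected_missed``, ``corrected_extra``.  Defaults to all ok.
    meta : str
        Free-form source description.
    """

    intervals: np.ndarray
    times: np.ndarray = None
    flags: np.ndarray = None
    meta: str = ""

    def __post_init__(self) -> None:
        self.intervals = np.asarray(self.intervals, dtype=float)
        if self.intervals.ndim != 1 or self.intervals.size == 0:
            raise ValueError("intervals must be a non-empty 1-d sequence")
        if not np.all(np.isfinite(self.intervals)) or np.any(self.intervals <= 0):
            raise ValueError("all RR intervals must be strictly positive and finite")
        rebuilt = self.cumulative_times(self.intervals)
        if self.times is None:
            self.times = rebuilt
        else:
            self.times = np.asarray(self.times, dtype=float)
            if self.times.shape != self.intervals.shape:
                raise ValueError("times and intervals must have equal length")
            if np.any(np.diff(self.times) <= 0):
                raise ValueError("times must be strictly increasing")
        if self.flags is None:
            self.flags = np.full(self.intervals.shape, FLAG_OK, dtype=object)
        else:
            self.flags = np.asarray(self.flags, dtype=object)
            if self.flags.shape != self.intervals.shape:
                raise ValueError("flags must have the same length as intervals")
            bad = set(self.flags) - _VALID_FLAGS
            if bad:
                raise ValueError(f"unknown beat flags: {sorted(bad)}")

    @staticmethod
    def cumulative_times(intervals: np.ndarray) -> np.ndarray:
        """Onset times (s) implied by a sequence of intervals (ms)."""
        t = np.empty(len(intervals))
        t[0] = 0.0
        np.cumsum(np.asarray(intervals, dtype=float)[:-1] / 1000.0, out=t[1:])
        return t

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def duration_s(self) -> float:
        """Total recording duration in seconds (sum of all intervals)."""
        return float(np.sum(self.intervals)) / 1000.0

    @property
    def n_flagged(self) -> int:
        return int(np.sum(self.flags != FLAG_OK))

    def copy(self) -> "RRSeries":
        return RRSeries(
            self.intervals.copy(), self.times.copy(), self.flags.copy(), self.meta
        )


def read_rr(path, dialect: str = "plain_ms") -> RRSeries:
    """Read an RR-interval series from disk.

    Parameters
    ----------
    path : path-like
    dialect : {'plain_ms', 'time_interval_csv'}

    Returns
    -------
    RRSeries
        Cumulative times are rebuilt from the intervals; for the CSV
        dialect the file-supplied times are validated against the
        rebuilt ones to within 1 ms.  All flags start as ``ok``.
    """
    path = Path(path)
    text = path.read_text()
    if dialect == "plain_ms":
        intervals = []
        for lineno, raw in enumerate(text.splitlines(), start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            try:
                val = float(line)
            except ValueError:
                raise RRParseError(
                    f"{path}: non-numeric RR value {line!r} at line {lineno}"
                ) from None
            if not np.isfinite(val) or val <= 0:
                raise ValueError(
                    f"{path}: non-positive RR interval {val} at line {lineno}"
                )
            intervals.append(val)
        if not intervals:
            raise ValueError(f"{path}: no RR intervals found")
        return RRSeries(np.array(intervals), meta=str(path))
    if dialect == "time_interval_csv":
        try:
            df = pd.read_csv(path)
        except pd.errors.EmptyDataError:
            raise ValueError(f"{path}: no RR intervals found") from None
        for col in ("time_s", "rr_ms"):
            if col not in df.columns:
                raise RRParseError(f"{path}: missing required column {col!r}")
        bad = df.index[~np.isfinite(pd.to_numeric(df["rr_ms"], errors="coerce"))]
        if len(bad):
            # +2: header line plus 1-based numbering
            raise RRParseError(
                f"{path}: non-numeric RR value at line {int(bad[0]) + 2}"
            )
        if df.empty:
            raise ValueError(f"{path}: no RR intervals found")
        intervals = df["rr_ms"].to_numpy(dtype=float)
        if np.any(intervals <= 0):
            line = int(np.flatnonzero(intervals <= 0)[0]) + 2
            raise ValueError(f"{path}: non-positive RR interval at line {line}")
        series = RRSeries(intervals, meta=str(path))
        supplied = df["time_s"].to_numpy(dtype=float)
        if np.max(np.abs(supplied - series.times)) > 1e-3:
            raise ValueError(
                f"{path}: time_s column inconsistent with cumulative rr_ms "
                "(deviation exceeds 1 ms)"
            )
        return series
    raise ValueError(f"unknown RR dialect {dialect!r}")


def write_rr(series: RRSeries, path, dialect: str = "plain_ms") -> None:
    """Write an RR series in one of the interchange dialects."""
    path = Path(path)
    if dialect == "plain_ms":
        lines = [f"# {series.meta}"] if series.meta else []
        lines += [format(v, ".6f").rstrip("0").rstrip(".") for v in series.intervals]
        path.write_text("\n".join(lines) + "\n")
    elif dialect == "time_interval_csv":
        pd.DataFrame(
            {"time_s": series.times, "rr_ms": series.intervals}
        ).to_csv(path, index=False, float_format="%.6f")
    else:
        raise ValueError(f"unknown RR dialect {dialect!r}")


def write_results(curve, estimates: Iterable, path) -> None:
    """Write a rolling-alpha1 curve and threshold estimates as CSV.

    The file holds two sections: the per-window curve with header
    ``t_end_s,mean_hr_bpm,alpha1,n_beats,artifact_frac`` and, after a
    blank line, the estimates with header
    ``target_alpha1,hr_bpm,extrapolated,segment_r2``.
    """
    points = list(curve.points)
    if not points:
        raise ValueError("cannot write an empty alpha1 curve")
    lines = ["t_end_s,mean_hr_bpm,alpha1,n_beats,artifact_frac"]
    for p in points:
        lines.append(
            f"{p.t_end:.6f},{p.mean_hr:.9f},{p.alpha1:.12f},"
            f"{p.n_beats},{p.artifact_frac:.9f}"
        )
    lines.append("")
    lines.append("target_alpha1,hr_bpm,extrapolated,segment_r2")
    for est in estimates:
        lines.append(
            f"{est.target_alpha1:g},{est.hr:.9f},"
            f"{'true' if est.extrapolated else 'false'},{est.segment.r2:.12f}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_results(path):
    """Re-parse a :func:`write_results` file into two DataFrames."""
    text = Path(path).read_text()
    head, _, tail = text.partition("\n\n")
    import io as _io

    curve = pd.read_csv(_io.StringIO(head))
    ests = pd.read_csv(_io.StringIO(tail))
    return curve, ests


def read_pairs(path) -> pd.DataFrame:
    """Read paired reference/estimated threshold HRs.

    Expects CSV with header ``id,ref_hr,est_hr``.
    """
    df = pd.read_csv(path)
    missing = {"id", "ref_hr", "est_hr"} - set(df.columns)
    if missing:
        raise RRParseError(f"{path}: missing required columns {sorted(missing)}")
    return df
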