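"""Synthetic RR series with known correlation structure.

Three generators:

* :func:`generate_fgn` — exact fractional Gaussian noise by circulant
  embedding (Davies–Harte), the stationary benchmark whose short-term
  DFA exponent is ~H.
* :func:`generate_ramp` — a full incremental exercise test: heart rate
  rises linearly while the beat-to-beat fluctuation is fractionally
  integrated noise whose integration order follows a programmed alpha1
  profile (plateau above 1.0, linear decline through 0.5 at a known
  heart rate, anticorrelated tail).  At the programmed crossing the
  fluctuation is exactly white, so alpha1 = 0.5 there by construction
  and the crossing heart rate serves as ground truth for end-to-end
  threshold recovery.
* :func:`inject_artifacts` — seeded ectopic / missed-beat / extra-beat
  contamination with ground-truth positions, for exercising the
  artifact-correction contract.

All generators are pure functions of their seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import RRSeries

__all__ = [
    "RampSpec",
    "RampTruth",
    "generate_fgn",
    "generate_ramp",
    "inject_artifacts",
]


def generate_fgn(hurst: float, n: int, seed: int) -> np.ndarray:
    """Exact fractional Gaussian noise by circulant embedding.

    Returns a zero-mean, unit-variance stationary sequence whose
    autocovariance is ``0.5 * (|k+1|^2H - 2|k|^2H + |k-1|^2H)``.
    H = 0.5 gives white noise; H > 0.5 persistent, H < 0.5
    antipersistent increments.  Bit-reproducible for a fixed seed.
    """
    if not 0.0 < hurst < 1.0:
        raise ValueError(f"Hurst parameter must lie in (0, 1), got {hurst}")
    if n < 2:
        raise ValueError("need n >= 2")
    rng = np.random.default_rng(seed)
    m = 1
    while m < n:
        m *= 2
    k = np.arange(m + 1, dtype=float)
    h2 = 2.0 * hurst
    gamma = 0.5 * ((k + 1) ** h2 - 2.0 * k**h2 + np.abs(k - 1) ** h2)
    row = np.concatenate([gamma, gamma[-2:0:-1]])  # circulant first row, length 2m
    lam = np.fft.fft(row).real
    lam = np.maximum(lam, 0.0)  # clip tiny negative round-off
    two_m = 2 * m
    # Hermitian random spectrum with the prescribed eigenvalues
    w = np.zeros(two_m, dtype=complex)
    w[0] = np.sqrt(lam[0]) * rng.standard_normal()
    w[m] = np.sqrt(lam[m]) * rng.standard_normal()
    a = rng.standard_normal(m - 1)
    b = rng.standard_normal(m - 1)
    w[1:m] = np.sqrt(lam[1:m] / 2.0) * (a + 1j * b)
    w[m + 1 :] = np.conj(w[1:m][::-1])
    x = np.fft.fft(w) / np.sqrt(two_m)
    return np.ascontiguousarray(x.real[:n])


@dataclass
class RampSpec:
    """Parameters of a synthetic incremental exercise test.

    The programmed alpha1 profile is ``alpha_hi`` for heart rates up to
    ``hr_decline_start``, then declines linearly in HR so that it
    crosses 0.5 exactly at ``hr_crossing`` (the ground-truth HRVT2),
    flooring at ``alpha_lo``.  ``noise_sd_ms`` sets the beat-to-beat
    fluctuation SD in ms (the exponent is amplitude-invariant, so this
    only needs to be physiologically plausible, not calibrated).
    """

    duration_s: float = 1200.0
    hr_start: float = 70.0
    hr_end: float = 190.0
    alpha_hi: float = 1.1
    alpha_lo: float = 0.3
    hr_decline_start: float = 140.0
    hr_crossing: float = 172.0
    noise_sd_ms: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.hr_start < self.hr_decline_start < self.hr_crossing < self.hr_end):
            raise ValueError(
                "need hr_start < hr_decline_start < hr_crossing < hr_end"
            )
        if not (self.alpha_hi > 0.5 > self.alpha_lo):
            raise ValueError("need alpha_hi > 0.5 > alpha_lo")
        if self.duration_s <= 0 or self.noise_sd_ms < 0:
            raise ValueError("duration_s must be > 0 and noise_sd_ms >= 0")

    def hr_at(self, t: float) -> float:
        """Programmed heart-rate trend (bpm) at time t (s)."""
        frac = np.clip(t / self.duration_s, 0.0, 1.0)
        return self.hr_start + (self.hr_end - self.hr_start) * frac

    def alpha_at_hr(self, hr) -> np.ndarray:
        """Programmed alpha1 as a function of heart rate."""
        hr = np.asarray(hr, dtype=float)
        slope = (0.5 - self.alpha_hi) / (self.hr_crossing - self.hr_decline_start)
        val = self.alpha_hi + slope * (hr - self.hr_decline_start)
        return np.clip(val, self.alpha_lo, self.alpha_hi)


@dataclass
class RampTruth:
    """Ground truth accompanying a generated ramp."""

    spec: RampSpec
    hr_crossing: float

    def alpha_of_hr(self, hr) -> np.ndarray:
        return self.spec.alpha_at_hr(hr)


_MA_LAGS = 300  # truncation of the fractional-integration MA expansion


def _fi_weights(d: float, lags: int = _MA_LAGS) -> np.ndarray:
    """MA weights of fractional integration of order d: psi_j = prod (m-1+d)/m."""
    j = np.arange(1, lags + 1, dtype=float)
    return np.concatenate([[1.0], np.cumprod((j - 1.0 + d) / j)])


def _expected_alpha1(d: float, scale_min: int = 4, scale_max: int = 16) -> float:
    """Exact expected short-term DFA slope of order-d fractional noise.

    For a Gaussian process with autocovariance ``C`` the expected
    squared per-box residual after line detrending of the integrated
    profile is ``tr(M C M')`` with ``M = (I - P) L`` (``L`` the cumsum
    operator, ``P`` the line projector), so the estimator's expectation
    at short scales can be computed analytically rather than assumed to
    be ``d + 0.5``.
    """
    psi = _fi_weights(d)
    gam = np.array([psi[: len(psi) - k] @ psi[k:] for k in range(scale_max)])
    gam = gam / gam[0]
    ns = np.arange(scale_min, scale_max + 1)
    fs = np.empty(len(ns), dtype=float)
    for i, n in enumerate(ns):
        t = np.arange(n, dtype=float)
        x = np.c_[np.ones(n), t]
        proj = np.eye(n) - x @ np.linalg.solve(x.T @ x, x.T)
        m = proj @ np.tril(np.ones((n, n)))
        c = gam[np.abs(np.subtract.outer(np.arange(n), np.arange(n)))]
        fs[i] = np.sqrt(np.trace(m @ c @ m.T) / (n - 1))
    return float(np.polyfit(np.log(ns), np.log(fs), 1)[0])


_D_GRID = np.linspace(-0.45, 0.85, 53)
_ALPHA_GRID: np.ndarray | None = None


def _d_for_alpha(alpha) -> np.ndarray:
    """Invert the exact d -> expected-alpha1 map (monotone, tabulated).

    Programming the integration order through this inverse makes the
    *expected measured* alpha1 profile of a ramp equal the programmed
    one — in particular exactly 0.5 (white noise, d = 0) at the
    programmed crossing — instead of inheriting the estimator's
    short-scale compression at high exponents.
    """
    global _ALPHA_GRID
    if _ALPHA_GRID is None:
        _ALPHA_GRID = np.array([_expected_alpha1(d) for d in _D_GRID])
    return np.interp(alpha, _ALPHA_GRID, _D_GRID)


def generate_ramp(spec: RampSpec) -> tuple[RRSeries, RampTruth]:
    """Generate a synthetic incremental exercise RR series.

    Beats are laid down sequentially: the mean interval tracks
    ``60000 / HR(t)`` and the fluctuation around it is fractionally
    integrated Gaussian noise of per-beat order
    ``d = alpha_at_hr(HR) - 0.5`` (variance-normalised, scaled to
    ``noise_sd_ms``).  ``d = 0`` — exactly white noise — occurs at the
    programmed crossing heart rate, which is returned as ground truth.
    """
    n_max = int(np.ceil(spec.duration_s * spec.hr_end / 60.0)) + 8
    rng = np.random.default_rng(spec.seed)
    eps = rng.standard_normal(n_max + _MA_LAGS)

    intervals = []
    t = 0.0
    k = 0
    while t < spec.duration_s and k < n_max:
        hr = spec.hr_at(t)
        base = 60000.0 / hr
        if spec.noise_sd_ms > 0:
            d = float(_d_for_alpha(spec.alpha_at_hr(hr)))
            psi = _fi_weights(d)
            # epsilon window ending at this beat, newest first
            window = eps[k + _MA_LAGS : k - 1 if k >= 1 else None : -1][: _MA_LAGS + 1]
            noise = float(psi @ window) / float(np.sqrt(psi @ psi))
            rr = base + spec.noise_sd_ms * noise
        else:
            rr = base
        rr = max(rr, 0.3 * base)  # physiological floor
        intervals.append(rr)
        t += rr / 1000.0
        k += 1
    series = RRSeries(
        np.asarray(intervals),
        meta=f"synthetic ramp seed={spec.seed} crossing={spec.hr_crossing}",
    )
    return series, RampTruth(spec=spec, hr_crossing=spec.hr_crossing)


def inject_artifacts(
    series: RRSeries,
    rate: float,
    mix: dict | None = None,
    seed: int = 0,
) -> tuple[RRSeries, np.ndarray]:
    """Contaminate an RR series with recording artifacts.

    Parameters
    ----------
    series : RRSeries
    rate : float
        Fraction of beats affected, in [0, 0.2]; beyond 20 % the series
        is considered unusable territory and refused.
    mix : dict, optional
        Proportions for ``ectopic`` (premature beat with compensatory
        pause: the two-beat pair is redistributed short+long, sum
        preserved), ``missed`` (two beats merged into one long
        interval) and ``extra`` (an interval split into a spurious
        short beat plus remainder, sum preserved).  Default
        ``{'missed': 0.7, 'extra': 0.2, 'ectopic': 0.1}`` — in
        ECG-grade exercise recordings detection dropouts dominate and
        rise with intensity, spurious detections come second, and
        frank ectopy is rare once ectopy-heavy subjects are screened
        out.
    seed : int

    Returns
    -------
    (RRSeries, ndarray)
        The contaminated series (flags untouched — detection is the
        job of preprocessing) and the onset times (s) of the affected
        sites in the contaminated series.
    """
    if not 0.0 <= rate <= 0.2:
        raise ValueError(f"artifact rate {rate} outside [0, 0.2]")
    if rate == 0:
        return series.copy(), np.array([])
    mix = dict(mix or {"missed": 0.7, "extra": 0.2, "ectopic": 0.1})
    kinds, weights = zip(*sorted(mix.items()))
    weights = np.asarray(weights, dtype=float)
    if np.any(weights < 0) or weights.sum() == 0:
        raise ValueError("mix proportions must be non-negative and not all zero")
    weights = weights / weights.sum()

    rng = np.random.default_rng(seed)
    n = len(series)
    n_sites = max(1, int(round(rate * n)))
    # sites spaced >= 3 beats apart so corrections cannot interact
    candidates = np.arange(2, n - 3)
    rng.shuffle(candidates)
    sites: list[int] = []
    for c in candidates:
        if all(abs(c - s) >= 3 for s in sites):
            sites.append(int(c))
        if len(sites) == n_sites:
            break
    sites.sort()
    site_kinds = rng.choice(len(kinds), size=len(sites), p=weights)

    rr = list(series.intervals)
    shift = 0  # running index shift caused by merges/splits
    affected_idx: list[int] = []
    for s, ki in zip(sites, site_kinds):
        i = s + shift
        kind = kinds[ki]
        if kind == "ectopic":
            f = rng.uniform(0.35, 0.45)
            pair = rr[i] + rr[i + 1]
            rr[i], rr[i + 1] = f * rr[i], pair - f * rr[i]
            affected_idx.append(i)
        elif kind == "missed":
            rr[i : i + 2] = [rr[i] + rr[i + 1]]
            affected_idx.append(i)
            shift -= 1
        else:  # extra
            f = rng.uniform(0.15, 0.30)
            rr[i : i + 1] = [f * rr[i], (1.0 - f) * rr[i]]
            affected_idx.append(i)
            shift += 1
    out = RRSeries(np.asarray(rr), meta=series.meta + " +artifacts")
    return out, out.times[np.asarray(affected_idx, int)]
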