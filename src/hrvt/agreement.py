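"""Method-comparison statistics for paired threshold heart rates.

Validation of an HRV-derived threshold against a reference (e.g. the
gas-exchange second ventilatory threshold) uses the standard
method-comparison toolkit: Pearson correlation and OLS regression of
the estimate on the reference with its standard error of estimate
(SEE), a paired t-test of the means, a Shapiro–Wilk normality check on
the differences, and Bland–Altman bias with 1.96-SD limits of
agreement.  Differences are defined as estimate minus reference
throughout, and SDs use the n-1 denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["AgreementReport", "agreement_stats"]


@dataclass
class AgreementReport:
    """Paired-comparison statistics between reference and estimated HRs.

    ``bias = mean(est - ref)``; ``loa_low``/``loa_high`` are
    ``bias -/+ 1.96 * sd_diff``.  When either column has zero variance
    the correlation/regression block (``r``, ``r2``, ``see``, regression
    coefficients) is NaN and ``degenerate_note`` explains why; the
    Bland–Altman block is always reported.
    """

    n: int
    mean_ref: float
    sd_ref: float
    mean_est: float
    sd_est: float
    r: float
    r2: float
    see: float
    slope: float
    intercept: float
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    t_stat: float
    p_value: float
    shapiro_p: float
    degenerate_note: Optional[str] = None

    def summary(self) -> str:
        lines = [
            "Paired threshold-HR agreement",
            "=" * 45,
            f"pairs (n)                 {self.n:>10d}",
            f"reference mean (SD) bpm   {self.mean_ref:>10.1f} ({self.sd_ref:.1f})",
            f"estimate  mean (SD) bpm   {self.mean_est:>10.1f} ({self.sd_est:.1f})",
            f"Pearson r                 {self.r:>10.3f}",
            f"R^2                       {self.r2:>10.3f}",
            f"SEE (bpm)                 {self.see:>10.2f}",
            f"regression est~ref        slope {self.slope:.3f}, "
            f"intercept {self.intercept:.1f}",
            f"bias est-ref (bpm)        {self.bias:>10.2f}",
            f"SD of differences (bpm)   {self.sd_diff:>10.2f}",
            f"limits of agreement (bpm) {self.loa_low:>10.2f} to {self.loa_high:.2f}",
            f"paired t (p)              {self.t_stat:>10.3f} ({self.p_value:.3f})",
            f"Shapiro-Wilk p (diff)     {self.shapiro_p:>10.3f}",
        ]
        if self.degenerate_note:
            lines.append(f"note: {self.degenerate_note}")
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        d = {k: v for k, v in self.__dict__.items() if k != "degenerate_note"}
        return pd.DataFrame({"statistic": list(d), "value": list(d.values())})


def agreement_stats(pairs) -> AgreementReport:
    """Compute the full agreement report for paired threshold HRs.

    Parameters
    ----------
    pairs : DataFrame with columns ``ref_hr`` and ``est_hr``, or a
        sequence of (ref_hr, est_hr) tuples.  At least 3 complete
        pairs.

    Returns
    -------
    AgreementReport

    Raises
    ------
    ValueError
        On fewer than 3 pairs or missing values.
    """
    if isinstance(pairs, pd.DataFrame):
        ref = pairs["ref_hr"].to_numpy(dtype=float)
        est = pairs["est_hr"].to_numpy(dtype=float)
    else:
        arr = np.asarray(list(pairs), dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("pairs must be (ref_hr, est_hr) tuples")
        ref, est = arr[:, 0], arr[:, 1]
    n = len(ref)
    if n < 3:
        raise ValueError(f"need at least 3 pairs, got {n}")
    if not (np.all(np.isfinite(ref)) and np.all(np.isfinite(est))):
        raise ValueError("missing or non-finite values in pairs")

    diff = est - ref
    bias = float(diff.mean())
    sd_diff = float(diff.std(ddof=1))
    with np.errstate(invalid="ignore"):
        shapiro_p = float(stats.shapiro(diff).pvalue) if np.ptp(diff) > 0 else np.nan
    if sd_diff > 0:
        t_stat = bias / (sd_diff / np.sqrt(n))
        p_value = float(2 * stats.t.sf(abs(t_stat), df=n - 1))
    else:
        t_stat, p_value = np.nan, np.nan

    degenerate = None
    if np.ptp(ref) == 0 or np.ptp(est) == 0:
        degenerate = (
            "zero variance in a column: correlation/regression undefined; "
            "Bland-Altman block still valid"
        )
        r = r2 = see = slope = intercept = np.nan
    else:
        r = float(stats.pearsonr(ref, est).statistic)
        r2 = r * r
        slope, intercept = (float(v) for v in np.polyfit(ref, est, 1))
        resid = est - (intercept + slope * ref)
        see = float(np.sqrt(np.sum(resid**2) / (n - 2)))

    return AgreementReport(
        n=n,
        mean_ref=float(ref.mean()),
        sd_ref=float(ref.std(ddof=1)),
        mean_est=float(est.mean()),
        sd_est=float(est.std(ddof=1)),
        r=r,
        r2=r2,
        see=see,
        slope=slope,
        intercept=intercept,
        bias=bias,
        sd_diff=sd_diff,
        loa_low=bias - 1.96 * sd_diff,
        loa_high=bias + 1.96 * sd_diff,
        t_stat=float(t_stat) if np.isfinite(t_stat) else np.nan,
        p_value=p_value,
        shapiro_p=shapiro_p,
        degenerate_note=degenerate,
    )
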