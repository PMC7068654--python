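"""Statistical layer: per-cell and pooled Spearman correlations between
baseline and peak/amplitude, one-population t-tests of R against zero,
coefficients of variation, and the F_P/F0 indicator-conversion formula.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class CorrelationResult:
    """Baseline-vs-peak and baseline-vs-amplitude rank correlations for one
    analysis unit (a cell, or a pooled recording session)."""

    unit_id: str
    r_baseline_peak: float
    r_baseline_amplitude: float
    n: int
    corrected: bool = False


@dataclass(frozen=True)
class PopulationTest:
    """Two-tailed one-population Student's t of per-unit Rs against zero."""

    rs: tuple[float, ...]
    mean: float
    sem: float
    t: float
    p: float
    n: int

    @property
    def df(self) -> int:
        return self.n - 1


class ConstantInputError(ValueError):
    """Raised when a rank correlation is requested on a constant vector."""


def spearman_r(x, y) -> float:
    """Spearman rank correlation (Pearson correlation of average ranks,
    ties receiving mean rank)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantInputError("rank correlation undefined for constant input")
    return float(sps.spearmanr(x, y).statistic)


def one_population_t(rs) -> PopulationTest:
    """t = mean / (sd / sqrt(n)) with n-1 df, two-sided p."""
    rs = np.asarray(rs, dtype=float)
    if rs.size < 2:
        raise ValueError("need at least 2 values")
    if np.ptp(rs) == 0:
        raise ValueError("zero variance: t undefined")
    res = sps.ttest_1samp(rs, 0.0)
    return PopulationTest(
        rs=tuple(float(r) for r in rs),
        mean=float(np.mean(rs)),
        sem=float(sps.sem(rs)),
        t=float(res.statistic),
        p=float(res.pvalue),
        n=int(rs.size),
    )


def per_cell_correlations(
    events: pd.DataFrame,
    unit_id: str = "cell",
    baseline_col: str = "baseline",
    peak_col: str = "peak",
    amplitude_col: str = "amplitude",
    corrected: bool = False,
) -> CorrelationResult:
    """Rank correlations over one cell's events (or ROIs).

    A constant peak or amplitude column makes that R NaN (the cell is then
    excluded from population tests); a constant baseline raises, since both
    Rs are undefined.
    """
    if len(events) < 3:
        raise ValueError("need at least 3 events for a correlation")
    b = events[baseline_col].to_numpy(dtype=float)
    try:
        r_peak = spearman_r(b, events[peak_col].to_numpy(dtype=float))
    except ConstantInputError:
        if np.ptp(b) == 0:
            raise
        r_peak = float("nan")
    try:
        r_amp = spearman_r(b, events[amplitude_col].to_numpy(dtype=float))
    except ConstantInputError:
        if np.ptp(b) == 0:
            raise
        r_amp = float("nan")
    return CorrelationResult(unit_id, r_peak, r_amp, len(events), corrected)


def pooled_correlations(
    events: pd.DataFrame, session_id: str = "session", **kwargs
) -> CorrelationResult:
    """Single R pair over events pooled across all cells of one session —
    used where per-cell event counts are too low for per-cell Rs."""
    return per_cell_correlations(events, unit_id=session_id, **kwargs)


def population_summary(results: list[CorrelationResult]) -> dict:
    """Population t-tests over per-unit Rs (NaN units dropped, with count)."""
    out: dict = {"n_units": len(results)}
    for key, attr in (("peak", "r_baseline_peak"), ("amplitude", "r_baseline_amplitude")):
        rs = np.array([getattr(r, attr) for r in results], dtype=float)
        ok = np.isfinite(rs)
        out[f"n_dropped_{key}"] = int((~ok).sum())
        test = one_population_t(rs[ok])
        out[key] = test
    return out


def coefficient_of_variation(values) -> float:
    """Sample SD / mean (ddof=1); requires a positive mean."""
    values = np.asarray(values, dtype=float)
    m = values.mean()
    if m <= 0:
        raise ValueError("CV requires a positive mean")
    if values.size < 2:
        return 0.0
    return float(values.std(ddof=1) / m)


def fp_over_f0(ca0_nm: float, cap_nm: float, kd_nm: float) -> float:
    """Peak-over-baseline fluorescence F_P/F0 implied by the law of mass
    action for an indicator with negligible Ca-free fluorescence:

        F_P/F0 = Ca_P (K_D + Ca_0) / ((K_D + Ca_P) Ca_0)
    """
    if ca0_nm <= 0 or cap_nm <= 0 or kd_nm <= 0:
        raise ValueError("all arguments must be > 0")
    return float(cap_nm * (kd_nm + ca0_nm) / ((kd_nm + cap_nm) * ca0_nm))
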