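"""Volatility-regime detection: rolling volatility, multiple structural breaks
in its mean, and regime-wise residual covariances.

The identification stage needs two periods with different structural shock
variances.  Variance shifts in the tweet series show up as level shifts in its
rolling standard deviation ("historical volatility"), so breaks are located by
least-squares mean-shift segmentation of the volatility series: for each
candidate break count ``m`` the segmentation minimizing the total
within-segment sum of squares is found exactly by dynamic programming under a
minimum-segment-length (trimming) constraint, and ``m`` is chosen by BIC.
Residuals are then split at the break date into a high-volatility regime 1
(post-break) and a low-volatility regime 2 (pre-break), following the
convention that regime 1 is the turbulent period even though it comes later.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DataError
from .data_io import TransformedSeries
from .var_model import ReducedVARFit

__all__ = [
    "VolatilitySeries",
    "BreakModel",
    "RegimePartition",
    "rolling_volatility",
    "detect_breaks",
    "assign_regimes",
    "volatility_break_to_panel_date",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class VolatilitySeries:
    """Rolling standard deviations, dated at the end of each window."""

    dates: pd.DatetimeIndex
    values: np.ndarray
    window: int

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class BreakModel:
    """Chosen segmentation of the volatility series plus the BIC table."""

    break_indices: tuple[int, ...]     # position of the first obs of each new segment
    break_dates: tuple[pd.Timestamp, ...]
    bic_by_count: dict[int, float]
    confidence_bands: tuple[tuple[pd.Timestamp, pd.Timestamp], ...]
    trim: float
    n_breaks: int
    breaks_by_count: dict[int, tuple[int, ...]] | None = None

    def single_break_index(self) -> int:
        """The optimal one-break split (identification consumes two regimes)."""
        if self.n_breaks == 1:
            return self.break_indices[0]
        if self.breaks_by_count and 1 in self.breaks_by_count:
            return self.breaks_by_count[1][0]
        raise DataError("no admissible single-break segmentation available")


@dataclass(frozen=True)
class RegimePartition:
    """Residual rows split into the two volatility regimes."""

    regime_of_date: pd.Series          # date -> 1 (high, post-break) or 2 (low)
    covariances: dict[int, np.ndarray]  # regime -> 3x3, divide-by-n convention
    counts: dict[int, int]
    break_date: pd.Timestamp


def rolling_volatility(series: TransformedSeries, window: int = 20) -> VolatilitySeries:
    """Rolling sample standard deviation (n-1 denominator, trailing window)."""
    if window < 2:
        raise ConfigError("window must be >= 2")
    x = np.asarray(series.values, dtype=float)
    if len(x) < window:
        raise DataError(f"series length {len(x)} shorter than window {window}")
    vol = pd.Series(x).rolling(window).std(ddof=1).to_numpy()[window - 1:]
    return VolatilitySeries(dates=series.dates[window - 1:], values=vol, window=window)


def _segment_cost_matrix(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Prefix sums so SSE of x[i:j] is O(1): returns (S1, S2) cumulative."""
    s1 = np.concatenate([[0.0], np.cumsum(x)])
    s2 = np.concatenate([[0.0], np.cumsum(x * x)])
    return s1, s2


def _sse(s1: np.ndarray, s2: np.ndarray, i: np.ndarray | int, j: np.ndarray | int):
    n = np.asarray(j) - np.asarray(i)
    tot = s2[j] - s2[i]
    mean_part = (s1[j] - s1[i]) ** 2 / n
    return tot - mean_part


def _dp_segment(x: np.ndarray, max_breaks: int, h: int):
    """Exact DP over all segmentations with segments of length >= h.

    Returns ``(ssr_by_count, breaks_by_count)`` where ``breaks_by_count[m]``
    lists, for the optimal m-break fit, the index of the first observation of
    each post-break segment.
    """
    n = len(x)
    s1, s2 = _segment_cost_matrix(x)
    # dp[m, j]: min SSE of x[:j] split into m+1 segments; j is an end index
    dp = np.full((max_breaks + 1, n + 1), np.inf)
    arg = np.zeros((max_breaks + 1, n + 1), dtype=int)
    ends = np.arange(h, n + 1)
    dp[0, ends] = _sse(s1, s2, 0, ends)
    for m in range(1, max_breaks + 1):
        for j in range((m + 1) * h, n + 1):
            t = np.arange(m * h, j - h + 1)    # last break position candidates
            cand = dp[m - 1, t] + _sse(s1, s2, t, j)
            k = int(np.argmin(cand))
            dp[m, j] = cand[k]
            arg[m, j] = t[k]
    ssr, brks = {}, {}
    for m in range(max_breaks + 1):
        if not np.isfinite(dp[m, n]):
            continue
        ssr[m] = float(dp[m, n])
        b, j = [], n
        for mm in range(m, 0, -1):
            j = int(arg[mm, j])
            b.append(j)
        brks[m] = tuple(sorted(b))
    return ssr, brks


def detect_breaks(vol: VolatilitySeries, max_breaks: int = 5, trim: float = 0.15) -> BreakModel:
    """Locate mean shifts in the volatility series, BIC-selecting the count.

    For each ``m <= max_breaks`` the globally optimal m-break least-squares
    segmentation (segments >= trim * n observations) is found by dynamic
    programming; the chosen ``m`` minimizes
    ``BIC = n ln(SSR/n) + (2m+1) ln(n)``.  The per-break confidence band is
    the profile region where moving that break (others fixed) raises the SSR
    by less than the 95% chi-square(1) increment times the residual variance
    -- an approximation, reported as such.
    """
    if not 0 < trim < 0.5:
        raise ConfigError("trim must be in (0, 0.5)")
    x = np.asarray(vol.values, dtype=float)
    n = len(x)
    h = max(int(np.ceil(trim * n)), 2)
    if n < 2 * h:
        raise DataError(f"series of length {n} cannot hold two segments of {h}")
    ssr_by_m, breaks_by_m = _dp_segment(x, max_breaks, h)
    bic = {
        m: n * np.log(max(ssr_by_m[m], 1e-300) / n) + (2 * m + 1) * np.log(n)
        for m in ssr_by_m
    }
    best_m = min(bic, key=lambda m: bic[m])
    breaks = breaks_by_m[best_m]
    # profile-SSR confidence band per break, holding the others fixed
    s1, s2 = _segment_cost_matrix(x)
    sigma2 = max(ssr_by_m[best_m] / n, 1e-300)
    crit = float(stats.chi2.ppf(0.95, 1)) * sigma2
    bands = []
    bounds = (0,) + breaks + (n,)
    for i, b in enumerate(breaks):
        lo_edge, hi_edge = bounds[i], bounds[i + 2]
        cand = np.arange(lo_edge + h, hi_edge - h + 1)
        prof = _sse(s1, s2, lo_edge, cand) + _sse(s1, s2, cand, hi_edge)
        inside = cand[prof - prof.min() <= crit]
        bands.append((vol.dates[inside.min()], vol.dates[inside.max()]))
    if best_m > 1:
        logger.warning(
            "BIC selected %d breaks; downstream identification consumes a "
            "single two-regime split", best_m
        )
    return BreakModel(
        break_indices=breaks,
        break_dates=tuple(vol.dates[b] for b in breaks),
        bic_by_count={m: float(v) for m, v in bic.items()},
        confidence_bands=tuple(bands),
        trim=trim,
        n_breaks=best_m,
        breaks_by_count={m: v for m, v in breaks_by_m.items()},
    )


def volatility_break_to_panel_date(break_date: pd.Timestamp, window: int) -> pd.Timestamp:
    """Map a break dated at a trailing-window end to the underlying regime date.

    A variance step at day b bleeds into trailing-window volatilities over the
    following ``window`` days, so the fitted mean shift centres near
    ``b + window/2``; subtracting ``window // 2`` undoes that smearing.
    """
    return break_date - pd.Timedelta(days=window // 2)


def assign_regimes(fit: ReducedVARFit, break_date) -> RegimePartition:
    """Split VAR residuals at ``break_date`` and compute per-regime covariances.

    Rows on or before the break date form regime 2 (low volatility); rows
    after it form regime 1 (high volatility).  Covariances use within-regime
    demeaning and the divide-by-n convention, matching the moment system.
    """
    break_date = pd.Timestamp(break_date)
    dates = fit.residual_dates
    post = dates > break_date
    n1, n2 = int(post.sum()), int((~post).sum())
    if min(n1, n2) < 10:
        raise DataError(
            f"degenerate regime split at {break_date.date()}: {n2} / {n1} rows"
        )
    cov = {}
    for regime, mask in ((1, post), (2, ~post)):
        e = fit.residuals[mask]
        e = e - e.mean(axis=0)
        cov[regime] = e.T @ e / e.shape[0]
    labels = pd.Series(np.where(post, 1, 2), index=dates)
    return RegimePartition(
        regime_of_date=labels,
        covariances=cov,
        counts={1: n1, 2: n2},
        break_date=break_date,
    )
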