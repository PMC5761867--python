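"""Unit-root screening: ADF with drift (BIC lag selection) and KPSS.

Every series entering the VAR must be stationary.  Two complementary tests
are run per series: the augmented Dickey-Fuller test (null: unit root) and
the KPSS level-stationarity test (null: stationary).  A series is scheduled
for differencing only when both tests agree it is integrated -- ADF fails to
reject its unit-root null and KPSS rejects its stationarity null.

Conventions fixed here:

* ADF: drift (intercept, no trend) specification; augmentation lag chosen by
  BIC over ``0..max_lag`` on a common estimation sample; 95% critical value
  fixed at the asymptotic -2.86.
* KPSS: Bartlett-kernel long-run variance with the Schwert truncation lag
  ``floor(4 * (n/100)**0.25)``; 95% critical value 0.463.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from statsmodels.tsa.stattools import adfuller, kpss as _sm_kpss

from .errors import DataError

__all__ = [
    "UnitRootResult",
    "ScreenVerdict",
    "adf_drift",
    "kpss",
    "schwert_lag",
    "screen",
    "ADF_CRIT_95",
    "KPSS_CRIT_95",
]

logger = logging.getLogger(__name__)

ADF_CRIT_95 = -2.86   # asymptotic 5% point, drift case
KPSS_CRIT_95 = 0.463  # asymptotic 5% point, level stationarity


@dataclass(frozen=True)
class UnitRootResult:
    test_name: str          # "ADF-drift" or "KPSS"
    statistic: float
    critical95: float
    lags_used: int
    stationary: bool


@dataclass(frozen=True)
class ScreenVerdict:
    """Per-series screening outcome and the resulting differencing plan."""

    adf: UnitRootResult
    kpss: UnitRootResult
    difference: bool
    conflict: bool


def _values(series) -> np.ndarray:
    x = np.asarray(series.values if hasattr(series, "values") else series, dtype=float)
    if x.ndim != 1:
        raise DataError("series must be one-dimensional")
    return x


def adf_drift(series, max_lag: int = 14) -> UnitRootResult:
    """ADF test with drift; augmentation lags picked by BIC over ``0..max_lag``.

    The reported statistic is the t-ratio on the lagged level; stationarity is
    declared when it falls below the asymptotic 95% critical value -2.86.
    """
    x = _values(series)
    if len(x) <= max_lag + 10:
        raise DataError(f"series too short ({len(x)}) for max_lag={max_lag}")
    if np.ptp(x) == 0:
        raise DataError("constant series: ADF regression is degenerate")
    stat, _pval, usedlag, _nobs, _crit, _icbest = adfuller(
        x, maxlag=max_lag, regression="c", autolag="BIC"
    )
    return UnitRootResult(
        test_name="ADF-drift",
        statistic=float(stat),
        critical95=ADF_CRIT_95,
        lags_used=int(usedlag),
        stationary=bool(stat < ADF_CRIT_95),
    )


def schwert_lag(n: int) -> int:
    """Schwert truncation rule ``floor(4 * (n/100)**(1/4))``; 6 at n=639."""
    return int(np.floor(4.0 * (n / 100.0) ** 0.25))


def kpss(series) -> UnitRootResult:
    """KPSS level-stationarity test with the Schwert truncation lag."""
    x = _values(series)
    if len(x) < 25:
        raise DataError(f"series too short ({len(x)}) for KPSS")
    nlags = schwert_lag(len(x))
    with warnings.catch_warnings():
        # statsmodels warns when the statistic is outside its p-value table;
        # we compare against the fixed critical value ourselves.
        warnings.simplefilter("ignore")
        stat, _pval, _lags, _crit = _sm_kpss(x, regression="c", nlags=nlags)
    return UnitRootResult(
        test_name="KPSS",
        statistic=float(stat),
        critical95=KPSS_CRIT_95,
        lags_used=nlags,
        stationary=bool(stat < KPSS_CRIT_95),
    )


def screen(series_map: dict[str, object], max_lag: int = 14) -> dict[str, ScreenVerdict]:
    """Run both tests per series and propose a differencing plan.

    A series is flagged for differencing iff ADF fails to reject the unit root
    AND KPSS rejects stationarity.  The conflicting pattern (ADF rejects, KPSS
    also rejects) is logged and flagged for review without differencing.
    """
    out = {}
    for name, series in series_map.items():
        a = adf_drift(series, max_lag=max_lag)
        k = kpss(series)
        diff = (not a.stationary) and (not k.stationary)
        conflict = a.stationary and not k.stationary
        if conflict:
            logger.warning(
                "%s: ADF rejects the unit root but KPSS rejects stationarity; "
                "not differencing, flagged for review", name
            )
        out[name] = ScreenVerdict(adf=a, kpss=k, difference=diff, conflict=conflict)
    return out
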