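"""Daily count panels, the inverse hyperbolic sine transform, and panel assembly.

The pipeline works with three jointly modelled daily series -- officers shot to
death (``law``), citizens shot by police (``ctz``: either minorities or white
non-Hispanics), and BLM-related tweet volume (``twt``).  Counts are
variance-stabilized with the inverse hyperbolic sine (IHS)

    g = ln(theta * y + sqrt(1 + theta**2 * y**2)),   theta > 0,

which behaves like ``log`` for large ``y`` but is defined at zero, so the
zero-heavy homicide counts need no offset.  With ``theta = 1`` this is
``asinh``.  Coefficients of linear models fit on the transformed scale read as
elasticities (percent responses to percent shocks).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError

__all__ = [
    "DailyCountSeries",
    "TransformedSeries",
    "SystemPanel",
    "SummaryStats",
    "read_panel",
    "ihs_transform",
    "ihs_inverse",
    "difference",
    "assemble_panel",
    "summarize",
    "summary_table",
]

logger = logging.getLogger(__name__)

#: canonical column roles of the input CSV
PANEL_COLUMNS = ("law", "minorities", "whites", "twitter")


@dataclass(frozen=True)
class DailyCountSeries:
    """A gap-free daily series of nonnegative integer counts."""

    name: str
    dates: pd.DatetimeIndex
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.ndim != 1 or len(values) != len(self.dates):
            raise DataError(f"{self.name}: dates and values must align 1-d")
        if len(values) < 2:
            raise DataError(f"{self.name}: need at least 2 observations")
        if not np.issubdtype(values.dtype, np.integer):
            if not np.all(values == np.floor(values)):
                raise DataError(f"{self.name}: counts must be integers")
            values = values.astype(np.int64)
        if np.any(values < 0):
            bad = self.dates[np.argmax(values < 0)]
            raise DataError(f"{self.name}: negative count at {bad.date()}")
        if self.dates.has_duplicates:
            dup = self.dates[self.dates.duplicated()][0]
            raise DataError(f"{self.name}: duplicate date {dup.date()}")
        full = pd.date_range(self.dates[0], self.dates[-1], freq="D")
        if len(full) != len(self.dates) or not (full == self.dates).all():
            missing = full.difference(self.dates)
            raise DataError(
                f"{self.name}: calendar gap, missing "
                f"{[str(d.date()) for d in missing[:5]]}"
                + ("..." if len(missing) > 5 else "")
            )
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class TransformedSeries:
    """A real-valued daily series on the IHS scale (optionally differenced)."""

    name: str
    dates: pd.DatetimeIndex
    values: np.ndarray
    theta: float = 1.0
    differenced: bool = False

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or len(values) != len(self.dates):
            raise DataError(f"{self.name}: dates and values must align 1-d")
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class SystemPanel:
    """Aligned T x 3 system of transformed series, column order (law, ctz, twt).

    ``variables`` records the concrete role of each column; column 1 is one of
    ``minorities`` / ``whites`` (model 1 vs model 2), and column 2 is the
    first-differenced tweet series.
    """

    variables: tuple[str, str, str]
    matrix: np.ndarray
    dates: pd.DatetimeIndex
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        matrix = np.asarray(self.matrix, dtype=float)
        if matrix.ndim != 2 or matrix.shape[1] != 3:
            raise DataError("panel matrix must be T x 3")
        if matrix.shape[0] != len(self.dates):
            raise DataError("panel matrix and dates must align")
        if not np.all(np.isfinite(matrix)):
            raise DataError("panel contains missing or non-finite cells")
        object.__setattr__(self, "matrix", matrix)

    @property
    def nobs(self) -> int:
        return self.matrix.shape[0]

    def column(self, i: int) -> np.ndarray:
        return self.matrix[:, i]


@dataclass(frozen=True)
class SummaryStats:
    """Seven-number summary (quartiles by linear interpolation, sd with n-1)."""

    min: float
    first_quartile: float
    median: float
    mean: float
    third_quartile: float
    max: float
    sd: float


def read_panel(path, columns: dict[str, str] | None = None) -> dict[str, DailyCountSeries]:
    """Read a daily CSV panel into one :class:`DailyCountSeries` per variable.

    Parameters
    ----------
    path : str or file-like
        CSV with a ``date`` column (ISO-8601) and one integer column per
        variable.
    columns : dict, optional
        Maps the canonical roles (``law``, ``minorities``, ``whites``,
        ``twitter``) to the column names actually present; defaults to the
        identity map.
    """
    colmap = {c: c for c in PANEL_COLUMNS}
    if columns:
        colmap.update(columns)
    frame = pd.read_csv(path)
    if "date" not in frame.columns:
        raise ConfigError("input CSV must have a 'date' column")
    missing = [src for src in colmap.values() if src not in frame.columns]
    if missing:
        raise ConfigError(f"input CSV missing columns: {missing}")
    try:
        dates = pd.DatetimeIndex(pd.to_datetime(frame["date"], format="ISO8601"))
    except (ValueError, TypeError) as exc:
        raise DataError(f"unparseable date column: {exc}") from exc
    out = {}
    for role, src in colmap.items():
        raw = pd.to_numeric(frame[src], errors="coerce")
        if raw.isna().any():
            raise DataError(f"{src}: non-numeric or missing value")
        out[role] = DailyCountSeries(name=role, dates=dates, values=raw.to_numpy())
    return out


def ihs_transform(series: DailyCountSeries, theta: float = 1.0) -> TransformedSeries:
    """Apply the IHS transform ``g = ln(theta*y + sqrt(1 + theta^2 y^2))``.

    Strictly increasing and odd in ``y``; with ``theta=1`` it equals
    ``asinh(y)``, so ``y=0 -> 0``, ``y=1 -> 0.8814``, ``y=6 -> 2.4918``.
    """
    if theta <= 0:
        raise ConfigError(f"theta must be positive, got {theta}")
    y = np.asarray(series.values, dtype=float)
    g = np.arcsinh(theta * y) if theta == 1.0 else np.log(theta * y + np.hypot(1.0, theta * y))
    return TransformedSeries(
        name=series.name, dates=series.dates, values=g, theta=theta, differenced=False
    )


def ihs_inverse(values: np.ndarray, theta: float = 1.0) -> np.ndarray:
    """Analytic inverse of :func:`ihs_transform`: ``y = sinh(g) / theta``.

    For ``theta=1`` this is plain ``sinh``; exact to floating precision.
    """
    return np.sinh(np.asarray(values, dtype=float)) / theta


def difference(series: TransformedSeries) -> TransformedSeries:
    """First difference; the tweet series enters the system in differences."""
    if series.differenced:
        raise DataError(f"{series.name}: already differenced once")
    if len(series) < 2:
        raise DataError(f"{series.name}: need length >= 2 to difference")
    return TransformedSeries(
        name=series.name,
        dates=series.dates[1:],
        values=np.diff(series.values),
        theta=series.theta,
        differenced=True,
    )


def assemble_panel(
    law: TransformedSeries, ctz: TransformedSeries, twt: TransformedSeries
) -> SystemPanel:
    """Align the three model series on their common dates.

    ``law`` and ``ctz`` are undifferenced IHS levels; ``twt`` must already be
    differenced (so its first calendar day is gone, and the level series' first
    day drops out of the intersection).
    """
    if law.differenced or ctz.differenced:
        raise DataError("law and ctz must be undifferenced levels")
    if not twt.differenced:
        raise DataError("twt must be first-differenced")
    common = law.dates.intersection(ctz.dates).intersection(twt.dates)
    if len(common) == 0:
        raise DataError("series share no common dates")
    cols = []
    for s in (law, ctz, twt):
        idx = s.dates.get_indexer(common)
        cols.append(s.values[idx])
    meta = {
        "theta": {s.name: s.theta for s in (law, ctz, twt)},
        "differenced": {s.name: s.differenced for s in (law, ctz, twt)},
    }
    return SystemPanel(
        variables=(law.name, ctz.name, twt.name),
        matrix=np.column_stack(cols),
        dates=common,
        meta=meta,
    )


def summarize(series) -> SummaryStats:
    """Seven-number summary of a count or transformed series.

    Quartiles use linear interpolation between order statistics; sd uses the
    n-1 denominator.  A singleton's sd is reported as 0 with a warning so that
    summaries stay total.
    """
    x = np.asarray(series.values if hasattr(series, "values") else series, dtype=float)
    if x.size == 0:
        raise DataError("cannot summarize an empty series")
    if x.size == 1:
        warnings.warn("sd of a single observation is undefined; reporting 0")
        sd = 0.0
    else:
        sd = float(np.std(x, ddof=1))
    q1, med, q3 = np.quantile(x, [0.25, 0.5, 0.75], method="linear")
    return SummaryStats(
        min=float(x.min()),
        first_quartile=float(q1),
        median=float(med),
        mean=float(x.mean()),
        third_quartile=float(q3),
        max=float(x.max()),
        sd=sd,
    )


def summary_table(series_map: dict[str, object]) -> pd.DataFrame:
    """Summary statistics for several series as one table (rows: min..sd)."""
    rows = ["min", "1Q", "median", "mean", "3Q", "max", "sd"]
    data = {}
    for name, series in series_map.items():
        s = summarize(series)
        data[name] = [s.min, s.first_quartile, s.median, s.mean, s.third_quartile, s.max, s.sd]
    return pd.DataFrame(data, index=rows)
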