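"""Structural impulse responses, bootstrap bands, and practical conversions.

The moving-average matrices Psi_h of the reduced form come from powers of the
companion matrix; structural responses are Phi_h = Psi_h B with B the
contemporaneous-effects matrix, so Phi_0 = B entrywise.  Because all series
enter the system IHS-transformed (log-like), responses read as elasticities:
the (j, k) entry is the percent response of variable j, h days after a 1%
structural shock to variable k.  The tweet variable enters the system in
first differences, so its row is reported cumulatively to make it comparable
with the level variables.  "Practical terms" conversions multiply an
elasticity by the raw-count baseline mean to express a 100% shock as a
change in daily counts.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .bootstrap import BootstrapResult
from .errors import ConfigError, EstimationError
from .identification import StructuralSolution
from .var_model import ReducedVARFit, companion_matrix

__all__ = ["IRFResult", "PracticalEffect", "structural_irf", "attach_bands", "practical_effect"]

#: row index of the differenced (cumulatively reported) tweet variable
TWT_ROW = 2


@dataclass(frozen=True)
class IRFResult:
    """Structural responses over a daily horizon with optional bands.

    ``responses[h, j, k]`` is the response of variable j at day h to a unit
    (1%) structural shock in variable k, with the tweet row cumulated;
    ``responses_raw`` keeps the per-day (non-cumulated) values.
    """

    horizon: int
    responses: np.ndarray              # (H+1, 3, 3), twt row cumulated
    responses_raw: np.ndarray          # (H+1, 3, 3)
    cumulative_flags: tuple[bool, bool, bool]
    band1: np.ndarray | None = None    # (H+1, 3, 3) half-widths, 1 sd
    band2: np.ndarray | None = None    # 2 sd
    significant: np.ndarray | None = None  # point +/- 2 sd excludes zero


@dataclass(frozen=True)
class PracticalEffect:
    """An elasticity restated as a daily count change for a 100% shock."""

    elasticity: float
    baseline_mean: float
    delta_count: float


def _structural_responses(lag_coeffs: np.ndarray, B: np.ndarray, horizon: int) -> np.ndarray:
    """Raw Phi_h = Psi_h B for h = 0..horizon via companion powers."""
    C = companion_matrix(lag_coeffs)
    m = C.shape[0]
    out = np.empty((horizon + 1, 3, 3))
    power = np.eye(m)
    for h in range(horizon + 1):
        out[h] = power[:3, :3] @ B
        power = power @ C
    return out


def _cumulate(raw: np.ndarray, flags: tuple[bool, bool, bool]) -> np.ndarray:
    resp = raw.copy()
    for j, flag in enumerate(flags):
        if flag:
            resp[:, j, :] = np.cumsum(raw[:, j, :], axis=0)
    return resp


def structural_irf(
    fit: ReducedVARFit, solution: StructuralSolution, horizon: int = 7
) -> IRFResult:
    """Structural IRFs to unit (1%) shocks over ``0..horizon`` days.

    Requires a stable fit (companion spectral radius < 1); the day-0 response
    matrix equals the contemporaneous matrix B exactly.
    """
    if horizon < 0:
        raise ConfigError("horizon must be >= 0")
    radius = float(np.max(np.abs(np.linalg.eigvals(fit.companion))))
    if radius >= 1.0:
        raise EstimationError(f"unstable VAR (companion radius {radius:.3f})")
    raw = _structural_responses(fit.lag_coeffs, solution.b_matrix, horizon)
    flags = (False, False, True)
    return IRFResult(
        horizon=horizon,
        responses=_cumulate(raw, flags),
        responses_raw=raw,
        cumulative_flags=flags,
    )


def attach_bands(irf: IRFResult, boot: BootstrapResult) -> IRFResult:
    """Add 1- and 2-sd bootstrap bands around the point IRF.

    Half-widths are the pointwise standard deviations of the replicate IRFs
    (cumulated the same way as the point estimate); the solid line stays the
    original-data estimate.  A response is flagged significant where the
    2-sd interval excludes zero -- the conventional reading of the 2-sd band
    as an approximate 95% interval.
    """
    if boot.replicate_irfs is None:
        raise ConfigError("bootstrap result carries no replicate IRFs")
    if boot.replicate_irfs.shape[1] != irf.horizon + 1:
        raise ConfigError("bootstrap IRF horizon does not match")
    repl = np.stack([_cumulate(r, irf.cumulative_flags) for r in boot.replicate_irfs])
    sd = repl.std(axis=0, ddof=1)
    significant = np.abs(irf.responses) - 2.0 * sd > 0
    return replace(irf, band1=sd, band2=2.0 * sd, significant=significant)


def practical_effect(elasticity: float, baseline_mean: float) -> PracticalEffect:
    """Convert an elasticity to daily counts for a doubling (100% shock).

    ``delta_count = elasticity * baseline_mean`` with the raw-count sample
    mean as the baseline; rounding is left to the presentation layer.
    """
    if baseline_mean < 0:
        raise ConfigError("baseline mean must be nonnegative")
    return PracticalEffect(
        elasticity=float(elasticity),
        baseline_mean=float(baseline_mean),
        delta_count=float(elasticity) * float(baseline_mean),
    )
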