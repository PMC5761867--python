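"""Fixed-design wild bootstrap of the VAR-plus-identification chain.

Standard errors and p-values for the contemporaneous coefficients and shock
variances come from a fixed-design wild bootstrap: each replicate multiplies
every residual *row* by a single random weight shared across the three
equations, preserving the contemporaneous correlation structure in
expectation while conditional heteroskedasticity survives because weights
have unit variance.  The regressor matrix is held fixed, coefficients are
refit on it, regime covariances are recomputed with the original break date,
and the moment system is re-solved (warm-started at the original solution).
The break date is *not* re-detected per replicate: inference is conditional
on the estimated regimes, mirroring the stagewise estimation procedure.

The default weight law is Mammen's two-point distribution.  The choice
matters here more than in a mean-regression bootstrap: the identified
parameters are functions of second moments only, and sign-flip (Rademacher)
weights leave every product ``w_t^2 e_t e_t'`` unchanged, so they propagate
no sampling variation into the moment system and collapse the bootstrap
distribution.  Mammen (and Gaussian) weights have non-degenerate ``w^2``
with ``E[w^2] = 1``, giving the regime covariances -- and everything
downstream of them -- genuine replicate variation.  Rademacher and Gaussian
laws remain available for comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, EstimationError, IdentificationError
from .identification import StructuralSolution, solve_identification
from .regimes import RegimePartition
from .var_model import ReducedVARFit

__all__ = ["BootstrapResult", "wild_bootstrap", "coefficient_pvalues"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BootstrapResult:
    """Replicate draws of the structural parameters (failures excluded)."""

    n_replicates: int                  # successful replicates
    replicate_deltas: np.ndarray       # (B_ok, 6)
    replicate_variances: np.ndarray    # (B_ok, 6): regime-1 then regime-2
    replicate_irfs: np.ndarray | None  # (B_ok, H+1, 3, 3) raw (non-cumulated)
    failures: int
    seed: int


def _draw_weights(rng: np.random.Generator, n: int, law: str) -> np.ndarray:
    if law == "rademacher":
        return rng.integers(0, 2, size=n) * 2.0 - 1.0
    if law == "mammen":
        # two-point law with E w = 0, E w^2 = 1, E w^3 = 1
        phi = (1.0 + np.sqrt(5.0)) / 2.0
        p = phi / np.sqrt(5.0)                   # P(w = 1 - phi)
        lo, hi = 1.0 - phi, phi
        return np.where(rng.random(n) < p, lo, hi)
    if law == "gaussian":
        return rng.standard_normal(n)
    if law == "unit":
        return np.ones(n)
    raise ConfigError(f"unknown weight law '{law}'")


def wild_bootstrap(
    fit: ReducedVARFit,
    partition: RegimePartition,
    solution: StructuralSolution,
    B: int = 500,
    seed: int = 0,
    *,
    weights: str = "mammen",
    horizon: int | None = None,
    max_failure_share: float = 0.05,
) -> BootstrapResult:
    """Bootstrap the estimation chain conditional on the fitted design.

    Per replicate: draw one weight per time point, perturb the residual rows,
    rebuild the outcomes on the fixed regressor matrix, refit the VAR by
    least squares, recompute the two regime covariances at the original break
    date, and re-solve the identification system.  Replicates where the
    moment system has no admissible root are dropped and counted as failures.

    With ``horizon`` set, each replicate's structural impulse responses are
    also stored (raw, non-cumulated), for the IRF confidence bands.
    """
    from .irf import _structural_responses  # local import: avoid module cycle

    if B < 1:
        raise ConfigError("B must be >= 1")
    rng = np.random.default_rng(seed)
    X = fit.design
    pinv_X = np.linalg.pinv(X)
    post = np.asarray(fit.residual_dates > partition.break_date)
    n1, n2 = int(post.sum()), int((~post).sum())
    if min(n1, n2) < 10:
        raise EstimationError("regime partition too unbalanced to bootstrap")
    deltas, variances, irfs = [], [], []
    failures = 0
    for _ in range(B):
        w = _draw_weights(rng, fit.nobs, weights)
        e_star = fit.residuals * w[:, None]
        y_star = fit.fitted + e_star
        beta_star = pinv_X @ y_star
        resid_star = y_star - X @ beta_star
        cov = {}
        for regime, mask in ((1, post), (2, ~post)):
            e = resid_star[mask]
            e = e - e.mean(axis=0)
            cov[regime] = e.T @ e / e.shape[0]
        try:
            sol = solve_identification(cov[1], cov[2], start=solution, force=True)
        except IdentificationError:
            failures += 1
            continue
        deltas.append(sol.deltas)
        variances.append(sol.variance_vector())
        if horizon is not None:
            p = fit.lag_order
            lags = np.stack(
                [beta_star[1 + 3 * (k - 1): 1 + 3 * k].T for k in range(1, p + 1)]
            )
            irfs.append(_structural_responses(lags, sol.b_matrix, horizon))
    if failures > max_failure_share * B:
        logger.warning(
            "wild bootstrap: %d of %d replicates failed identification", failures, B
        )
    if not deltas:
        raise EstimationError("all bootstrap replicates failed identification")
    return BootstrapResult(
        n_replicates=len(deltas),
        replicate_deltas=np.asarray(deltas),
        replicate_variances=np.asarray(variances),
        replicate_irfs=np.asarray(irfs) if horizon is not None else None,
        failures=failures,
        seed=seed,
    )


def coefficient_pvalues(
    result: BootstrapResult, estimates: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Standard errors and two-sided p-values for the six coefficients.

    The standard error is the replicate standard deviation.  The p-value is
    the symmetric-percentile bootstrap p with the (count+1)/(B+1) correction:
    replicates are centred at the point estimate, and the p-value doubles the
    smaller tail share beyond ``|estimate|``.
    """
    if result.n_replicates < 100:
        raise ConfigError("need at least 100 replicates for p-values")
    est = np.asarray(estimates, dtype=float)
    repl = result.replicate_deltas
    b = repl.shape[0]
    se = repl.std(axis=0, ddof=1)
    centred = repl - est
    pvals = np.empty(est.shape)
    for q in range(est.size):
        hi = (np.sum(centred[:, q] >= abs(est[q])) + 1) / (b + 1)
        lo = (np.sum(centred[:, q] <= -abs(est[q])) + 1) / (b + 1)
        pvals[q] = min(1.0, 2.0 * min(hi, lo))
    return se, pvals
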