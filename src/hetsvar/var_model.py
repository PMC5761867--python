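"""Reduced-form VAR(p) estimation by equation-wise least squares.

The trivariate system

    Z_t = D_0 + D_1 Z_{t-1} + ... + D_p Z_{t-p} + e_t

is estimated equation by equation with OLS (identical to joint least squares
for an unrestricted VAR).  The lag order is chosen by AIC on a common
estimation sample; a reproduce mode can pin ``p`` directly.  The fit exposes
the residual matrix (consumed by the regime/identification stages) and the
companion matrix (consumed by the impulse-response stage).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import SystemPanel
from .errors import ConfigError, EstimationError

__all__ = ["ReducedVARFit", "select_lag", "fit_var", "companion_matrix", "companion_stability"]


@dataclass(frozen=True)
class ReducedVARFit:
    """Least-squares VAR(p) fit for a 3-variable system."""

    lag_order: int
    intercepts: np.ndarray        # (3,)
    lag_coeffs: np.ndarray        # (p, 3, 3), lag_coeffs[k-1] = D_k
    residuals: np.ndarray         # (T-p, 3)
    residual_dates: pd.DatetimeIndex
    fitted: np.ndarray            # (T-p, 3)
    design: np.ndarray            # (T-p, 1+3p) fixed regressor matrix
    aic: float
    variables: tuple[str, str, str]

    @property
    def nobs(self) -> int:
        return self.residuals.shape[0]

    @property
    def companion(self) -> np.ndarray:
        return companion_matrix(self.lag_coeffs)


def _lag_design(Z: np.ndarray, p: int, start: int | None = None):
    """Stack intercept and p lags; rows start at ``start`` (default p)."""
    T = Z.shape[0]
    s = p if start is None else start
    X = np.ones((T - s, 1 + 3 * p))
    for k in range(1, p + 1):
        X[:, 1 + 3 * (k - 1): 1 + 3 * k] = Z[s - k: T - k]
    return X, Z[s:]


def _sigma_ml(resid: np.ndarray) -> np.ndarray:
    n = resid.shape[0]
    return resid.T @ resid / n


def select_lag(panel: SystemPanel, p_max: int = 14) -> tuple[int, pd.DataFrame]:
    """Choose the VAR order by AIC on a common sample (rows from p_max on).

    AIC(p) = ln det(Sigma_hat_p) + 2 k_p / T with k_p the total number of
    estimated coefficients; returns the argmin and the criterion table.
    """
    Z = panel.matrix
    T = Z.shape[0]
    if T <= 3 * p_max + 10:
        raise ConfigError(f"sample too short (T={T}) for p_max={p_max}")
    rows = []
    for p in range(1, p_max + 1):
        X, Y = _lag_design(Z, p, start=p_max)
        beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
        resid = Y - X @ beta
        n = Y.shape[0]
        k_p = beta.size
        sign, logdet = np.linalg.slogdet(_sigma_ml(resid))
        if sign <= 0:
            raise EstimationError(f"singular residual covariance at p={p}")
        rows.append({"p": p, "aic": logdet + 2.0 * k_p / n, "n_coeffs": k_p})
    table = pd.DataFrame(rows).set_index("p")
    return int(table["aic"].idxmin()), table


def fit_var(panel: SystemPanel, p: int) -> ReducedVARFit:
    """Fit the VAR(p) by per-equation OLS on intercept + p lags of all series."""
    if p < 1:
        raise ConfigError("lag order must be >= 1")
    Z = panel.matrix
    T = Z.shape[0]
    if T - p <= 3 * p + 1:
        raise ConfigError(f"sample too short (T={T}) for p={p}")
    X, Y = _lag_design(Z, p)
    # collinearity guard: a constant data column duplicates the intercept
    for j in range(3):
        if np.ptp(Z[:, j]) == 0:
            raise EstimationError(f"column '{panel.variables[j]}' is constant")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise EstimationError("collinear regressors in the lag design")
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)   # (1+3p, 3)
    fitted = X @ beta
    resid = Y - fitted
    sign, logdet = np.linalg.slogdet(_sigma_ml(resid))
    aic = logdet + 2.0 * beta.size / Y.shape[0]
    lag_coeffs = np.stack(
        [beta[1 + 3 * (k - 1): 1 + 3 * k].T for k in range(1, p + 1)]
    )
    return ReducedVARFit(
        lag_order=p,
        intercepts=beta[0].copy(),
        lag_coeffs=lag_coeffs,
        residuals=resid,
        residual_dates=panel.dates[p:],
        fitted=fitted,
        design=X,
        aic=float(aic),
        variables=panel.variables,
    )


def companion_matrix(lag_coeffs: np.ndarray) -> np.ndarray:
    """Stack D_1..D_p into the 3p x 3p first-order companion form."""
    p = lag_coeffs.shape[0]
    m = 3 * p
    C = np.zeros((m, m))
    C[:3] = np.concatenate(list(lag_coeffs), axis=1)
    if p > 1:
        C[3:, :-3] = np.eye(m - 3)
    return C


def companion_stability(fit: ReducedVARFit) -> tuple[float, bool]:
    """Spectral radius of the companion matrix; stable iff < 1."""
    radius = float(np.max(np.abs(np.linalg.eigvals(fit.companion))))
    return radius, radius < 1.0
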