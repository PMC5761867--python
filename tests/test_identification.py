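import numpy as np
import pytest

from hetsvar import identification as ident
from hetsvar.errors import IdentificationError

#: the estimated magnitudes used throughout as a realistic parameter point
TABLE_DELTAS = np.array([-0.09, 1.25, 0.63, 0.82, -0.27, 0.00])
TABLE_VARS = {1: np.array([0.097, 0.330, 0.042]), 2: np.array([0.058, 0.432, 0.012])}


def explicit_moments(deltas, v):
    """Independent entrywise oracle for the six implied second moments.

    Writes each moment as an explicit polynomial in the coefficients, rather
    than forming the matrix product, so the two routes are independent.
    """
    d12, d13, d21, d23, d31, d32 = deltas
    v1, v2, v3 = v
    return np.array(
        [
            v1 + d12**2 * v2 + d13**2 * v3,                 # var(e_law)
            d21 * v1 + d12 * v2 + d13 * d23 * v3,           # cov(e_law, e_ctz)
            d31 * v1 + d12 * d32 * v2 + d13 * v3,           # cov(e_law, e_twt)
            d21**2 * v1 + v2 + d23**2 * v3,                 # var(e_ctz)
            d21 * d31 * v1 + d32 * v2 + d23 * v3,           # cov(e_ctz, e_twt)
            d31**2 * v1 + d32**2 * v2 + v3,                 # var(e_twt)
        ]
    )


def forward_pair(deltas, variances):
    s1 = ident.implied_covariance(deltas, variances[1])
    s2 = ident.implied_covariance(deltas, variances[2])
    return s1, s2


class TestMomentResiduals:
    def test_zero_deltas_leave_covariances(self):
        s1, s2 = forward_pair(TABLE_DELTAS, TABLE_VARS)
        variances = {1: np.diag(s1), 2: np.diag(s2)}
        r = ident.moment_residuals(np.zeros(6), variances, s1, s2)
        # variance rows vanish, covariance rows echo the sample covariances
        for i, row in enumerate((0, 3, 5, 6, 9, 11)):
            assert r[row] == pytest.approx(0.0, abs=1e-12)
        assert r[1] == pytest.approx(-s1[1, 0])
        assert r[2] == pytest.approx(-s1[2, 0])

    def test_forward_construction_gives_zero(self):
        s1, s2 = forward_pair(TABLE_DELTAS, TABLE_VARS)
        r = ident.moment_residuals(TABLE_DELTAS, TABLE_VARS, s1, s2)
        np.testing.assert_allclose(r, 0.0, atol=1e-14)

    def test_matrix_identity_matches_explicit_formulas(self):
        """B diag(v) B' agrees entrywise with the explicit moment polynomials
        for 100 random parameter draws."""
        rng = np.random.default_rng(123)
        for _ in range(100):
            deltas = rng.normal(scale=0.8, size=6)
            v = np.exp(rng.normal(size=3))
            M = ident.implied_covariance(deltas, v)
            vech = np.array([M[0, 0], M[1, 0], M[2, 0], M[1, 1], M[2, 1], M[2, 2]])
            np.testing.assert_allclose(vech, explicit_moments(deltas, v), atol=1e-12)


class TestJacobian:
    def test_analytic_jacobian_matches_finite_differences(self):
        rng = np.random.default_rng(7)
        s1, s2 = forward_pair(TABLE_DELTAS, TABLE_VARS)
        theta = np.concatenate(
            [TABLE_DELTAS, np.log(TABLE_VARS[1]), np.log(TABLE_VARS[2])]
        ) + rng.normal(scale=0.05, size=12)
        r0, J = ident._residual_and_jacobian(theta, s1, s2)
        eps = 1e-7
        J_fd = np.empty((12, 12))
        for q in range(12):
            tp = theta.copy()
            tp[q] += eps
            rp, _ = ident._residual_and_jacobian(tp, s1, s2)
            J_fd[:, q] = (rp - r0) / eps
        np.testing.assert_allclose(J, J_fd, atol=1e-5)


class TestSolve:
    def test_recovers_table_magnitude_parameters(self):
        s1, s2 = forward_pair(TABLE_DELTAS, TABLE_VARS)
        sol = ident.solve_identification(s1, s2)
        np.testing.assert_allclose(sol.deltas, TABLE_DELTAS, atol=1e-6)
        np.testing.assert_allclose(sol.shock_variances[1], TABLE_VARS[1], atol=1e-6)
        np.testing.assert_allclose(sol.shock_variances[2], TABLE_VARS[2], atol=1e-6)
        assert sol.moment_residual_norm < 1e-8

    def test_diagonal_case_gives_zero_deltas(self):
        s1 = np.diag([2.0, 1.0, 0.5])
        s2 = np.diag([1.0, 1.0, 2.0])
        sol = ident.solve_identification(s1, s2)
        np.testing.assert_allclose(sol.deltas, 0.0, atol=1e-8)
        np.testing.assert_allclose(sol.shock_variances[1], [2.0, 1.0, 0.5], atol=1e-8)

    def test_identical_covariances_rejected(self):
        s1, _ = forward_pair(TABLE_DELTAS, TABLE_VARS)
        with pytest.raises(IdentificationError, match="6 equations and 9"):
            ident.solve_identification(s1, s1.copy())

    def test_weak_identification_guard(self):
        s1 = np.diag([1.0, 2.0, 3.0])
        s2 = s1 * 1.05
        with pytest.raises(IdentificationError, match="weak identification"):
            ident.solve_identification(s1, s2)
        sol = ident.solve_identification(s1, s2, force=True)
        assert sol.converged

    def test_conservation_at_solution(self):
        """At any declared solution the implied covariances reproduce the
        inputs entrywise."""
        rng = np.random.default_rng(77)
        for _ in range(10):
            deltas = rng.normal(scale=0.5, size=6)
            variances = {1: np.exp(rng.normal(size=3)), 2: np.exp(rng.normal(size=3))}
            s1, s2 = forward_pair(deltas, variances)
            try:
                sol = ident.solve_identification(s1, s2)
            except IdentificationError:
                continue
            np.testing.assert_allclose(
                ident.implied_covariance(sol.deltas, sol.shock_variances[1]), s1,
                atol=1e-8,
            )
            np.testing.assert_allclose(
                ident.implied_covariance(sol.deltas, sol.shock_variances[2]), s2,
                atol=1e-8,
            )

    def test_regime_relabel_invariance(self):
        """Swapping the regimes swaps the variance blocks, deltas unchanged."""
        s1, s2 = forward_pair(TABLE_DELTAS, TABLE_VARS)
        sol = ident.solve_identification(s1, s2)
        swapped = ident.solve_identification(s2, s1)
        np.testing.assert_allclose(swapped.deltas, sol.deltas, atol=1e-6)
        np.testing.assert_allclose(
            swapped.shock_variances[1], sol.shock_variances[2], atol=1e-6
        )


class TestDiagnostics:
    def _solution(self):
        return ident.StructuralSolution(
            deltas=TABLE_DELTAS,
            shock_variances=TABLE_VARS,
            moment_residual_norm=0.0,
            converged=True,
            starts_tried=1,
        )

    def test_all_replicates_above_one_small_p(self):
        repl = np.tile(np.array([[2.0, 2.0, 3.0, 1.0, 1.0, 1.0]]), (199, 1))
        d = ident.variance_ratio_test(self._solution(), repl)
        np.testing.assert_allclose(d.ratio_pvalues, 1.0 / 200.0)

    def test_replicates_symmetric_about_one(self):
        rng = np.random.default_rng(1)
        f = np.exp(rng.normal(scale=0.2, size=(400, 3)))
        repl = np.hstack([f, np.ones((400, 3))])
        d = ident.variance_ratio_test(self._solution(), repl)
        assert np.all(np.abs(d.ratio_pvalues - 0.5) < 0.12)

    def test_uniqueness_statistic_is_one_under_common_rescaling(self):
        v1 = np.array([0.2, 0.4, 0.1])
        sol = ident.StructuralSolution(
            deltas=TABLE_DELTAS,
            shock_variances={1: 3.0 * v1, 2: v1},
            moment_residual_norm=0.0,
            converged=True,
            starts_tried=1,
        )
        repl = np.hstack([np.tile(3.0 * v1, (150, 1)), np.tile(v1, (150, 1))])
        d = ident.uniqueness_test(sol, repl)
        for stat in d.uniqueness_stats.values():
            assert stat == pytest.approx(1.0)
        for p in d.uniqueness_pvalues.values():
            assert p == pytest.approx(1.0)

    def test_heterogeneous_shift_rejected(self):
        rng = np.random.default_rng(2)
        # tweet ratio ~3.2, law ratio ~1.7: strongly non-homogeneous
        base = np.array([1.7, 0.8, 3.2])
        f = base * np.exp(rng.normal(scale=0.05, size=(300, 3)))
        repl = np.hstack([f, np.ones((300, 3))])
        sol = ident.StructuralSolution(
            deltas=TABLE_DELTAS,
            shock_variances={1: base.copy(), 2: np.ones(3)},
            moment_residual_norm=0.0,
            converged=True,
            starts_tried=1,
        )
        d = ident.uniqueness_test(sol, repl)
        assert d.uniqueness_pvalues[(0, 2)] < 0.05
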