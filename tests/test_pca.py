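import numpy as np
import pytest

from essdyn.alignment import align_trajectory, residue_rmsf
from essdyn.pca import (
    correlation_from_covariance,
    covariance,
    eigendecompose,
    matrix_bundle,
    mean_center,
    mode_msf,
    partial_correlation,
    project,
    reduce_matrix,
)
from essdyn.synthetic import (
    chain_model_data,
    make_reference,
    random_orthonormal_modes,
    rigid_body_generators,
)

from conftest import random_spd


class TestMeanCenter:
    def test_constant_row_becomes_zero(self):
        data = np.vstack([np.full(4, 7.0), np.arange(4.0)])
        centered, means = mean_center(data)
        np.testing.assert_allclose(centered[0], 0.0)
        assert means[0] == 7.0

    def test_idempotent(self, rng):
        data = rng.normal(size=(6, 9))
        once, _ = mean_center(data)
        twice, _ = mean_center(once)
        np.testing.assert_allclose(twice, once, atol=1e-14)

    def test_matches_brute_force(self, rng):
        data = rng.normal(size=(6, 4))
        centered, means = mean_center(data)
        for i in range(6):
            mu = sum(data[i]) / 4
            assert means[i] == pytest.approx(mu, abs=1e-14)
            for t in range(4):
                assert centered[i, t] == pytest.approx(data[i, t] - mu, abs=1e-14)


class TestCovariance:
    def test_dimension_is_3m_squared(self, rng):
        centered, _ = mean_center(rng.normal(size=(9, 20)))
        assert covariance(centered).shape == (9, 9)

    def test_anticorrelated_closed_form(self):
        n = 8
        row = np.array([1.0, -1] * (n // 2)) * np.sqrt((n - 1) / n)
        data = np.vstack([row, -row])  # unit variance, perfectly anticorrelated
        Q = covariance(data)
        np.testing.assert_allclose(Q, [[1, -1], [-1, 1]], atol=1e-12)

    def test_matches_elementwise_double_loop(self, rng):
        centered, _ = mean_center(rng.normal(size=(5, 50)))
        Q = covariance(centered)
        n = 50
        for i in range(5):
            for j in range(5):
                acc = sum(centered[i, t] * centered[j, t] for t in range(n))
                assert Q[i, j] == pytest.approx(acc / (n - 1), abs=1e-12)

    def test_psd_within_tolerance(self, rng):
        centered, _ = mean_center(rng.normal(size=(12, 8)))  # rank deficient
        Q = covariance(centered)
        evals = np.linalg.eigvalsh(Q)
        assert evals.min() >= -1e-10 * np.abs(Q).max()


class TestCorrelation:
    def test_unit_diagonal(self, rng):
        Q = random_spd(rng, 6)
        R = correlation_from_covariance(Q)
        np.testing.assert_allclose(np.diag(R), 1.0, atol=1e-10)
        assert np.abs(R).max() <= 1 + 1e-10

    def test_rank1_closed_form(self):
        R = correlation_from_covariance(np.array([[4.0, 2], [2, 1]]))
        np.testing.assert_allclose(R, [[1, 1], [1, 1]], atol=1e-12)

    def test_matches_per_element_oracle(self, rng):
        Q = random_spd(rng, 5)
        R = correlation_from_covariance(Q)
        for i in range(5):
            for j in range(5):
                assert R[i, j] == pytest.approx(
                    Q[i, j] / np.sqrt(Q[i, i] * Q[j, j]), abs=1e-12
                )

    def test_zero_variance_variable_named(self):
        Q = np.diag([1.0, 0.0, 2.0])
        with pytest.raises(ValueError, match=r"\[1\]"):
            correlation_from_covariance(Q)

    def test_correlation_of_standardized_data_equals_its_covariance(self, rng):
        data = rng.normal(size=(5, 200)) * rng.uniform(0.5, 3, size=(5, 1))
        centered, _ = mean_center(data)
        std = centered / centered.std(axis=1, ddof=1, keepdims=True)
        np.testing.assert_allclose(
            correlation_from_covariance(covariance(centered)),
            covariance(std),
            atol=1e-10,
        )


def partial_correlation_by_regression(data, i, j, others):
    """Brute-force partial correlation: correlate the residuals of i and j
    after least-squares regression on the remaining variables."""
    X = data[others].T
    X = np.column_stack([np.ones(len(X)), X])

    def residual(v):
        beta, *_ = np.linalg.lstsq(X, v, rcond=None)
        return v - X @ beta

    ri, rj = residual(data[i]), residual(data[j])
    return float(ri @ rj / np.sqrt((ri @ ri) * (rj @ rj)))


class TestPartialCorrelation:
    def test_diagonal_q_gives_identity(self):
        P, omega = partial_correlation(np.diag([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(P, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(omega, np.diag([1, 0.5, 1 / 3]), atol=1e-12)

    def test_symmetric_unit_diagonal(self, rng):
        P, _ = partial_correlation(random_spd(rng, 7))
        np.testing.assert_allclose(P, P.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(P), 1.0)

    def test_chain_fixture_recovers_conditional_independence(self):
        # X <- Y -> Z: direct X-Y and Y-Z dependence only; X-Z correlation is
        # entirely mediated by Y, so the partial correlation vanishes
        rng = np.random.default_rng(2024)
        data = chain_model_data(10_000, rng)
        centered, _ = mean_center(data)
        Q = covariance(centered)
        R = correlation_from_covariance(Q)
        P, _ = partial_correlation(Q)
        assert abs(R[0, 2]) >= 0.3
        assert abs(P[0, 2]) <= 0.02
        # brute-force regression-residual oracle agrees
        oracle = partial_correlation_by_regression(centered, 0, 2, [1])
        assert P[0, 2] == pytest.approx(oracle, abs=1e-10)
        assert P[0, 1] == pytest.approx(
            partial_correlation_by_regression(centered, 0, 1, [2]), abs=1e-10
        )

    def test_singular_q_rejected_with_advice(self, rng):
        centered, _ = mean_center(rng.normal(size=(10, 4)))
        with pytest.raises(ValueError, match="outlier"):
            partial_correlation(covariance(centered))


class TestEigendecompose:
    def test_identity_matrix(self):
        modes = eigendecompose(np.eye(5), k=3)
        np.testing.assert_allclose(modes.eigenvalues, 1.0)
        assert modes.trace == pytest.approx(5.0)
        # sign rule: largest-|.| component positive
        for col in modes.eigenvectors.T:
            assert col[np.argmax(np.abs(col))] > 0

    def test_reconstruction(self, rng):
        M = random_spd(rng, 8)
        modes = eigendecompose(M)
        recon = modes.eigenvectors @ np.diag(modes.eigenvalues) @ modes.eigenvectors.T
        assert np.abs(recon - M).max() <= 1e-10

    def test_rigid_orthogonal_displacements_give_six_zero_modes(self):
        # displacements built orthogonal to the 3 translation + 3 rotation
        # generators leave exactly 6 near-zero covariance eigenvalues
        ref = make_reference(10)
        rng = np.random.default_rng(5)
        disp = rng.normal(size=(30, 100))
        G = rigid_body_generators(ref)
        disp -= G @ (G.T @ disp)
        Q = covariance(mean_center(disp)[0])
        modes = eigendecompose(Q)
        lam = modes.eigenvalues_full
        assert int((lam < 1e-9 * lam[0]).sum()) == 6
        assert modes.rank == 24

    def test_orthonormal_columns_and_descending_order(self, rng):
        modes = eigendecompose(random_spd(rng, 9), k=5)
        V = modes.eigenvectors
        np.testing.assert_allclose(V.T @ V, np.eye(5), atol=1e-10)
        assert np.all(np.diff(modes.eigenvalues) <= 1e-12)

    def test_agrees_with_jacobi_oracle(self, rng):
        M = random_spd(rng, 6)
        modes = eigendecompose(M)
        # independent Jacobi rotation sweep oracle
        A = M.copy()
        for _ in range(100):
            off = np.abs(A - np.diag(np.diag(A)))
            p, q = np.unravel_index(np.argmax(off), A.shape)
            if off[p, q] < 1e-14:
                break
            theta = 0.5 * np.arctan2(2 * A[p, q], A[q, q] - A[p, p])
            J = np.eye(6)
            J[p, p] = J[q, q] = np.cos(theta)
            J[p, q] = np.sin(theta)
            J[q, p] = -np.sin(theta)
            A = J.T @ A @ J
        jacobi_evals = np.sort(np.diag(A))[::-1]
        np.testing.assert_allclose(modes.eigenvalues_full, jacobi_evals, atol=1e-9)

    def test_non_symmetric_rejected(self, rng):
        with pytest.raises(ValueError, match="symmetric"):
            eigendecompose(rng.normal(size=(4, 4)))

    def test_r_eigenvalues_above_one_count(self, rng):
        R = correlation_from_covariance(random_spd(rng, 6))
        modes = eigendecompose(R, matrix_kind="R")
        assert modes.n_eigenvalues_gt_one == int(
            sum(1 for lam in modes.eigenvalues_full if lam > 1)
        )


class TestReduceMatrix:
    def test_single_residue_formula(self, rng):
        M = random_spd(rng, 3)
        assert reduce_matrix(M)[0, 0] == pytest.approx(np.trace(M))

    def test_isotropic_closed_form(self):
        sigma2 = 2.5
        np.testing.assert_allclose(
            reduce_matrix(sigma2 * np.eye(9)), 3 * sigma2 * np.eye(3), atol=1e-12
        )

    def test_matches_triple_indexed_brute_force(self, rng):
        m = 4
        M = rng.normal(size=(3 * m, 3 * m))
        M = M + M.T
        red = reduce_matrix(M)
        for j in range(m):
            for k in range(m):
                acc = sum(M[3 * j + a, 3 * k + a] for a in range(3))
                assert red[j, k] == pytest.approx(acc, abs=1e-12)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            reduce_matrix(np.eye(7))
        with pytest.raises(ValueError, match="m=3"):
            reduce_matrix(np.eye(12), m=3)


class TestProject:
    def test_zero_dv_zero_projection(self, rng):
        modes = eigendecompose(random_spd(rng, 6), k=3)
        proj = project(np.zeros((6, 5)), modes)
        np.testing.assert_array_equal(proj.pcs, 0.0)

    def test_parseval_completeness(self, rng):
        centered, _ = mean_center(rng.normal(size=(6, 30)))
        modes = eigendecompose(covariance(centered))
        proj = project(centered, modes, weighted=False)
        np.testing.assert_allclose(
            (proj.pcs**2).sum(axis=0), (centered**2).sum(axis=0), atol=1e-10
        )

    def test_pc_variance_matches_planted_eigenvalue(self):
        rng = np.random.default_rng(99)
        lam_true = np.array([9.0, 4.0, 1.0])
        V, _ = np.linalg.qr(rng.normal(size=(8, 3)))
        data = V @ (np.sqrt(lam_true)[:, None] * rng.standard_normal((3, 2000)))
        centered, _ = mean_center(data)
        modes = eigendecompose(covariance(centered), k=3)
        proj = project(centered, modes)
        var1 = proj.pcs[0].var(ddof=1)
        assert var1 == pytest.approx(9.0, rel=0.15)
        assert var1 == pytest.approx(modes.eigenvalues[0], rel=1e-9)
        # weighted scores have unit variance
        np.testing.assert_allclose(
            proj.pcs_weighted.var(axis=1, ddof=1), 1.0, atol=1e-6
        )

    def test_weighted_projection_requires_positive_eigenvalues(self, rng):
        centered, _ = mean_center(rng.normal(size=(9, 4)))
        modes = eigendecompose(covariance(centered))  # rank <= 3
        with pytest.raises(ValueError, match="non-positive"):
            project(centered, modes, weighted=True)


class TestModeMsf:
    def test_unweighted_sums_to_one_per_mode(self, rng):
        modes = eigendecompose(random_spd(rng, 9), k=4)
        msf = mode_msf(modes)
        np.testing.assert_allclose(msf.sum(axis=1), 1.0, atol=1e-12)

    def test_localized_mode(self):
        modes = eigendecompose(np.diag([4.0] + [0.1] * 8), k=1)
        msf = mode_msf(modes)
        np.testing.assert_allclose(msf[0], [1.0, 0.0, 0.0], atol=1e-12)

    def test_weighted_matches_per_component_brute_force(self, rng):
        modes = eigendecompose(random_spd(rng, 6), k=2)
        msf = mode_msf(modes, weighted=True)
        for k in range(2):
            for i in range(2):
                acc = sum(modes.eigenvectors[3 * i + a, k] ** 2 for a in range(3))
                assert msf[k, i] == pytest.approx(
                    modes.eigenvalues[k] * acc, abs=1e-12
                )

    def test_distance_mode_set_rejected(self, rng):
        modes = eigendecompose(random_spd(rng, 7))
        with pytest.raises(ValueError, match="distance-pair"):
            mode_msf(modes)


class TestConsistencyAndBundle:
    def test_trace_equals_eigenvalue_sum_and_total_msf(self, planted_trajectory):
        traj, _ = planted_trajectory
        aligned = align_trajectory(traj)
        centered, _ = mean_center(aligned.data)
        Q = covariance(centered)
        modes = eigendecompose(Q)
        assert modes.trace == pytest.approx(np.trace(Q), rel=1e-8)
        # trace(Q) = sum of residue MSFs (up to the n vs n-1 denominator)
        rmsf = residue_rmsf(aligned)
        n = traj.n_frames
        assert (rmsf**2).sum() * n / (n - 1) == pytest.approx(modes.trace, rel=1e-8)

    def test_bundle_contents(self, rng):
        centered, _ = mean_center(rng.normal(size=(9, 120)))
        bundle = matrix_bundle(centered, cartesian=True)
        np.testing.assert_allclose(
            bundle.precision @ bundle.R, np.eye(9), atol=1e-8
        )
        np.testing.assert_allclose(
            bundle.anti_image @ bundle.P, np.eye(9), atol=1e-8
        )
        np.testing.assert_allclose(
            bundle.inverse_covariance @ bundle.Q, np.eye(9), atol=1e-8
        )
        assert bundle.reduced_Q.shape == (3, 3)

    def test_reduced_renormalization_flag(self, rng):
        centered, _ = mean_center(rng.normal(size=(9, 120)))
        bundle = matrix_bundle(centered, cartesian=True, renormalize_reduced=True)
        np.testing.assert_allclose(np.diag(bundle.reduced_R), 1.0, atol=1e-12)
        np.testing.assert_allclose(np.diag(bundle.reduced_P), 1.0, atol=1e-12)
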