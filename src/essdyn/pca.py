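"""Covariance / correlation / partial-correlation PCA engine.

From a mean-centred data matrix A' (variables x frames) three symmetric
matrices are built:

* Q = A'(A')^T / (n - 1)  — the covariance matrix (Å² for Cartesian data);
* R — the correlation matrix, Q normalised by the variable standard
  deviations;
* P — the partial correlation matrix, the negative-normalised inverse of Q,
  measuring direct pairwise dependence with all other variables held fixed.

Each is eigendecomposed into a ``ModeSet`` of orthonormal modes with
descending eigenvalues.  The inverses R^-1 (precision) and P^-1 (anti-image)
and the inverse covariance Q^-1 complete the statistical circle, and every
3m x 3m Cartesian matrix has a rotationally invariant m x m reduced form
whose (j, k) element is the trace of the 3x3 inter-residue block.

Normalisation note: the sample (n-1) covariance denominator is used so that
eigenvalues and the trace of Q carry variance units (Å²); eigenvectors are
unaffected by the choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

__all__ = [
    "ModeSet",
    "MatrixBundle",
    "ProjectionSet",
    "mean_center",
    "covariance",
    "correlation_from_covariance",
    "partial_correlation",
    "eigendecompose",
    "reduce_matrix",
    "project",
    "mode_msf",
    "matrix_bundle",
]

#: eigenvalues below this fraction of the largest count as zero for rank
ZERO_EIGENVALUE_RTOL = 1e-9


@dataclass
class ModeSet:
    """Top-k eigenmodes of a Q, R or P matrix.

    ``trace`` is the sum of *all* eigenvalues of the source matrix and
    ``condition_number`` the ratio of the largest to the smallest eigenvalue
    counted as non-zero (relative tolerance 1e-9).
    """

    eigenvectors: np.ndarray  # d x k, orthonormal columns
    eigenvalues: np.ndarray  # k, descending
    matrix_kind: str  # Q | R | P
    trace: float
    condition_number: float
    k_retained: int
    eigenvalues_full: np.ndarray = field(repr=False, default=None)
    rank: int = 0
    n_eigenvalues_gt_one: int = 0

    @property
    def d(self) -> int:
        return self.eigenvectors.shape[0]


@dataclass
class ProjectionSet:
    """Displacement-vector projections onto retained modes.

    ``pcs`` rows are the unweighted principal components V_k^T DV(t); the
    weighted variant divides by sqrt(lambda_k), giving unit-variance scores.
    """

    pcs: np.ndarray  # k x n unweighted
    pcs_weighted: np.ndarray  # k x n
    dv: np.ndarray  # d x n displacement vectors


@dataclass
class MatrixBundle:
    """Q, R, P with their inverses and (for Cartesian data) reduced forms."""

    Q: np.ndarray
    R: np.ndarray
    P: np.ndarray
    inverse_covariance: np.ndarray  # Q^-1
    precision: np.ndarray  # R^-1
    anti_image: np.ndarray  # P^-1
    reduced_Q: np.ndarray | None = None
    reduced_R: np.ndarray | None = None
    reduced_P: np.ndarray | None = None


def mean_center(data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centre each row (variable) to zero mean over frames."""
    data = np.asarray(data, dtype=float)
    if data.shape[1] < 2:
        raise ValueError("mean centering requires at least 2 frames")
    means = data.mean(axis=1)
    return data - means[:, None], means


def covariance(centered: np.ndarray) -> np.ndarray:
    """Sample covariance Q = A'(A')^T / (n-1) of a row-centred matrix."""
    centered = np.asarray(centered, dtype=float)
    n = centered.shape[1]
    if n < 2:
        raise ValueError("covariance requires at least 2 frames")
    Q = centered @ centered.T / (n - 1)
    return 0.5 * (Q + Q.T)


def correlation_from_covariance(Q: np.ndarray) -> np.ndarray:
    """R_ij = Q_ij / sqrt(Q_ii Q_jj); errors on zero-variance variables."""
    d = np.diag(Q)
    bad = np.nonzero(d <= 0)[0]
    if bad.size:
        raise ValueError(
            f"zero-variance variable(s) {bad.tolist()}: remove them or apply "
            "outlier treatment before computing correlations"
        )
    s = 1.0 / np.sqrt(d)
    R = Q * np.outer(s, s)
    np.fill_diagonal(R, 1.0)
    return 0.5 * (R + R.T)


def _pinv_sym(M: np.ndarray, rcond: float) -> np.ndarray:
    """Eigendecomposition-based pseudo-inverse of a symmetric matrix."""
    evals, evecs = scipy.linalg.eigh(M)
    keep = np.abs(evals) > rcond * np.abs(evals).max()
    inv_vals = np.where(keep, 1.0 / np.where(keep, evals, 1.0), 0.0)
    return (evecs * inv_vals) @ evecs.T


def partial_correlation(
    Q: np.ndarray, rcond: float = 1e-12, pseudo: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Partial correlations from the precision of Q.

    With Omega = Q^-1: P_ij = -Omega_ij / sqrt(Omega_ii Omega_jj) for i != j
    and P_ii = 1.  Returns ``(P, Omega)``.  Raises when Q is numerically
    singular (smallest eigenvalue < rcond * largest), unless ``pseudo`` is
    set, in which case the Moore-Penrose pseudo-inverse restricted to the
    non-null subspace is used.  The pseudo route is what the Cartesian
    pipeline needs: quaternion alignment confines every frame to a fixed
    3m - 6 dimensional subspace, so the full-space Q is rank-deficient by
    exactly the six trivial rigid-body directions.
    """
    evals = scipy.linalg.eigvalsh(Q)
    if not pseudo and (evals[0] < rcond * evals[-1] or evals[-1] <= 0):
        raise ValueError(
            "covariance matrix is numerically singular; apply outlier "
            "treatment or reduce the number of variables"
        )
    if pseudo:
        omega = _pinv_sym(Q, max(rcond, ZERO_EIGENVALUE_RTOL))
    else:
        omega = scipy.linalg.inv(Q, check_finite=False)
    omega = 0.5 * (omega + omega.T)
    s = 1.0 / np.sqrt(np.diag(omega))
    P = -omega * np.outer(s, s)
    np.fill_diagonal(P, 1.0)
    return 0.5 * (P + P.T), omega


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-|.| component (lowest index on ties)
    is positive."""
    v = vectors.copy()
    for j in range(v.shape[1]):
        i = int(np.argmax(np.abs(v[:, j])))  # argmax takes the lowest index on ties
        if v[i, j] < 0:
            v[:, j] = -v[:, j]
    return v


def eigendecompose(
    M: np.ndarray, k: int | None = None, matrix_kind: str = "Q"
) -> ModeSet:
    """Full symmetric eigendecomposition with the top-k modes retained.

    Eigenvalues are sorted descending; eigenvector signs follow the
    largest-component-positive convention so outputs are reproducible.
    """
    M = np.asarray(M, dtype=float)
    scale = max(np.abs(M).max(), 1.0)
    if not np.allclose(M, M.T, atol=1e-8 * scale):
        raise ValueError("matrix is not symmetric")
    evals, evecs = scipy.linalg.eigh(0.5 * (M + M.T))
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    d = M.shape[0]
    k = d if k is None else min(k, d)
    lam_max = max(evals[0], 0.0)
    zero_tol = ZERO_EIGENVALUE_RTOL * lam_max
    positive = evals[evals > zero_tol]
    cond = float(positive[0] / positive[-1]) if positive.size else np.inf
    return ModeSet(
        eigenvectors=_fix_signs(evecs[:, :k]),
        eigenvalues=evals[:k].copy(),
        matrix_kind=matrix_kind,
        trace=float(evals.sum()),
        condition_number=cond,
        k_retained=k,
        eigenvalues_full=evals,
        rank=int(positive.size),
        n_eigenvalues_gt_one=int((evals > 1.0).sum()),
    )


def reduce_matrix(M: np.ndarray, m: int | None = None) -> np.ndarray:
    """Residue-level m x m reduction of a 3m x 3m Cartesian matrix.

    Element (j, k) is the trace of the 3x3 block coupling residues j and k:
    M~_jk = M_xj,xk + M_yj,yk + M_zj,zk.
    """
    M = np.asarray(M, dtype=float)
    if M.shape[0] != M.shape[1] or M.shape[0] % 3:
        raise ValueError("matrix dimension must be square and divisible by 3")
    m_inferred = M.shape[0] // 3
    if m is not None and m != m_inferred:
        raise ValueError(f"dimension mismatch: {M.shape[0]} rows for m={m}")
    m = m_inferred
    return np.einsum("iaja->ij", M.reshape(m, 3, m, 3))


def project(
    centered_dv: np.ndarray, modes: ModeSet, weighted: bool = True
) -> ProjectionSet:
    """Project displacement vectors onto retained modes.

    Unweighted pc_k(t) = V_k^T DV(t); the weighted score divides by
    sqrt(lambda_k) (requires positive eigenvalues; pass ``weighted=False``
    to skip it for rank-deficient mode sets).
    """
    dv = np.asarray(centered_dv, dtype=float)
    if dv.shape[0] != modes.d:
        raise ValueError("dimension mismatch between DV and modes")
    pcs = modes.eigenvectors.T @ dv
    lam = modes.eigenvalues
    if not weighted:
        return ProjectionSet(pcs=pcs, pcs_weighted=np.full_like(pcs, np.nan), dv=dv)
    if np.any(lam <= 0):
        raise ValueError("weighted projection undefined for non-positive eigenvalues")
    return ProjectionSet(pcs=pcs, pcs_weighted=pcs / np.sqrt(lam)[:, None], dv=dv)


def mode_msf(modes: ModeSet, weighted: bool = False) -> np.ndarray:
    """Per-residue mean squared fluctuation of each Cartesian mode.

    Unweighted MSF_i of mode k sums the squared x, y, z components of V_k at
    residue i (so it sums to 1 over residues); the weighted form multiplies
    by lambda_k.  Shape (k, m).  Only defined for Cartesian mode sets.
    """
    if modes.d % 3:
        raise ValueError(
            "per-residue MSF is undefined for distance-pair mode sets "
            "(no residue mapping)"
        )
    m = modes.d // 3
    comp = modes.eigenvectors.T.reshape(modes.k_retained, m, 3)
    msf = (comp**2).sum(axis=2)
    if weighted:
        msf = msf * modes.eigenvalues[:, None]
    return msf


def matrix_bundle(
    centered: np.ndarray,
    cartesian: bool = True,
    renormalize_reduced: bool = False,
    pseudo: bool | None = None,
) -> MatrixBundle:
    """Build Q, R, P, their inverses, and (Cartesian) reduced forms.

    ``renormalize_reduced`` rescales the reduced R and P block-trace forms
    back to unit diagonal (off by default; the reduced covariance is never
    renormalised).  ``pseudo`` selects the pseudo-inverse route for the
    precision/anti-image matrices; it defaults to on for Cartesian data,
    whose aligned covariance is rank-deficient by the six rigid-body
    directions, and off for distance data.
    """
    if pseudo is None:
        pseudo = cartesian
    Q = covariance(centered)
    R = correlation_from_covariance(Q)
    P, inv_Q = partial_correlation(Q, pseudo=pseudo)
    if pseudo:
        precision = _pinv_sym(R, ZERO_EIGENVALUE_RTOL)
        anti_image = _pinv_sym(P, ZERO_EIGENVALUE_RTOL)
    else:
        precision = scipy.linalg.inv(R, check_finite=False)
        anti_image = scipy.linalg.inv(P, check_finite=False)
    red_Q = red_R = red_P = None
    if cartesian:
        red_Q = reduce_matrix(Q)
        red_R = reduce_matrix(R)
        red_P = reduce_matrix(P)
        if renormalize_reduced:
            for red in (red_R, red_P):
                s = 1.0 / np.sqrt(np.diag(red))
                red *= np.outer(s, s)
    return MatrixBundle(Q, R, P, inv_Q, precision, anti_image, red_Q, red_R, red_P)
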