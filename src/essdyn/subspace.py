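"""Similarity of essential subspaces.

Two mode sets spanning the same variable space are compared through three
standard metrics: the cumulative overlap (CO) of a single mode against a
basis, the root mean square inner product (RMSIP) of two equal-dimension
subspaces, and the principal (canonical) angles obtained from the singular
values of the basis cross-product.  Principal angles of at most 30 degrees
are conventionally read as high similarity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .pca import ModeSet

__all__ = [
    "SubspaceReport",
    "cumulative_overlap",
    "rmsip",
    "principal_angles",
    "compare_mode_sets",
]

HIGH_SIMILARITY_ANGLE_DEG = 30.0


@dataclass
class SubspaceReport:
    dim_a: int
    dim_b: int
    cumulative_overlaps: np.ndarray  # CO of each of A's vectors vs B's basis
    rmsip: float
    principal_angles: np.ndarray  # degrees, ascending
    high_similarity_count: int  # angles <= 30 degrees
    rmsip_curve: np.ndarray | None = None  # RMSIP at k = 1..k_max

    def to_text(self) -> str:
        lines = [
            f"# subspace comparison: dim_a={self.dim_a} dim_b={self.dim_b}",
            "# CO = sqrt(sum_k (v . b_k)^2) of each mode of set A against set B",
            f"# RMSIP = {self.rmsip:.6f}",
            f"# principal angles <= {HIGH_SIMILARITY_ANGLE_DEG:.0f} deg (high "
            f"similarity): {self.high_similarity_count}",
            "# mode  CO        PA_deg",
        ]
        for i in range(len(self.principal_angles)):
            co = self.cumulative_overlaps[i] if i < len(self.cumulative_overlaps) else np.nan
            lines.append(f"{i + 1:4d}  {co:8.4f}  {self.principal_angles[i]:9.4f}")
        if self.rmsip_curve is not None:
            lines.append("# k  RMSIP(k)")
            lines += [f"{k + 1:3d}  {v:.6f}" for k, v in enumerate(self.rmsip_curve)]
        return "\n".join(lines) + "\n"


def _check_orthonormal(B: np.ndarray, name: str, tol: float = 1e-6) -> None:
    G = B.T @ B
    if not np.allclose(G, np.eye(B.shape[1]), atol=tol):
        raise ValueError(f"{name} does not have orthonormal columns")


def cumulative_overlap(v: np.ndarray, basis: np.ndarray) -> float:
    """CO = sqrt(sum_k (v . b_k)^2) of unit vector ``v`` against an
    orthonormal basis; 1 when v lies in the span, 0 when orthogonal."""
    v = np.asarray(v, dtype=float).ravel()
    basis = np.atleast_2d(np.asarray(basis, dtype=float))
    if basis.shape[0] != v.size:
        raise ValueError("dimension mismatch between vector and basis")
    if abs(np.linalg.norm(v) - 1.0) > 1e-8:
        raise ValueError("vector must be unit length")
    _check_orthonormal(basis, "basis")
    return float(np.sqrt(((basis.T @ v) ** 2).sum()))


def rmsip(U: np.ndarray, V: np.ndarray) -> float:
    """Root mean square inner product of two orthonormal d x k bases:
    sqrt((1/k) sum_ij (u_i . v_j)^2)."""
    U = np.asarray(U, dtype=float)
    V = np.asarray(V, dtype=float)
    if U.shape != V.shape:
        raise ValueError("RMSIP requires equal dimensions (same d and k)")
    _check_orthonormal(U, "U")
    _check_orthonormal(V, "V")
    k = U.shape[1]
    return float(np.sqrt(((U.T @ V) ** 2).sum() / k))


def principal_angles(U: np.ndarray, V: np.ndarray) -> np.ndarray:
    """Canonical angles between the column spans of U and V, in degrees,
    ascending; singular values of U^T V are clamped to [0, 1] before arccos."""
    U = np.asarray(U, dtype=float)
    V = np.asarray(V, dtype=float)
    if U.size == 0 or V.size == 0 or U.ndim != 2 or V.ndim != 2:
        raise ValueError("empty basis")
    if U.shape[0] != V.shape[0]:
        raise ValueError("bases live in different variable spaces")
    _check_orthonormal(U, "U")
    _check_orthonormal(V, "V")
    sigma = np.linalg.svd(U.T @ V, compute_uv=False)
    sigma = np.clip(sigma, 0.0, 1.0)
    return np.degrees(np.arccos(np.sort(sigma)[::-1]))


def compare_mode_sets(
    a: ModeSet | np.ndarray,
    b: ModeSet | np.ndarray,
    k: int | None = None,
) -> SubspaceReport:
    """Full similarity report over the top-k modes of each set.

    When the two sets retain different numbers of modes, the comparison uses
    min(k_a, k_b) and warns.  ``rmsip_curve[k-1]`` gives the RMSIP of the
    leading k modes for k = 1..k_max, supporting "how many modes capture the
    essential dynamics" analyses.
    """
    A = a.eigenvectors if isinstance(a, ModeSet) else np.asarray(a, dtype=float)
    B = b.eigenvectors if isinstance(b, ModeSet) else np.asarray(b, dtype=float)
    if A.shape[0] != B.shape[0]:
        raise ValueError("mode sets live in different variable spaces")
    k_max = min(A.shape[1], B.shape[1])
    if A.shape[1] != B.shape[1]:
        warnings.warn(
            f"mode sets retain {A.shape[1]} vs {B.shape[1]} modes; comparing "
            f"the leading {k_max}"
        )
    if k is not None:
        k_max = min(k, k_max)
    A = A[:, :k_max]
    B = B[:, :k_max]
    cos = np.abs(A.T @ B)
    overlaps = np.sqrt((cos**2).sum(axis=1))
    angles = principal_angles(A, B)
    curve = np.array(
        [rmsip(A[:, : j + 1], B[:, : j + 1]) for j in range(k_max)]
    )
    return SubspaceReport(
        dim_a=k_max,
        dim_b=k_max,
        cumulative_overlaps=overlaps,
        rmsip=rmsip(A, B),
        principal_angles=angles,
        high_similarity_count=int((angles <= HIGH_SIMILARITY_ANGLE_DEG).sum()),
        rmsip_curve=curve,
    )
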