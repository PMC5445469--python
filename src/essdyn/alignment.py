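"""Quaternion least-squares superposition and trajectory alignment.

Every frame is translated so its (unweighted, CA-only) centroid sits at the
origin and then rotated to minimise the least-squares displacement to the
reference frame, which is likewise centred.  The optimal proper rotation is
obtained from the leading eigenvector of Horn's 4x4 key matrix built from
the coordinate cross-covariance; this is exactly the rotation that minimises
RMSD over all proper rotations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import Trajectory

__all__ = [
    "AlignedTrajectory",
    "optimal_superposition",
    "align_trajectory",
    "residue_rmsf",
]


@dataclass
class AlignedTrajectory:
    """Aligned 3m x n coordinate matrix with per-frame RMSD to the reference."""

    data: np.ndarray
    labels: list[tuple[str, int]]
    frame_ids: list[str]
    reference_index: int
    rmsd_per_frame: np.ndarray
    block_labels: list[str] | None = field(default=None)

    @property
    def n_residues(self) -> int:
        return len(self.labels)

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]

    def frame(self, t: int) -> np.ndarray:
        return self.data[:, t].reshape(-1, 3)

    @property
    def mean_structure(self) -> np.ndarray:
        """Mean aligned conformation, shape (m, 3)."""
        return self.data.mean(axis=1).reshape(-1, 3)


def _as_points(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        if x.size % 3:
            raise ValueError("flat coordinate vector length must be divisible by 3")
        x = x.reshape(-1, 3)
    return x


def _key_matrix(S: np.ndarray) -> np.ndarray:
    """Horn's 4x4 key matrix from the 3x3 cross-covariance S = sum x_i y_i^T."""
    Sxx, Sxy, Sxz = S[0]
    Syx, Syy, Syz = S[1]
    Szx, Szy, Szz = S[2]
    return np.array(
        [
            [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
            [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
            [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
            [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
        ]
    )


def _quat_to_rotation(q: np.ndarray) -> np.ndarray:
    w, x, y, z = q
    return np.array(
        [
            [w * w + x * x - y * y - z * z, 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), w * w - x * x + y * y - z * z, 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), w * w - x * x - y * y + z * z],
        ]
    )


def optimal_superposition(
    x: np.ndarray, x_ref: np.ndarray
) -> tuple[np.ndarray, float]:
    """Optimal proper rotation superposing centred ``x`` onto centred ``x_ref``.

    Returns ``(rotation, rmsd)`` where ``rotation @ x_i`` best fits
    ``x_ref_i`` in the least-squares sense and
    ``rmsd = sqrt(mean_i ||R x_i - x_ref_i||^2)`` in Å.

    Raises on fewer than 3 atoms or (near-)collinear configurations, for
    which the optimal rotation is not unique.
    """
    x = _as_points(x)
    y = _as_points(x_ref)
    if x.shape != y.shape:
        raise ValueError("coordinate shape mismatch")
    m = x.shape[0]
    if m < 3:
        raise ValueError("at least 3 atoms required for a unique superposition")
    # collinearity check on the reference: two significant singular values needed
    for pts in (x, y):
        sv = np.linalg.svd(pts - pts.mean(axis=0), compute_uv=False)
        if sv[1] < 1e-8 * max(sv[0], 1.0):
            raise ValueError("degenerate (collinear) configuration: rotation not unique")

    S = x.T @ y
    K = _key_matrix(S)
    evals, evecs = np.linalg.eigh(K)
    # leading eigenvector; deterministic pick under (near-)degeneracy
    top = np.isclose(evals, evals[-1], rtol=1e-12, atol=0.0)
    candidates = [evecs[:, i] for i in np.nonzero(top)[0]]
    q = max(candidates, key=lambda v: tuple(np.round(np.abs(v), 12)))
    nz = np.nonzero(np.abs(q) > 1e-12)[0]
    if nz.size and q[nz[0]] < 0:
        q = -q
    R = _quat_to_rotation(q / np.linalg.norm(q))
    diff = x @ R.T - y
    rmsd = float(np.sqrt((diff**2).sum() / m))
    return R, rmsd


def align_trajectory(traj: Trajectory) -> AlignedTrajectory:
    """Centre every frame at the origin and rotate it onto the centred
    reference frame by quaternion least squares.

    The reference frame itself ends up centred and unrotated.
    """
    ref = traj.reference
    ref = ref - ref.mean(axis=0)
    m, n = traj.n_residues, traj.n_frames
    aligned = np.empty((3 * m, n))
    rmsd = np.empty(n)
    for t in range(n):
        x = traj.frame(t)
        x = x - x.mean(axis=0)
        if t == traj.reference_index:
            aligned[:, t] = ref.reshape(-1)
            rmsd[t] = 0.0
            continue
        R, r = optimal_superposition(x, ref)
        aligned[:, t] = (x @ R.T).reshape(-1)
        rmsd[t] = r
    return AlignedTrajectory(
        aligned, list(traj.labels), list(traj.frame_ids), traj.reference_index, rmsd
    )


def residue_rmsf(aligned: AlignedTrajectory | np.ndarray) -> np.ndarray:
    """Per-residue RMSF over frames:
    ``rmsf_i = sqrt(mean_t ||x_i(t) - <x_i>||^2)`` in Å."""
    data = aligned.data if isinstance(aligned, AlignedTrajectory) else np.asarray(aligned)
    if data.shape[1] < 2:
        raise ValueError("RMSF requires at least 2 frames")
    dev = data - data.mean(axis=1, keepdims=True)
    msf_per_row = (dev**2).mean(axis=1)
    return np.sqrt(msf_per_row.reshape(-1, 3).sum(axis=1))
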