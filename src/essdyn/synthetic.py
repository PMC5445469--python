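"""Synthetic alpha-carbon trajectories with planted covariance structure.

Toy CA traces (helix, extended chain, or random walk with ~3.8 Å consecutive
spacing) are decorated with Gaussian displacements along planted orthonormal
mode vectors with chosen eigenvalues, optionally contaminated with per-frame
rigid-body rotations and translations, so that the full analysis pipeline
(alignment, outlier treatment, PCA, subspace comparison) can be validated
against known ground truth without any external data.

The six rigid-body generators at the reference (three unit translations and
three centred infinitesimal-rotation fields r_i x e_axis, jointly
orthonormalised) are exposed so planted modes can be constructed orthogonal
to the trivial subspace, making the 3m - 6 rank structure of the Cartesian
covariance matrix exactly testable.

These are Gaussian, harmonic-like fluctuations: they reproduce the second
moments PCA sees but none of the anharmonicity, solvent friction or
multi-basin kinetics of real molecular dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import Trajectory, write_ca_pdb

__all__ = [
    "PlantedModel",
    "make_reference",
    "rigid_body_generators",
    "random_orthonormal_modes",
    "sample_trajectory",
    "sample_displacements",
    "write_trajectory_pdbs",
    "chain_model_data",
    "two_cluster_points",
]


def make_reference(m: int, geometry: str = "helix", seed: int = 0) -> np.ndarray:
    """Non-degenerate CA trace of m residues with ~3.8 Å consecutive spacing.

    Geometries: "helix" (ideal alpha-helix parameters), "extended"
    (near-straight zig-zag; end-to-end ~ 3.8 (m-1) Å), "random"
    (self-avoiding-ish random walk, reproducible for a fixed seed).
    """
    if m < 4:
        raise ValueError("at least 4 residues required")
    if geometry == "helix":
        # alpha-helix CA geometry: radius 2.3 Å, rise 1.5 Å, 100 deg/residue
        t = np.arange(m) * np.deg2rad(100.0)
        coords = np.column_stack(
            [2.3 * np.cos(t), 2.3 * np.sin(t), 1.5 * np.arange(m)]
        )
    elif geometry == "extended":
        # flat zig-zag with 3.8 Å bonds, slight kink to avoid collinearity
        x = np.arange(m) * 3.79
        y = 0.27 * (np.arange(m) % 2)
        z = 0.13 * np.sin(0.5 * np.arange(m))
        coords = np.column_stack([x, y, z])
    elif geometry == "random":
        rng = np.random.default_rng(seed)
        steps = rng.normal(size=(m - 1, 3))
        steps /= np.linalg.norm(steps, axis=1, keepdims=True)
        coords = np.vstack([[0.0, 0.0, 0.0], np.cumsum(3.8 * steps, axis=0)])
    else:
        raise ValueError(f"unknown geometry {geometry!r}")
    return coords


def rigid_body_generators(ref: np.ndarray) -> np.ndarray:
    """Orthonormal basis (3m x 6) of the rigid-body subspace at ``ref``:
    3 uniform translations and 3 centred infinitesimal rotations
    r_i x e_axis about the centroid, jointly orthonormalised by QR."""
    ref = np.asarray(ref, dtype=float).reshape(-1, 3)
    m = ref.shape[0]
    centred = ref - ref.mean(axis=0)
    gens = []
    for axis in np.eye(3):
        gens.append(np.tile(axis, m))  # translation
    for axis in np.eye(3):
        gens.append(np.cross(centred, axis).reshape(-1))  # infinitesimal rotation
    G = np.column_stack(gens)
    Qmat, _ = np.linalg.qr(G)
    return Qmat[:, :6]


def random_orthonormal_modes(
    ref: np.ndarray,
    n_modes: int,
    rng: np.random.Generator,
    orthogonal_to_rigid: bool = True,
) -> np.ndarray:
    """Random orthonormal 3m x n_modes internal-mode basis, optionally
    projected orthogonal to the 6 rigid-body generators."""
    ref = np.asarray(ref, dtype=float).reshape(-1, 3)
    d = 3 * ref.shape[0]
    limit = d - 6 if orthogonal_to_rigid else d
    if n_modes > limit:
        raise ValueError(f"at most {limit} modes available")
    raw = rng.normal(size=(d, n_modes))
    if orthogonal_to_rigid:
        G = rigid_body_generators(ref)
        raw -= G @ (G.T @ raw)
    Qmat, _ = np.linalg.qr(raw)
    return Qmat[:, :n_modes]


@dataclass
class PlantedModel:
    """Ground-truth generative model: frame t = ref + sum_j sqrt(lambda_j)
    z_jt v_j with independent standard-normal z, plus optional per-frame
    rigid noise (rotation up to 30 degrees, translation up to 5 Å)."""

    reference: np.ndarray  # (m, 3)
    eigenvectors: np.ndarray  # 3m x j, orthonormal
    eigenvalues: np.ndarray  # j, descending, Å^2
    rigid_noise: bool = False
    seed: int = 0
    labels: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.reference = np.asarray(self.reference, dtype=float).reshape(-1, 3)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        self.eigenvectors = np.asarray(self.eigenvectors, dtype=float)
        if np.any(np.diff(self.eigenvalues) > 0) or np.any(self.eigenvalues < 0):
            raise ValueError("planted eigenvalues must be non-negative, descending")
        V = self.eigenvectors
        if not np.allclose(V.T @ V, np.eye(V.shape[1]), atol=1e-8):
            raise ValueError("planted eigenvectors must be orthonormal")
        if not self.labels:
            self.labels = [("A", i + 1) for i in range(self.reference.shape[0])]

    @property
    def m(self) -> int:
        return self.reference.shape[0]


def _random_rotation(rng: np.random.Generator, max_angle_deg: float = 30.0):
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.deg2rad(rng.uniform(0.0, max_angle_deg))
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def sample_displacements(
    model: PlantedModel, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Ground-truth internal displacements (3m x n), before any rigid noise."""
    z = rng.standard_normal((model.eigenvalues.size, n))
    return model.eigenvectors @ (np.sqrt(model.eigenvalues)[:, None] * z)


def sample_trajectory(
    model: PlantedModel, n: int
) -> tuple[Trajectory, np.ndarray]:
    """Sample n frames from the planted model.

    Returns ``(trajectory, displacements)`` where ``displacements`` (3m x n)
    is the ground truth added to the reference before any rigid noise; the
    reference frame (index 0) is the clean reference itself.
    """
    if n < 2:
        raise ValueError("at least 2 frames required")
    rng = np.random.default_rng(model.seed)
    disp = sample_displacements(model, n, rng)
    disp[:, 0] = 0.0  # frame 0 is the clean reference
    ref_flat = model.reference.reshape(-1)
    frames = ref_flat[:, None] + disp
    if model.rigid_noise:
        for t in range(1, n):
            R = _random_rotation(rng)
            shift = rng.uniform(-5.0, 5.0, size=3)
            pts = frames[:, t].reshape(-1, 3)
            frames[:, t] = (pts @ R.T + shift).reshape(-1)
    traj = Trajectory(frames, list(model.labels), reference_index=0)
    return traj, disp


def write_trajectory_pdbs(
    traj: Trajectory, out_dir: str | Path, prefix: str = "frame"
) -> list[Path]:
    """Write one PDB file per frame; returns the paths in frame order."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for t in range(traj.n_frames):
        path = out_dir / f"{prefix}_{t:05d}.pdb"
        write_ca_pdb(path, traj.frame(t), traj.labels)
        paths.append(path)
    return paths


def chain_model_data(
    n: int, rng: np.random.Generator, coupling: float = 0.7
) -> np.ndarray:
    """3 x n data from the chain X <- Y -> Z: X and Z each correlate with Y
    (marginal correlation ~= ``coupling``) but are conditionally independent
    given Y, so the planted partial correlation P_XZ is zero while the
    marginal R_XZ ~= coupling**2."""
    y = rng.standard_normal(n)
    noise_sd = np.sqrt(1.0 - coupling**2)
    x = coupling * y + noise_sd * rng.standard_normal(n)
    z = coupling * y + noise_sd * rng.standard_normal(n)
    return np.vstack([x, y, z])


def two_cluster_points(
    n: int,
    rng: np.random.Generator,
    weights: tuple[float, float] = (0.7, 0.3),
    centers: tuple[tuple[float, float], tuple[float, float]] = ((-3.0, 0.0), (3.0, 0.0)),
    sd: float = 0.7,
) -> np.ndarray:
    """n x 2 mixture of two isotropic Gaussian clusters (free-energy-basin
    fixture); basin populations follow ``weights``."""
    n0 = int(round(weights[0] * n))
    pts = np.vstack(
        [
            np.asarray(centers[0]) + sd * rng.standard_normal((n0, 2)),
            np.asarray(centers[1]) + sd * rng.standard_normal((n - n0, 2)),
        ]
    )
    return pts[rng.permutation(n)]
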