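"""Cartesian PCA of a synthetic CA trajectory with known mode structure.

Plants three internal modes with eigenvalues (9, 4, 1) A^2 on a 20-residue
helix, contaminates every frame with a random rigid rotation/translation,
and shows that quaternion alignment followed by covariance PCA recovers the
planted spectrum and subspace.
"""

import numpy as np

from essdyn import align_trajectory, covariance, eigendecompose, mean_center
from essdyn.subspace import principal_angles
from essdyn.synthetic import (
    PlantedModel,
    make_reference,
    random_orthonormal_modes,
    sample_trajectory,
)

ref = make_reference(20, "helix")
rng = np.random.default_rng(0)
planted_vectors = random_orthonormal_modes(ref, 3, rng)
planted_lambda = np.array([9.0, 4.0, 1.0])
model = PlantedModel(ref, planted_vectors, planted_lambda, rigid_noise=True, seed=42)
traj, _ = sample_trajectory(model, 2000)

aligned = align_trajectory(traj)
centered, _ = mean_center(aligned.data)
modes = eigendecompose(covariance(centered), k=3, matrix_kind="Q")

print("planted eigenvalues (A^2):  ", planted_lambda)
print("recovered eigenvalues (A^2):", np.round(modes.eigenvalues, 3))
print("trace of Q (A^2):           ", round(modes.trace, 3))
print("principal angles to planted subspace (deg):",
      np.round(principal_angles(modes.eigenvectors, planted_vectors), 4))
# The recovered eigenvalues estimate the planted variances; the near-zero
# principal angles show the essential subspace itself is recovered despite
# the rigid-body contamination that alignment had to remove.
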