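"""Animating essential modes as a pseudo-trajectory.

Synthesises X(tau) = ref + sum_k A_k sin(omega_k tau) V_k over a window of
covariance modes, with amplitudes A_k = C sqrt(lambda_k) and frequencies
omega_k = B sqrt(1/lambda_k): large-amplitude essential motions move slowly,
small ones wiggle fast.  Writes a multi-model PDB plus PyMOL scripts.
"""

from pathlib import Path

import numpy as np

from essdyn import align_trajectory, covariance, eigendecompose, mean_center
from essdyn.animation import AnimationSpec, mode_amplitudes_frequencies, write_animation
from essdyn.synthetic import PlantedModel, make_reference, random_orthonormal_modes, sample_trajectory

ref = make_reference(20, "helix")
rng = np.random.default_rng(2)
model = PlantedModel(
    ref, random_orthonormal_modes(ref, 3, rng), np.array([9.0, 4.0, 1.0]), seed=2
)
traj, _ = sample_trajectory(model, 1000)
aligned = align_trajectory(traj)
modes = eigendecompose(covariance(mean_center(aligned.data)[0]), k=3, matrix_kind="Q")

spec = AnimationSpec(k0=1, w=1, matrix_kind="Q", frames_per_cycle=40)
out_dir = Path("scratch/animation_demo")
pdb = write_animation(out_dir, aligned.mean_structure.reshape(-1), modes, spec,
                      aligned.labels)

A, omega = mode_amplitudes_frequencies(modes.eigenvalues[:2], "Q", B=1.0,
                                       C=2.0 / np.sqrt(modes.eigenvalues[0]))
print("animated modes 1-2 of Q; eigenvalues:", np.round(modes.eigenvalues[:2], 2))
print("amplitudes A_k (A):   ", np.round(A, 3))
print("frequencies omega_k:  ", np.round(omega, 3))
print("wrote", pdb, "and PyMOL play/colour scripts alongside it")
# Mode 1 (largest eigenvalue) gets the 2 A peak amplitude and the lowest
# frequency; the written PDB holds 40 MODEL frames covering one period of
# that slowest mode.
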