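"""Pooling two trajectories for comparative PCA.

A "native" and a "mutant" system share their mode structure but the mutant
is displaced along an internal direction and is more flexible.  Joint PCA
of the pooled matrix separates the systems along PC1 and exposes the
flexibility difference as per-block score variance.
"""

import numpy as np

from essdyn import covariance, eigendecompose, mean_center
from essdyn.pooling import per_block_projections, pool
from essdyn.synthetic import PlantedModel, make_reference, random_orthonormal_modes, sample_trajectory

ref = make_reference(20, "helix")
rng = np.random.default_rng(8)
vectors = random_orthonormal_modes(ref, 2, rng)
shift_direction = random_orthonormal_modes(ref, 1, np.random.default_rng(9))[:, 0]

native_model = PlantedModel(ref, vectors, np.array([2.0, 1.0]), seed=21)
mutant_model = PlantedModel(ref, vectors, np.array([4.0, 2.0]), seed=22)
native, _ = sample_trajectory(native_model, 1500)
mutant, _ = sample_trajectory(mutant_model, 1500)
mutant.data += 5.0 * shift_direction[:, None]  # conformational shift

pooled = pool([native, mutant], source_ids=["native", "mutant"])
modes = eigendecompose(covariance(mean_center(pooled.data)[0]), k=3)
scores = per_block_projections(pooled, modes)

gap = scores["native"][0].mean() - scores["mutant"][0].mean()
print("pooled matrix:", pooled.data.shape, "block offsets:", pooled.offsets)
print("PC1 score-mean separation: %.2f A (planted shift 5.00 A)" % abs(gap))
for name in ("native", "mutant"):
    print(f"{name}: PC score variances:", np.round(scores[name].var(axis=1, ddof=1), 2))
# Grand-mean centring keeps the between-system displacement in the data, so
# PC1 separates the blocks by the planted 5 A shift, and the mutant's larger
# planted eigenvalues appear directly as larger per-block score variances.
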