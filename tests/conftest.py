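import numpy as np
import pytest

from essdyn.synthetic import (
    PlantedModel,
    make_reference,
    random_orthonormal_modes,
    sample_trajectory,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def helix_ref():
    return make_reference(12, "helix")


@pytest.fixture
def planted_model(helix_ref):
    """3 planted modes (9, 4, 1 A^2) orthogonal to the rigid-body subspace,
    rigid per-frame noise on."""
    gen = np.random.default_rng(7)
    vectors = random_orthonormal_modes(helix_ref, 3, gen)
    return PlantedModel(
        helix_ref, vectors, np.array([9.0, 4.0, 1.0]), rigid_noise=True, seed=7
    )


@pytest.fixture
def planted_trajectory(planted_model):
    traj, disp = sample_trajectory(planted_model, 400)
    return traj, disp


def random_spd(rng, d, jitter=0.5):
    """Random well-conditioned symmetric positive definite matrix."""
    A = rng.normal(size=(d, d))
    return A @ A.T + (d * jitter) * np.eye(d)
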