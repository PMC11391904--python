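import numpy as np
import pytest

from namdnn.data import Geometry
from namdnn.heads import ExcitedStateModel, HeadConfig, ModelConfig
from namdnn.models import SamplingSpec, generate_dataset, make_conical_2d
from namdnn.representation import RepresentationConfig


def random_rotation(rng):
    """Proper rotation matrix (det = +1) from a QR decomposition."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


def tiny_model(kind="equivariant", nac_mode="equivariant_direct",
               dipoles=True, n_states=2, seed=0, n_features=16,
               head_init="random"):
    """Small untrained model; random head weights so symmetry checks are
    non-trivial."""
    cfg = ModelConfig(
        n_states=n_states,
        representation=RepresentationConfig(
            kind=kind, n_features=n_features, n_interactions=2,
            cutoff=10.0, n_radial_basis=8, seed=seed),
        heads=HeadConfig(dipoles=dipoles, nac_mode=nac_mode))
    return ExcitedStateModel.create(cfg, head_init=head_init)


@pytest.fixture(scope="session")
def ci2d():
    return make_conical_2d()


@pytest.fixture(scope="session")
def small_dataset(ci2d):
    """300 uncorrupted exact samples of the 2D conical model."""
    return generate_dataset(
        ci2d, SamplingSpec(scheme="uniform_box", n_samples=300, seed=5))


@pytest.fixture(scope="session")
def corrupted_dataset(ci2d):
    """300 samples with every coupled property sign-scrambled."""
    return generate_dataset(
        ci2d, SamplingSpec(scheme="uniform_box", n_samples=300, seed=7,
                           phase_corruption=1.0))


@pytest.fixture
def random_geometry():
    rng = np.random.default_rng(42)
    base = np.array([[0.0, 0.0, 0.0], [2.5, 0.0, 0.0], [1.2, 2.2, 0.0]])
    return Geometry(np.array([1, 6, 8]), base + 0.2 * rng.normal(size=(3, 3)))
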