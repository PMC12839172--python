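import numpy as np
import pytest

from mandiblemetrics.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def coarse_spec():
    # 2 mm phantom: all construction guarantees are resolution-independent,
    # and the coarse mesh keeps registration-heavy tests fast
    return PhantomSpec(mesh_edge_length=2.0)


@pytest.fixture(scope="session")
def planned(coarse_spec):
    return generate_phantom(coarse_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def rotation_matrix(axis, angle_deg):
    from scipy.spatial.transform import Rotation

    axis = np.asarray(axis, dtype=float)
    return Rotation.from_rotvec(np.radians(angle_deg) * axis / np.linalg.norm(axis)).as_matrix()


def random_rigid(rng, max_angle=30.0, max_translation=15.0):
    from mandiblemetrics.geometry import RigidTransform

    axis = rng.normal(size=3)
    angle = rng.uniform(0, max_angle)
    t = rng.normal(size=3)
    t = t / np.linalg.norm(t) * rng.uniform(0, max_translation)
    return RigidTransform(rotation_matrix(axis, angle), t)
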