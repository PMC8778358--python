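import numpy as np
import pytest

from dynopharm.pharmacophore import assemble_reference_model
from dynopharm.synthetic import make_pocket, make_trajectory, PlantSpec


@pytest.fixture(scope="session")
def pocket():
    """Toy pocket topology and its all-interactions-on frame."""
    return make_pocket()


@pytest.fixture(scope="session")
def ref_model():
    """The packaged eight-element reference pharmacophore."""
    return assemble_reference_model()


@pytest.fixture(scope="session")
def small_traj():
    """200-frame trajectory with mixed planted probabilities (seed 7)."""
    spec = PlantSpec(
        interactions=[
            (("A", 85, "LEU"), "hbond", 0.95),
            (("A", 83, "GLU"), "hbond", 0.9),
            (("A", 20, "PHE"), "pi_stack", 0.4),
            (("A", 135, "LEU"), "hydrophobic", 0.6),
            (("A", 52, "GLU"), "salt_bridge", 0.25),
        ],
        n_frames=200, seed=7, bridge_probability=0.5)
    return make_trajectory(spec)


def random_rigid_transform(rng):
    """Uniform random rotation (quaternion method) plus translation."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    R = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])
    t = rng.uniform(-20.0, 20.0, 3)
    return R, t
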