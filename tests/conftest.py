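import numpy as np
import pytest
import trimesh

from wristkin import synthetic as syn


@pytest.fixture(scope="session")
def templates():
    return syn.default_templates()


@pytest.fixture(scope="session")
def unit_cube():
    cube = trimesh.creation.box(extents=(1.0, 1.0, 1.0))
    cube.apply_translation([0.5, 0.5, 0.5])
    return cube


@pytest.fixture(scope="session")
def noise_free_specimen():
    """One synthetic wrist with default transection effects, no vertex noise."""
    effects = syn.default_effects()
    effects.vertex_noise_sd = 0.0
    return syn.generate_specimen("S001", effects=effects, seed=3)


@pytest.fixture(scope="session")
def neutral_bone_meshes(noise_free_specimen):
    return noise_free_specimen.meshes[("neutral", "intact")]


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
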