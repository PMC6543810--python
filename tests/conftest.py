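import numpy as np
import pytest

from kirpharm.synthetic import default_ensemble_spec, gen_feature_trajectory


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation matrix."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )


@pytest.fixture(scope="session")
def small_ensemble():
    """A 500-frame synthetic MD feature ensemble (fixed seed)."""
    return gen_feature_trajectory(default_ensemble_spec(n_frames=500), seed=7)


@pytest.fixture(scope="session")
def representatives(small_ensemble):
    from kirpharm.pharmacophore import merge_models

    return merge_models(small_ensemble.frame_models())
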