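import numpy as np
import pytest

from biotex.orientation import CrystalSymmetry, Orientation
from biotex.synthetic import TextureRecipe, generate_map


@pytest.fixture(scope="session")
def hex_sym():
    return CrystalSymmetry.hexagonal()


@pytest.fixture(scope="session")
def small_map():
    """A modest textured map shared across tests (seeded, 40x40)."""
    recipe = TextureRecipe(c_dispersion=8.0,
                           a_rotation_model=("dispersed", 10.0),
                           patch_noise=3.0, unindexed_fraction=0.25)
    emap, truth = generate_map(recipe, 40, 40, seed=20)
    return emap, truth


def constant_map(quat, width, height, step=0.5, phase=None):
    """Map with a single repeated orientation (helper for fixtures)."""
    from biotex.io import EBSDMap

    n = width * height
    q = np.tile(np.asarray(quat, dtype=float), (n, 1))
    ph = np.ones((height, width), dtype=int) if phase is None else phase
    return EBSDMap(
        orientations=Orientation(q),
        phase=ph,
        band_contrast=np.full((height, width), 150.0),
        step=step,
        phases={1: CrystalSymmetry.hexagonal()},
    )
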