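import numpy as np
import pytest

from petquant.image_io import SUVImage
from petquant.phantom import LesionSpec, PhantomSpec, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture
def uniform_image():
    """A 20^3 1-mm volume with uniform SUV 1.0."""
    return SUVImage(voxels=np.ones((20, 20, 20)), spacing=(1.0, 1.0, 1.0))


@pytest.fixture
def hot_sphere_phantom():
    """Noiseless, blurred phantom: one 8-mm sphere, peak 10, background 1."""
    spec = PhantomSpec(
        shape=(40, 40, 40),
        spacing=(1.0, 1.0, 1.0),
        background_suv=1.0,
        noise_sd=0.0,
        blur_fwhm=6.0,
        lesions=(LesionSpec(center=(20.0, 20.0, 20.0), radius=8.0, peak_suv=10.0),),
        rng_seed=7,
    )
    return generate_phantom(spec)


def flood_fill_6(binary, seed):
    """Reference 6-connected flood fill (BFS) on a boolean grid."""
    binary = np.asarray(binary, dtype=bool)
    if not binary[seed]:
        return set()
    shape = binary.shape
    seen = {tuple(seed)}
    queue = [tuple(seed)]
    while queue:
        x, y, z = queue.pop()
        for dx, dy, dz in ((1, 0, 0), (-1, 0, 0), (0, 1, 0),
                           (0, -1, 0), (0, 0, 1), (0, 0, -1)):
            nb = (x + dx, y + dy, z + dz)
            if all(0 <= c < n for c, n in zip(nb, shape)) \
                    and binary[nb] and nb not in seen:
                seen.add(nb)
                queue.append(nb)
    return seen
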