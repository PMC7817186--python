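import numpy as np
import pytest

from istomo.phantom import CellSpec, PhantomSpec


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def two_sphere_spec():
    """Two equal touching-with-overlap spheres on a small grid."""
    p = 218.5
    return PhantomSpec(
        shape=(32, 32, 64), pitch_nm=(p, p, p), medium_ri=1.337,
        effector=CellSpec(center_nm=(16 * p, 16 * p, 24 * p), radius_nm=8 * p,
                          cytoplasm_ri=1.360),
        target=CellSpec(center_nm=(16 * p, 16 * p, 38 * p), radius_nm=8 * p,
                        cytoplasm_ri=1.350),
        seed=3)


def random_blob(rng, shape, p=0.5, smooth=True):
    """A random connected-ish binary blob for mask-based property tests."""
    from scipy import ndimage

    field = ndimage.gaussian_filter(rng.standard_normal(shape), 1.5)
    mask = field > np.quantile(field, 1 - p * 0.5)
    if smooth:
        mask = ndimage.binary_closing(mask)
    return mask
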