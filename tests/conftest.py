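import numpy as np
import pytest

from octlam.phantom import PhantomSpec, generate_dataset
from octlam.preprocess import PreprocessConfig, assemble_volume

SMALL_SPEC = PhantomSpec(width=120, height=160, n_slices=64, n_layers=4, lesion_radius=7.0)
SMALL_CFG = PreprocessConfig(
    slice_lo=16, slice_hi=48, sample_stride=2, crop_width=60, out_xy=48, out_depth=16
)


def numerical_gradient(f, x, eps=1e-5):
    """Central-difference gradient of a scalar function of an array, in place."""
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        old = x[i]
        x[i] = old + eps
        fp = f()
        x[i] = old - eps
        fm = f()
        x[i] = old
        g[i] = (fp - fm) / (2 * eps)
    return g


@pytest.fixture(scope="session")
def small_volumes():
    """Six phantom volumes at the reduced 48x48x16 geometry, balanced labels."""
    stacks = generate_dataset(6, 0.5, SMALL_SPEC, seed=11)
    return [assemble_volume(s, SMALL_CFG) for s in stacks]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
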