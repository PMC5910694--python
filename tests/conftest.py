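import numpy as np
import pytest

from myoarch.dti import EigenMaps
from myoarch.phantom import four_slab_spec, generate_phantom


@pytest.fixture(scope="session")
def straight_phantom():
    """Four-slab straight-fibre phantom (session-scoped: generation is pure)."""
    spec = four_slab_spec()
    return spec, generate_phantom(spec)


@pytest.fixture(scope="session")
def arc_phantom():
    spec = four_slab_spec(arc_radius_mm=58.8)
    return spec, generate_phantom(spec)


def make_eigenmaps(e1_field: np.ndarray, affine: np.ndarray,
                   fa: float = 0.3, md: float = 1.33e-3) -> EigenMaps:
    """Synthetic eigen-decomposition maps with a prescribed e1 field and
    constant FA/MD, for direct tractography tests."""
    shape = e1_field.shape[:3]
    evals = np.tile([1.7e-3, 1.2e-3, 1.1e-3], shape + (1,))
    evecs = np.zeros(shape + (3, 3))
    evecs[..., 0, :] = e1_field
    return EigenMaps(
        evals=evals,
        evecs=evecs,
        fa=np.full(shape, fa),
        md=np.full(shape, md),
        mask=np.ones(shape, dtype=bool),
        affine=np.asarray(affine, dtype=float),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
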