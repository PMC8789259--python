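import numpy as np
import pytest

from virtuheart import fusion, synthetic


@pytest.fixture(scope="session")
def default_pair():
    """One synthetic patient at the cohort-mean study conditions."""
    spec = synthetic.SyntheticCohortSpec(seed=3)
    return synthetic.generate_lge_t1_pair(spec)


@pytest.fixture(scope="session")
def noiseless_pair():
    spec = synthetic.SyntheticCohortSpec(seed=5, noise_sd=0.0)
    return synthetic.generate_lge_t1_pair(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def annulus_grid():
    """Small homogeneous annular grid for geometry tests."""
    from virtuheart import geometry
    lm = synthetic.generate_substrate_phantom("homogeneous", n=36,
                                              r_outer=16.0, r_inner=8.0)
    return geometry.build_grid(lm, 1000.0)


@pytest.fixture(scope="session")
def slab_grid():
    """Rectangular 20 x 10 mm slab at 1 mm resolution."""
    from virtuheart import geometry
    lm = fusion.TissueLabelMap(np.ones((10, 20), dtype=np.int8), (1.0, 1.0))
    return geometry.build_grid(lm, 1000.0)
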