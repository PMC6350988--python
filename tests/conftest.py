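import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from qpmcell.phantoms import PhantomSpec, PopulationSpec, make_phantom, sample_population


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_population():
    """A reduced two-class population shared by the classifier tests."""
    return sample_population(PopulationSpec(n_per_class=40, seed=11))


@pytest.fixture(scope="session")
def smooth_phantom():
    return make_phantom(PhantomSpec(base="hemi_ellipsoid", diameter_px=40,
                                    plateau_opl_nm=300, bump_height_frac=0.0))


@pytest.fixture(scope="session")
def bumpy_phantom():
    return make_phantom(PhantomSpec(base="hemi_ellipsoid", diameter_px=40,
                                    plateau_opl_nm=300, bump_height_frac=0.11))
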