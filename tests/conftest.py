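import numpy as np
import pytest

from poicrime.geodata_io import PointSet, StudyArea
from poicrime.density_estimation import KernelSpec
from poicrime.synthetic_city import (benchmark_city_spec, generate_poi_layout,
                                     sample_crimes)
from poicrime.evaluation import CityBundle

ALL_KERNELS = ("gaussian", "tophat", "epanechnikov", "exponential", "linear",
               "cosine")


@pytest.fixture
def area60():
    return StudyArea(0.0, 0.0, 3000.0, n_cells_per_side=60)


@pytest.fixture
def area30():
    return StudyArea(0.0, 0.0, 600.0, n_cells_per_side=30)


@pytest.fixture
def exp_kernel():
    return KernelSpec("exponential", 75.0)


@pytest.fixture
def random_points():
    rng = np.random.default_rng(42)
    return PointSet("test", rng.uniform(-300, 300, (20, 2)))


@pytest.fixture
def benchmark_bundle():
    """Standard 3-signal + 12-clutter synthetic city at 60x60 grid."""
    spec = benchmark_city_spec(seed=7)
    layout = generate_poi_layout(spec)
    crimes = sample_crimes(spec, layout)
    return CityBundle("synthetic", layout, crimes, spec.area), spec
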