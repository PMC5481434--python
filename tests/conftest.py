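import numpy as np
import pytest

from glycotma import synthetic_data as sd


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_scene():
    """A 300-um core with one region of each glycan class, fast to render."""

    spec = sd.SceneSpec(
        core_diameter_um=300.0,
        regions=(
            sd.RegionSpec("dual", center_um=(100.0, 150.0), radius_um=35.0),
            sd.RegionSpec("ca199_only", center_um=(200.0, 100.0), radius_um=30.0),
            sd.RegionSpec("stra_only", center_um=(200.0, 200.0), radius_um=30.0),
        ),
        seed=42,
    )
    return sd.generate_scene(spec)


@pytest.fixture(scope="session")
def default_cohort():
    return sd.generate_cohort(sd.CohortSpec(n_patients=45, seed=7))
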