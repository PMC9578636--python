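import numpy as np
import pytest

from testisquant import SceneSpec, make_nuclei_scene


@pytest.fixture(scope="session")
def clean_scene():
    """Noise-free, well-separated 5-nucleus scene (min sep = 5 radii)."""
    spec = SceneSpec(shape=(24, 128, 128), n_cells=5, min_separation_um=10.0,
                     noise="none", seed=11)
    stack, truth = make_nuclei_scene(spec)
    return spec, stack, truth


@pytest.fixture(scope="session")
def niche_scene():
    """Hub + GSC/CySC scene used by phenotyping tests."""
    spec = SceneSpec(shape=(36, 160, 160), n_cells=6, min_separation_um=7.0,
                     include_hub=True, hub_radius_um=10.0, n_gsc=4, n_cysc=3,
                     marker_fractions={"vasa": 0.5, "zfh1": 0.25}, seed=5)
    stack, truth = make_nuclei_scene(spec)
    return spec, stack, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
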