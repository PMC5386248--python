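import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pocketphylo.pocket_geometry import detect_pockets
from pocketphylo.synthetic_data import (
    CavitySpec,
    StudyConfig,
    make_cavity_structure,
    synthetic_grid_params,
)

settings.register_profile(
    "default",
    max_examples=25,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def sphere_fixture():
    """Enclosed spherical cavity (r = 6 Å) with its detected pockets."""
    model, truth = make_cavity_structure(30, CavitySpec("sphere", radius=6.0))
    params = synthetic_grid_params(spacing=0.5)
    pockets = detect_pockets(model, params)
    return model, truth, params, pockets


@pytest.fixture(scope="session")
def mini_study_config():
    """A scaled-down 3-group study for fast pipeline tests."""
    return StudyConfig(
        group_labels=("I", "II", "III"),
        n_clr={"I": 6, "II": 7, "III": 9},
        radii={"I": 3.0, "II": 3.5, "III": 4.0},
        n_common=4,
        specifics={},
        n_shared_columns=5,
        sequence_length=40,
        n_conserved_common=3,
        n_conserved_other_clr=2,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260927)
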