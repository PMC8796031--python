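import numpy as np
import pytest

from spikebeam import (build_sphere_head, build_source_grid,
                       eeg_sphere_leadfield, meg_sphere_leadfield,
                       place_sensors)

# standard three-shell profile: brain 0.33, skull 0.01, skin 0.43 S/m
RADII = [80.0, 85.0, 92.0]
SIGMA_3C = [0.33, 0.01, 0.43]


@pytest.fixture(scope="session")
def head3():
    return build_sphere_head(RADII, SIGMA_3C, label="3C-standard")


@pytest.fixture(scope="session")
def head_homog():
    return build_sphere_head(RADII, [0.33, 0.33, 0.33], label="homogeneous")


@pytest.fixture(scope="session")
def eeg_sensors(head3):
    return place_sensors(head3, "eeg", 60, 0.0, "hemisphere")


@pytest.fixture(scope="session")
def meg_sensors(head3):
    return place_sensors(head3, "meg", 80, 20.0, "hemisphere")


@pytest.fixture(scope="session")
def grid_coarse(head3):
    return build_source_grid(head3, spacing=14.0, margin=2.0)


@pytest.fixture(scope="session")
def eeg_lf(head3, eeg_sensors, grid_coarse):
    return eeg_sphere_leadfield(head3, eeg_sensors, grid_coarse)


@pytest.fixture(scope="session")
def meg_lf(meg_sensors, grid_coarse):
    with np.errstate(all="ignore"):
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return meg_sphere_leadfield(meg_sensors, grid_coarse)


@pytest.fixture(scope="session")
def lateral_index(grid_coarse):
    """A superficial lateral grid point, spike-like."""
    return grid_coarse.nearest_index([24.0, 0.0, 48.0])
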