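import numpy as np
import pytest

import folliquant as fq
from folliquant.synthetic import default_manifest, load_fixture


@pytest.fixture(scope="session")
def cal02():
    """0.2 um/px, 1 s/frame, AP along x."""
    return fq.Calibration(pixel_size=0.2, frame_interval=1.0, axis_frame=0.0)


@pytest.fixture(scope="session")
def fiber_scene():
    """Stage-10 fiber scene (seed 0): stack, mask, filopodia, manifest."""
    return fq.generate_fiber_scene(load_fixture("fiber_stage10"))


@pytest.fixture(scope="session")
def clean_fiber_scene():
    """Fiber scene without filopodia, puncta or noise: isolates the
    fiber-intensity allocation."""
    m = load_fixture("fiber_stage10").replace(
        filopodia_per_cell=0, puncta_contrast=0.0, noise_sigma=0.0)
    return fq.generate_fiber_scene(m)


@pytest.fixture(scope="session")
def ablation_cell_scene():
    m = load_fixture("ablation_control_cell_APcut")
    return fq.generate_ablation_pair(m), m


@pytest.fixture(scope="session")
def oscillation_movie():
    m = default_manifest("oscillation", n_cells_ap=4, n_cells_dv=3)
    return fq.generate_oscillation_movie(m), m


@pytest.fixture(scope="session")
def rotation_movie():
    m = default_manifest("rotation", n_cells_ap=4, n_cells_dv=3,
                         noise_sigma=0.0)
    return fq.generate_rotation_movie(m), m


@pytest.fixture
def rng():
    return np.random.default_rng(42)
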