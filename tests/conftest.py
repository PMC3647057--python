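import numpy as np
import pytest

import renalqmri as rq


@pytest.fixture(scope="session")
def cd0h_zero_sd_phantom() -> rq.KidneyPhantom:
    """Default-grid CD0h phantom with zero biological variance: every
    compartment carries the reference means exactly."""
    preset = rq.table_preset("CD0h").with_zero_sd()
    return rq.make_kidney_phantom(preset=preset, seed=7)


@pytest.fixture(scope="session")
def multi_echo_acq() -> rq.AcquisitionConfig:
    return rq.AcquisitionConfig(te_list_ms=(5.0, 10.0, 20.0, 40.0, 80.0))


@pytest.fixture(scope="session")
def small_grid() -> tuple[int, int]:
    """Small grid for tests that build many phantoms."""
    return (64, 32)


@pytest.fixture(scope="session")
def label_map() -> np.ndarray:
    return rq.make_label_map((256, 128))
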