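import numpy as np
import pytest

from bse import source_model as sm
from bse import synthetic as syn


@pytest.fixture(scope="session")
def stimulus_set():
    return syn.make_stimulus_set(seed=11)


@pytest.fixture(scope="session")
def small_geometry():
    """Desk-scale shell + MEG layout + leadfield + lambda=0.1 inverse."""
    shell = sm.build_source_shell(head_radius=0.09, n_sites=60, n_orient=2)
    layout = sm.make_sensor_layout(24, "meg", 0.09)
    leadfield = sm.forward_leadfield(shell, layout)
    inverse = sm.mne_inverse_operator(leadfield, lam=0.1)
    return shell, layout, leadfield, inverse


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
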