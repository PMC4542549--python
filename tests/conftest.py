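import numpy as np
import pytest

import splenotex as st


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture(scope="session")
def small_phantom_spec():
    """A reduced phantom for unit tests (not the default study conditions)."""
    return st.PhantomSpec(grid_shape=(96, 64, 64),
                          spleen_semi_axes=(26.0, 22.0, 42.0),
                          nodule_count=16, nodule_radius_mean=4.5,
                          nodule_radius_sd=0.5, mz_thickness=2.0,
                          vessel_count=2, artifact_count=0, noise_sd=0.0,
                          seed=42)


@pytest.fixture(scope="session")
def small_phantom(small_phantom_spec):
    return st.generate_spleen_phantom(small_phantom_spec)


@pytest.fixture(scope="session")
def default_phantom():
    """One phantom at the default (study-condition) resolution."""
    return st.generate_spleen_phantom(st.PhantomSpec(seed=2025))


@pytest.fixture(scope="session")
def pipeline_report():
    """The full default study, run once and shared across tests."""
    return st.run_pipeline(seed=1)


@pytest.fixture(scope="session")
def fig_study():
    """The four-simulation 2-D contrast study, run once."""
    return st.feature_simulation_study()
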