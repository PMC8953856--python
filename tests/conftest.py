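import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from raftitc import BindingParams1Site, TitrationDesign

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture
def design() -> TitrationDesign:
    """The study titration: 300 uM GM1:DPC into 15 uM peptide, 20 x 15 uL."""
    return TitrationDesign()


@pytest.fixture
def parent_params() -> BindingParams1Site:
    """Parent-sequence ground truth: K_D 23.8 nM, n 0.5, exothermic."""
    return BindingParams1Site(n=0.5, kd_nm=23.8, dh_kcal_per_mol=-8.0, q_dil_ucal=-0.2)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2026)
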