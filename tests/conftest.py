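import pytest
from hypothesis import HealthCheck, settings

from ehtmech.synthetic import SyntheticTissueSpec, generate_speckle, tissue_mask

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_spec():
    """Compact tissue used by the DIC unit tests (no zone structure needed)."""
    return SyntheticTissueSpec(
        length_mm=2.0, width_mm=2.0, wound_center_mm=1.0, wound_width_mm=0.5,
        border_width_mm=0.3, px_per_mm=50.0, seed=7,
    )


@pytest.fixture(scope="session")
def small_speckle(small_spec):
    return generate_speckle(small_spec)


@pytest.fixture(scope="session")
def small_mask(small_spec):
    return tissue_mask(small_spec)
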