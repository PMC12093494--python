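import dataclasses

import pytest
from hypothesis import HealthCheck, settings

from cazprofiler.simulate import SimConfig, generate_dataset

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


SMALL_TAXONOMY = (
    ("Cystobacterineae", "Myxococcaceae", 3),
    ("Cystobacterineae", "Archangiaceae", 2),
    ("Nannocystineae", "Nannocystaceae", 2),
    ("Sorangiineae", "Polyangiaceae", 3),
)


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    """Ten organisms across all three suborders, decoys on."""
    return dataclasses.replace(SimConfig(seed=11), taxonomy_spec=SMALL_TAXONOMY)


@pytest.fixture(scope="session")
def clean_cfg() -> SimConfig:
    """Ten organisms across all three suborders, decoys disabled."""
    return dataclasses.replace(
        SimConfig(seed=11), taxonomy_spec=SMALL_TAXONOMY, decoy_rates=(0.0, 0.0)
    )


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    return generate_dataset(small_cfg)


@pytest.fixture(scope="session")
def clean_dataset(clean_cfg):
    return generate_dataset(clean_cfg)
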