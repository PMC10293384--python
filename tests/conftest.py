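from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from megslow import RoiRecording, load_atlas

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def atlas():
    return load_atlas()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


def make_recording(
    rng: np.random.Generator,
    n_regions: int = 2,
    n_samples: int = 45_000,
    sample_rate: float = 312.5,
    subject: str = "S01",
    visit: str = "BL",
) -> RoiRecording:
    return RoiRecording(
        subject, visit, sample_rate, rng.standard_normal((n_regions, n_samples))
    )


@pytest.fixture()
def white_recording(rng):
    return make_recording(rng)
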