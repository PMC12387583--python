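import numpy as np
import pytest

from vergesim.geometry import WorldConfig, WorldPoint
from vergesim.subject_model import SyntheticSubject


@pytest.fixture
def world() -> WorldConfig:
    return WorldConfig()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture
def center(world) -> WorldPoint:
    return WorldPoint(0.0, world.eye_height_m, world.viewing_distance_m)


def make_subject(
    pfv=18.0, nfv=8.0, bias=0.65, noise=0.25, subject_id="s001"
) -> SyntheticSubject:
    return SyntheticSubject(
        subject_id=subject_id,
        pfv_amplitude=pfv,
        nfv_amplitude=nfv,
        baseline_bias_mean=bias,
        motor_noise_sd=noise,
    )


@pytest.fixture
def noiseless_subject() -> SyntheticSubject:
    return make_subject(bias=0.0, noise=0.0)
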