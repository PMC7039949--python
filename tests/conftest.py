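import numpy as np
import pytest

from eabrkit.config import StudyConfig
from eabrkit.pipeline import build_gen_params, run_pipeline
from eabrkit.synthdata import Condition, GenParams, GroundTruth
from eabrkit.stimulus import Polarity, PulseShape


@pytest.fixture(scope="session")
def default_config() -> StudyConfig:
    return StudyConfig(seed=1)


@pytest.fixture(scope="session")
def default_study_result(default_config):
    """Full default synthetic study (4 shapes x 2 polarities x 8 levels
    x 400 sweeps x 4 delays) run through the whole pipeline once."""
    return run_pipeline(default_config)


@pytest.fixture(scope="session")
def default_ground_truth(default_config) -> GroundTruth:
    return GroundTruth(
        params=build_gen_params(default_config),
        levels_nc=tuple(default_config.charge_levels_nc),
    )


@pytest.fixture
def quiet_params() -> GenParams:
    """Noise-free generator for deterministic structural checks."""
    return GenParams(noise_sd_uv=0.0, n_sweeps=2)


@pytest.fixture
def small_config() -> StudyConfig:
    return StudyConfig(
        seed=7,
        shapes=["rec", "ramp_up"],
        polarities=["anodic_first", "cathodic_first"],
        charge_levels_nc=[2.2, 3.4, 4.8, 7.0],
        generator={"n_sweeps": 20},
        model={},
    )


def make_condition(
    shape=PulseShape.REC,
    polarity=Polarity.ANODIC_FIRST,
    charge_nc=4.8,
    phase_duration_us=25.0,
    interphase_gap_us=10.0,
) -> Condition:
    return Condition.from_charge(
        shape, polarity, charge_nc, phase_duration_us, interphase_gap_us
    )
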