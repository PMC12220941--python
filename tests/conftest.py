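import numpy as np
import pytest

from optoerg.photometry import PhotometryCalibration, StimulusSpec
from optoerg.pipeline import AnalysisConfig
from optoerg.preprocessing import Trace


@pytest.fixture(scope="session")
def config() -> AnalysisConfig:
    return AnalysisConfig()


@pytest.fixture(scope="session")
def calibration() -> PhotometryCalibration:
    return PhotometryCalibration()


@pytest.fixture
def light_100() -> StimulusSpec:
    return StimulusSpec(100.0, background_luminance=30.0)


@pytest.fixture
def light_10() -> StimulusSpec:
    return StimulusSpec(10.0, background_luminance=30.0)


def make_trace(values, sample_rate=2000.0, pre_stimulus_ms=20.0) -> Trace:
    return Trace(
        values=np.asarray(values, float),
        sample_rate=sample_rate,
        pre_stimulus_ms=pre_stimulus_ms,
    )


def time_grid(n=1000, sample_rate=2000.0, pre_stimulus_ms=20.0):
    return np.arange(n) / sample_rate * 1000.0 - pre_stimulus_ms
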