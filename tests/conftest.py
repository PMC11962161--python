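import numpy as np
import pytest

from condtrack import (EmitterModel, MovieCalibration, NoiseModel,
                       simulate_movie)


@pytest.fixture(scope="session")
def fixture_noise() -> NoiseModel:
    """Study-condition camera noise used across the suite."""
    return NoiseModel()


@pytest.fixture(scope="session")
def clean_noise() -> NoiseModel:
    """No background, no shot noise, no read noise."""
    return NoiseModel(background_level=0.0, read_noise_sd=0.0, shot_noise=False)


@pytest.fixture(scope="session")
def small_calibration() -> MovieCalibration:
    return MovieCalibration(frame_count=10, roi=(64, 64))


@pytest.fixture(scope="session")
def tracking_movie():
    """A dense-enough tracking movie with ground truth, shared by tests.

    Ten 8-mer assemblies diffusing slowly, photobleaching over 200 frames in
    the full 240 x 184 analysis region at fixture noise.
    """
    cal = MovieCalibration(frame_count=200, roi=(240, 184))
    specs = [{"stoichiometry": 8, "d": 0.02} for _ in range(10)]
    movie, truths = simulate_movie(cal, specs,
                                   EmitterModel(bleach_rate=0.02),
                                   NoiseModel(), seed=11)
    return cal, movie, truths


def rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)
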