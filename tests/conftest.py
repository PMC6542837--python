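import numpy as np
import pytest

from biofilmwet import GrayImage
from biofilmwet.io import manifest_from_spec
from biofilmwet.phantoms import make_squeeze_video, study_condition_spec


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture
def flat_image():
    """A constant mid-gray 8-bit frame."""
    return GrayImage(np.full((64, 64), 120.0))


def render_and_measure(condition: str, seed: int = 0, noise_sd: float = 3.0, **overrides):
    """Render one study-condition video and run the full measurement chain."""
    from biofilmwet.squeeze import analyze_series, diameter_series

    spec = study_condition_spec(condition, seed=seed, noise_sd=noise_sd, **overrides)
    frames, truth = make_squeeze_video(spec)
    series = diameter_series(frames, manifest_from_spec(spec))
    return spec, truth, series, analyze_series(series)
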