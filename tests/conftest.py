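import numpy as np
import pytest

from blisterquant.config import CellConfig, PipelineConfig, StainConfig, TissueConfig
from blisterquant.synthetic import (
    OpticalModel,
    SlideSpec,
    generate_ihc_slide,
)


@pytest.fixture(scope="session")
def noiseless_model():
    return OpticalModel(noise_sd=0.0)


@pytest.fixture(scope="session")
def default_slide(noiseless_model):
    """The standard noiseless synthetic slide: 60 positive / 40 negative cells."""
    return generate_ihc_slide(SlideSpec(), noiseless_model, seed=1)


@pytest.fixture(scope="session")
def small_slide(noiseless_model):
    """A quick slide for unit tests: 384 px, 10 positive / 10 negative cells."""
    spec = SlideSpec(shape=(384, 384), n_positive=10, n_negative=10)
    return generate_ihc_slide(spec, noiseless_model, seed=2)


@pytest.fixture(scope="session")
def standard_library():
    from blisterquant.synthetic import default_standard_library

    return default_standard_library()


@pytest.fixture
def tissue_config():
    return TissueConfig()


@pytest.fixture
def stain_config():
    return StainConfig()


@pytest.fixture
def cell_config():
    return CellConfig()


@pytest.fixture
def pipeline_config():
    return PipelineConfig()


def brute_force_mean_filter(raster, window):
    """Reflection-padded windowed mean by direct summation (test oracle)."""
    raster = np.asarray(raster, dtype=float)
    half = window // 2
    padded = np.pad(raster, half, mode="symmetric")
    out = np.empty_like(raster)
    for i in range(raster.shape[0]):
        for j in range(raster.shape[1]):
            out[i, j] = padded[i : i + window, j : j + window].mean()
    return out
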