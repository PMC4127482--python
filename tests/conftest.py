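import numpy as np
import pytest

from shapecortex.fields import OrientationField
from shapecortex.model import ModelConfig
from shapecortex.stimuli import StimulusSpec, render
from shapecortex.v1 import lgn_response, v1_from_linear, v1_linear, v1_simple_bank
from shapecortex.v2v3 import subsample


@pytest.fixture(scope="session")
def config():
    return ModelConfig()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


def v1_field_of(img, config):
    """Run LGN + V1 simple/complex on an image (helper shared by tests)."""
    on_off = lgn_response(
        img, config.lgn_sigma, config.lgn_kappa, config.lgn_alpha,
        config.lgn_beta, config.border_mode,
    )
    lin = v1_linear(
        v1_simple_bank(
            on_off, config.n_orientations, config.v1_sigma1_px,
            config.v1_sigma2_px, config.v1_omega1, config.border_mode,
        )
    )
    return v1_from_linear(
        lin, k=config.v1_k, alpha=config.v1_alpha, beta=config.v1_beta
    )


def v1_on_v2_grid(img, config):
    fld = v1_field_of(img, config)
    return OrientationField(
        subsample(fld.data, config.v2_subsampling),
        resolution_scale=config.v2_subsampling,
    )


@pytest.fixture(scope="session")
def vertical_edge():
    return render(StimulusSpec(kind="edge", orientation=np.pi / 2, canvas=(64, 64)))


@pytest.fixture(scope="session")
def blank_image():
    return np.full((64, 64), 0.5)
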